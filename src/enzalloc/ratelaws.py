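"""Enzymatic rate laws for uni-uni reactions in unbranched pathways.

The most general law considered here is the reversible saturable (Haldane)
rate law

    v = eps * (kcat+ * s/K_S - kcat- * p/K_P) / (1 + s/K_S + p/K_P),

which factorizes, via the Haldane relationship
K_eq = (kcat+/kcat-) * (K_P/K_S), into

    v = eps * kcat+ * eta_for(theta) * eta_sat(s, p),

with the thermodynamic force efficiency eta_for = 1 - exp(-theta),
theta = ln(K_eq * s / p), and the saturation efficiency
eta_sat = (s/K_S) / (1 + s/K_S + p/K_P).  Four simplified laws follow as
limiting cases:

* trivial        v = eps * kcat                     (saturated, irreversible)
* Michaelis-Menten  v = eps * kcat * s/(s + K_S)    (irreversible, saturable)
* thermodynamic  v = eps * kcat * (1 - exp(-theta)) (reversible, saturated)
* mass-action    v = eps * (kcat/K_S) * (s - p/K_eq)  (reversible, dilute)

All quantities are unit-agnostic: enzyme levels may be molar or mass
concentrations as long as the kcat values are interpreted consistently
(turnover numbers or specific activities).  theta is dimensionless (gas
constant and temperature dropped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, InfeasibleError, MissingKineticsError

__all__ = [
    "RateLawKind",
    "ReactionKinetics",
    "ConvenienceKinetics",
    "PathwaySpec",
    "driving_force",
    "efficiencies",
    "rate_per_enzyme",
    "rate_gradient",
    "evaluate_rate",
    "enzyme_demand",
    "convenience_rate",
    "effective_uniuni_params",
]

_HALDANE_RTOL = 1e-9


class RateLawKind(str, Enum):
    """The five rate-law kinds, ordered by increasing complexity."""

    TRIVIAL = "trivial"
    MICHAELIS_MENTEN = "michaelis_menten"
    THERMODYNAMIC = "thermodynamic"
    MASS_ACTION = "mass_action"
    HALDANE = "haldane"

    @property
    def required_fields(self) -> tuple[str, ...]:
        return _REQUIRED_FIELDS[self]

    @property
    def reversible(self) -> bool:
        return self in (
            RateLawKind.THERMODYNAMIC,
            RateLawKind.MASS_ACTION,
            RateLawKind.HALDANE,
        )


_REQUIRED_FIELDS = {
    RateLawKind.TRIVIAL: ("kcat_fwd",),
    RateLawKind.MICHAELIS_MENTEN: ("kcat_fwd", "K_S"),
    RateLawKind.THERMODYNAMIC: ("kcat_fwd", "K_eq"),
    RateLawKind.MASS_ACTION: ("kcat_fwd", "K_S", "K_eq"),
    RateLawKind.HALDANE: ("kcat_fwd", "K_S", "K_P", "K_eq"),
}


@dataclass(frozen=True)
class ReactionKinetics:
    """Kinetic constants of one uni-uni reaction.

    Parameters
    ----------
    kcat_fwd
        Forward turnover number (time^-1) or specific activity.
    kcat_rev
        Reverse turnover; optional.  When all of ``kcat_rev``, ``K_S``,
        ``K_P`` and ``K_eq`` are supplied they must satisfy the Haldane
        relationship ``K_eq = (kcat_fwd/kcat_rev) * (K_P/K_S)``.
    K_S, K_P
        Michaelis constants of substrate and product (concentration).
    K_eq
        Equilibrium constant (dimensionless for a uni-uni reaction).
    """

    kcat_fwd: float
    kcat_rev: Optional[float] = None
    K_S: Optional[float] = None
    K_P: Optional[float] = None
    K_eq: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("kcat_fwd", "kcat_rev", "K_S", "K_P", "K_eq"):
            value = getattr(self, name)
            if value is not None and not (value > 0):
                raise DomainError(f"{name} must be strictly positive, got {value!r}")
        if None not in (self.kcat_rev, self.K_S, self.K_P, self.K_eq):
            implied = (self.kcat_fwd / self.kcat_rev) * (self.K_P / self.K_S)
            if not math.isclose(implied, self.K_eq, rel_tol=_HALDANE_RTOL):
                raise DomainError(
                    "Haldane relationship violated: "
                    f"(kcat_fwd/kcat_rev)*(K_P/K_S) = {implied:g} but K_eq = {self.K_eq:g}"
                )

    def require(self, kind: RateLawKind) -> None:
        """Raise if this reaction lacks a constant the rate law needs."""
        for name in kind.required_fields:
            if getattr(self, name) is None:
                raise MissingKineticsError(
                    f"rate law {kind.value!r} requires {name}, which is missing"
                )

    @property
    def kcat_rev_implied(self) -> float:
        """Reverse turnover implied by the Haldane relationship."""
        if self.kcat_rev is not None:
            return self.kcat_rev
        if self.K_S is None or self.K_P is None or self.K_eq is None:
            raise MissingKineticsError(
                "kcat_rev not supplied and cannot be derived (need K_S, K_P, K_eq)"
            )
        return self.kcat_fwd * self.K_P / (self.K_S * self.K_eq)


@dataclass(frozen=True)
class PathwaySpec:
    """An unbranched chain S_0 <-> S_1 <-> ... <-> S_n with one enzyme per step.

    ``s0``/``sn`` are the boundary concentrations; ``None`` marks a boundary
    that is free (subject to optimization).  ``eps_tot`` bounds the total
    (optionally weighted) enzyme level, ``s_tot`` the total concentration of
    free metabolites (a proxy for the osmotic/crowding limit).
    """

    reactions: tuple[ReactionKinetics, ...]
    eps_tot: float = 1.0
    s0: Optional[float] = None
    sn: Optional[float] = None
    s_tot: Optional[float] = None
    enzyme_weights: Optional[tuple[float, ...]] = None
    metabolite_weights: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", tuple(self.reactions))
        if len(self.reactions) < 1:
            raise DomainError("a pathway needs at least one reaction")
        if not (self.eps_tot > 0):
            raise DomainError("eps_tot must be strictly positive")
        for name in ("s0", "sn", "s_tot"):
            value = getattr(self, name)
            if value is not None and not (value > 0):
                raise DomainError(f"{name} must be strictly positive when given")
        if self.enzyme_weights is not None:
            w = tuple(float(x) for x in self.enzyme_weights)
            if len(w) != self.n or any(x <= 0 for x in w):
                raise DomainError("enzyme_weights must be n positive numbers")
            object.__setattr__(self, "enzyme_weights", w)
        if self.metabolite_weights is not None:
            b = tuple(float(x) for x in self.metabolite_weights)
            if len(b) != self.n + 1 or any(x <= 0 for x in b):
                raise DomainError("metabolite_weights must be n+1 positive numbers")
            object.__setattr__(self, "metabolite_weights", b)

    @property
    def n(self) -> int:
        return len(self.reactions)

    @property
    def weights(self) -> np.ndarray:
        if self.enzyme_weights is None:
            return np.ones(self.n)
        return np.asarray(self.enzyme_weights, dtype=float)

    @property
    def alphas(self) -> np.ndarray:
        """alpha_i = 1/kcat_i, the minimal enzymatic turnover times."""
        return np.array([1.0 / r.kcat_fwd for r in self.reactions])

    @property
    def betas(self) -> np.ndarray:
        """beta_i = K_M,i / kcat_i (the MM K_M is identified with K_S)."""
        out = []
        for r in self.reactions:
            if r.K_S is None:
                raise MissingKineticsError("beta requires K_S for every reaction")
            out.append(r.K_S / r.kcat_fwd)
        return np.array(out)

    @property
    def K_eqs(self) -> np.ndarray:
        out = []
        for r in self.reactions:
            if r.K_eq is None:
                raise MissingKineticsError("K_eq missing for a reaction")
            out.append(r.K_eq)
        return np.array(out)

    @property
    def K_eq_tot(self) -> float:
        return float(np.prod(self.K_eqs))

    @property
    def gammas(self) -> np.ndarray:
        """gamma_i = beta_i * prod_{j=i..n} K_eq_j (mass-action cost factors)."""
        keq = self.K_eqs
        tail = np.cumprod(keq[::-1])[::-1]  # tail[i] = prod_{j>=i} Keq_j
        return self.betas * tail

    @property
    def theta_tot(self) -> float:
        """Overall driving force ln(s0 * K_eq_tot / sn); needs fixed boundaries."""
        if self.s0 is None or self.sn is None:
            raise DomainError("theta_tot requires fixed boundary concentrations")
        return math.log(self.s0 * self.K_eq_tot / self.sn)

    def check_driving_force(self) -> None:
        if self.s0 is None or self.sn is None:
            raise InfeasibleError("boundary concentrations s0 and sn must be fixed")
        if self.s0 * self.K_eq_tot <= self.sn:
            raise InfeasibleError(
                "non-positive overall driving force: s0*K_eq_tot = "
                f"{self.s0 * self.K_eq_tot:g} <= sn = {self.sn:g}"
            )

    def with_(self, **kwargs) -> "PathwaySpec":
        return replace(self, **kwargs)


def driving_force(s_sub: float, s_prod: float, K_eq: float) -> float:
    """theta = ln(K_eq * s / p), the dimensionless driving force (-dG/RT)."""
    if not (s_sub > 0 and s_prod > 0 and K_eq > 0):
        raise DomainError("driving_force requires strictly positive arguments")
    return math.log(K_eq * s_sub / s_prod)


def efficiencies(
    s_sub: float, s_prod: float, kin: ReactionKinetics
) -> tuple[float, float]:
    """Thermodynamic and saturation efficiency factors (eta_for, eta_sat).

    ``s_prod = 0`` maps to theta -> +inf and eta_for = 1 (irreversible
    limit).  A missing K_P is treated as K_P -> inf.
    """
    if s_sub < 0 or s_prod < 0:
        raise DomainError("concentrations must be non-negative")
    kin.require(RateLawKind.MICHAELIS_MENTEN)
    if s_prod == 0:
        eta_for = 1.0
    else:
        if kin.K_eq is None:
            raise MissingKineticsError("eta_for requires K_eq")
        if s_sub == 0:
            eta_for = -math.inf
        else:
            eta_for = -math.expm1(-driving_force(s_sub, s_prod, kin.K_eq))
    kp = kin.K_P if kin.K_P is not None else math.inf
    denom = 1.0 + s_sub / kin.K_S + s_prod / kp
    eta_sat = (s_sub / kin.K_S) / denom
    return eta_for, eta_sat


def rate_per_enzyme(
    kind: RateLawKind, kin: ReactionKinetics, s_sub: float, s_prod: float
) -> float:
    """Net rate per unit enzyme, v/eps, for the given law (may be <= 0)."""
    kin.require(kind)
    k = kin.kcat_fwd
    if kind is RateLawKind.TRIVIAL:
        return k
    if kind is RateLawKind.MICHAELIS_MENTEN:
        return k * s_sub / (s_sub + kin.K_S)
    if kind is RateLawKind.THERMODYNAMIC:
        if s_sub <= 0:
            raise DomainError("thermodynamic rate law requires s_sub > 0")
        return k * (1.0 - s_prod / (s_sub * kin.K_eq))
    if kind is RateLawKind.MASS_ACTION:
        return (k / kin.K_S) * (s_sub - s_prod / kin.K_eq)
    # Haldane, in the numerically robust direct form (well-defined at p = 0)
    krev = kin.kcat_rev_implied
    num = k * s_sub / kin.K_S - krev * s_prod / kin.K_P
    den = 1.0 + s_sub / kin.K_S + s_prod / kin.K_P
    return num / den


def rate_gradient(
    kind: RateLawKind, kin: ReactionKinetics, s_sub: float, s_prod: float
) -> tuple[float, float]:
    """Analytic partials (d(v/eps)/ds, d(v/eps)/dp) of the rate per enzyme.

    Multiplying by the enzyme level gives the unscaled elasticities.
    """
    kin.require(kind)
    k = kin.kcat_fwd
    if kind is RateLawKind.TRIVIAL:
        return 0.0, 0.0
    if kind is RateLawKind.MICHAELIS_MENTEN:
        return k * kin.K_S / (s_sub + kin.K_S) ** 2, 0.0
    if kind is RateLawKind.THERMODYNAMIC:
        return (
            k * s_prod / (kin.K_eq * s_sub**2),
            -k / (kin.K_eq * s_sub),
        )
    if kind is RateLawKind.MASS_ACTION:
        return k / kin.K_S, -k / (kin.K_S * kin.K_eq)
    krev = kin.kcat_rev_implied
    num = k * s_sub / kin.K_S - krev * s_prod / kin.K_P
    den = 1.0 + s_sub / kin.K_S + s_prod / kin.K_P
    d_ds = (k / kin.K_S * den - num / kin.K_S) / den**2
    d_dp = (-krev / kin.K_P * den - num / kin.K_P) / den**2
    return d_ds, d_dp


def evaluate_rate(
    kind: RateLawKind,
    kin: ReactionKinetics,
    eps: float,
    s_sub: float,
    s_prod: float,
) -> float:
    """Reaction flux v = eps * (rate per enzyme); exactly linear in eps."""
    if eps < 0:
        raise DomainError("enzyme level must be non-negative")
    return eps * rate_per_enzyme(kind, kin, s_sub, s_prod)


def enzyme_demand(
    kind: RateLawKind,
    kin: ReactionKinetics,
    v: float,
    s_sub: float,
    s_prod: float,
) -> float:
    """Enzyme level needed to carry flux v at the given concentrations.

    Inverse of :func:`evaluate_rate` in eps; raises if the net rate per
    enzyme is non-positive (theta <= 0 for reversible laws).
    """
    if not (v > 0):
        raise DomainError("enzyme_demand requires v > 0")
    r = rate_per_enzyme(kind, kin, s_sub, s_prod)
    if r <= 0:
        raise InfeasibleError(
            f"non-positive rate per unit enzyme ({r:g}) at s={s_sub:g}, p={s_prod:g}: "
            "the requested flux direction is thermodynamically infeasible here"
        )
    return v / r


# ---------------------------------------------------------------------------
# Convenience-kinetics reduction to effective uni-uni constants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvenienceKinetics:
    """Convenience kinetics for A + B <-> P + Q (random-order, independent
    binding):

        v = eps * (kcat+ (a/K_A)(b/K_B) - kcat- (p/K_P)(q/K_Q))
            / ((1 + a/K_A)(1 + b/K_B) + (1 + p/K_P)(1 + q/K_Q) - 1)

    The overall equilibrium constant follows from the generalized Haldane
    relationship K_eq = (kcat+/kcat-) * K_P K_Q / (K_A K_B).
    """

    kcat_fwd: float
    kcat_rev: float
    K_A: float
    K_B: float
    K_P: float
    K_Q: float

    def __post_init__(self) -> None:
        for f in ("kcat_fwd", "kcat_rev", "K_A", "K_B", "K_P", "K_Q"):
            if not (getattr(self, f) > 0):
                raise DomainError(f"{f} must be strictly positive")

    @property
    def K_eq(self) -> float:
        return (self.kcat_fwd / self.kcat_rev) * (self.K_P * self.K_Q) / (
            self.K_A * self.K_B
        )


def convenience_rate(
    ck: ConvenienceKinetics, eps: float, a: float, b: float, p: float, q: float
) -> float:
    """Evaluate the full bi-bi convenience-kinetics rate."""
    num = ck.kcat_fwd * (a / ck.K_A) * (b / ck.K_B) - ck.kcat_rev * (p / ck.K_P) * (
        q / ck.K_Q
    )
    den = (1 + a / ck.K_A) * (1 + b / ck.K_B) + (1 + p / ck.K_P) * (1 + q / ck.K_Q) - 1
    return eps * num / den


def effective_uniuni_params(
    ck: ConvenienceKinetics, b: float, q: float
) -> ReactionKinetics:
    """Reduce a bi-bi convenience-kinetics reaction to effective uni-uni
    Haldane constants, treating co-substrate ``b`` and co-product ``q`` as
    fixed.

    The reduced law reproduces the full rate for *all* values of the free
    substrate s (= a) and product p.  With c0 = 1 + b/K_B + q/K_Q:

        kcat_fwd' = kcat_fwd * (b/K_B) / (1 + b/K_B)
        kcat_rev' = kcat_rev * (q/K_Q) / (1 + q/K_Q)
        K_S'      = K_A * c0 / (1 + b/K_B)
        K_P'      = K_P * c0 / (1 + q/K_Q)

    and K_eq' = (kcat_fwd'/kcat_rev')(K_P'/K_S') = K_eq * b/q, consistent
    with the mass balance of the fixed co-reactants.
    """
    if not (b > 0 and q > 0):
        raise DomainError("fixed co-reactant concentrations must be positive")
    rb = b / ck.K_B
    rq = q / ck.K_Q
    c0 = 1.0 + rb + rq
    kf = ck.kcat_fwd * rb / (1.0 + rb)
    kr = ck.kcat_rev * rq / (1.0 + rq)
    ks = ck.K_A * c0 / (1.0 + rb)
    kp = ck.K_P * c0 / (1.0 + rq)
    keq = (kf / kr) * (kp / ks)
    return ReactionKinetics(kcat_fwd=kf, kcat_rev=kr, K_S=ks, K_P=kp, K_eq=keq)
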
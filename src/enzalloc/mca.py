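"""Metabolic control analysis for unbranched pathways.

Conventions follow the unscaled formalism: elasticities are
E_{j,i} = dv_j/ds_i, and control coefficients are reported in the
reaction-scaled form C^J_l = (dJ/deps_l) * eps_l / J (dimensionless, summing
to 1) and C^{s_i}_l = (ds_i/deps_l) * eps_l / J (concentration per flux,
summing to 0 over l).  For a chain of n reactions with internal metabolites
s_1..s_{n-1}, stoichiometric matrix N and internal elasticity matrix E,

    C^s = -(N E)^{-1} N          (concentration control)
    C^J = E C^s + I              (flux control; all rows identical)

which satisfies the summation and connectivity theorems by construction up
to the conditioning of N E.

At flux-maximal states under a plain enzyme budget, two optimality rules
hold: the enzyme-control rule eps*_l = eps_tot * C^J_l, and the
enzyme-elasticity rule sum_j eps_j E_{j,i} = 0 around every internal
metabolite.  With a joint density constraint a*sum(eps) + b*sum(s) <= rho
the generalized rule eps*_l = eps_tot* C^J_l - J*(b/a) sum_i C^{s_i}_l
applies instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .allocate import OptimalState
from .errors import ControlUndefinedError, DomainError, NumericalError, RuleScopeError
from .numopt import steady_state
from .ratelaws import PathwaySpec, RateLawKind, rate_gradient

__all__ = [
    "ControlProfile",
    "elasticities",
    "control_coefficients",
    "finite_difference_control",
    "control_mass_action_analytic",
    "control_thermodynamic_analytic",
    "enzyme_control_rule",
    "generalized_enzyme_control_rule",
    "enzyme_elasticity_rule",
]


@dataclass
class ControlProfile:
    """Elasticities, control coefficients and theorem residuals at a steady state."""

    elasticities: np.ndarray  # (n, n+1): dv_j/ds_i over all metabolites
    flux_control: np.ndarray  # (n,): C^J, sums to 1
    conc_control: np.ndarray  # (n-1, n): C^{s_i}_l, rows sum to 0 over l
    summation_residual: float
    connectivity_residuals: np.ndarray  # (n-1,)
    J: float
    s: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def elasticities(
    pw: PathwaySpec, kind: RateLawKind, eps: Sequence[float], s: Sequence[float]
) -> np.ndarray:
    """Unscaled elasticity matrix E[j, i] = dv_{j+1}/ds_i (n x (n+1)).

    The chain structure makes it bidiagonal: reaction j responds only to
    its substrate s_{j-1} and (for reversible laws) its product s_j.
    """
    eps = np.asarray(eps, dtype=float)
    s = np.asarray(s, dtype=float)
    n = pw.n
    E = np.zeros((n, n + 1))
    for j, kin in enumerate(pw.reactions):
        p = s[j + 1]
        if kind in (RateLawKind.MICHAELIS_MENTEN, RateLawKind.TRIVIAL):
            p = 0.0
        if kind is RateLawKind.TRIVIAL:
            continue
        d_ds, d_dp = rate_gradient(kind, kin, s[j], p)
        E[j, j] = eps[j] * d_ds
        if kind.reversible:
            E[j, j + 1] = eps[j] * d_dp
    return E


def _incidence(n: int) -> np.ndarray:
    """Stoichiometric matrix of the internal metabolites: N[i-1, j]."""
    N = np.zeros((n - 1, n))
    for i in range(1, n):
        N[i - 1, i - 1] = 1.0
        N[i - 1, i] = -1.0
    return N


def control_coefficients(
    pw: PathwaySpec, kind: RateLawKind, eps: Sequence[float]
) -> ControlProfile:
    """Control coefficients at the steady state of the given enzyme profile.

    Computed from the stoichiometric and elasticity matrices; the summation
    and connectivity theorem residuals are evaluated and reported.  Raises
    :class:`ControlUndefinedError` where control is not defined (trivial
    law, or the saturated Michaelis-Menten limit with free s0, where any
    enzyme variation breaks the steady state).
    """
    if kind is RateLawKind.TRIVIAL:
        raise ControlUndefinedError(
            "the trivial rate law has zero elasticities: any enzyme variation "
            "breaks the steady state and control coefficients are not defined"
        )
    if kind is RateLawKind.MICHAELIS_MENTEN and pw.s0 is None:
        raise ControlUndefinedError(
            "control coefficients are not defined for the Michaelis-Menten "
            "chain without a fixed upstream concentration (the saturated "
            "optimum is a singular limit)"
        )
    eps = np.asarray(eps, dtype=float)
    n = pw.n
    J, s = steady_state(pw, kind, eps)
    E_full = elasticities(pw, kind, eps, s)

    if n == 1:
        C_J = np.array([1.0])
        C_s = np.zeros((0, 1))
    else:
        E_int = E_full[:, 1:n]  # (n, n-1)
        N = _incidence(n)
        M = N @ E_int
        try:
            C_s = -np.linalg.solve(M, N)
        except np.linalg.LinAlgError as exc:
            raise ControlUndefinedError(f"singular N*E matrix: {exc}") from exc
        C_J_mat = E_int @ C_s + np.eye(n)
        C_J = C_J_mat.mean(axis=0)
        row_spread = float(np.max(np.abs(C_J_mat - C_J)))
        if row_spread > 1e-6:
            raise NumericalError(
                f"flux control rows disagree by {row_spread:g}; state is not "
                "a consistent steady state"
            )

    summation = float(abs(np.sum(C_J) - 1.0))
    if n > 1:
        connectivity = np.abs(C_J @ E_full[:, 1:n])
    else:
        connectivity = np.empty(0)
    return ControlProfile(
        elasticities=E_full,
        flux_control=C_J,
        conc_control=C_s,
        summation_residual=summation,
        connectivity_residuals=connectivity,
        J=J,
        s=s,
        diagnostics={"eps": eps.copy()},
    )


def finite_difference_control(
    pw: PathwaySpec, kind: RateLawKind, eps: Sequence[float], rel_step: float = 1e-6
) -> np.ndarray:
    """Flux control coefficients from central-difference perturbation of
    steady_state, with one Richardson extrapolation step.  Independent
    cross-check for :func:`control_coefficients`."""
    eps = np.asarray(eps, dtype=float)
    J0, _ = steady_state(pw, kind, eps)

    def deriv(l: int, h: float) -> float:
        up, dn = eps.copy(), eps.copy()
        up[l] += h
        dn[l] -= h
        Ju, _ = steady_state(pw, kind, up)
        Jd, _ = steady_state(pw, kind, dn)
        return (Ju - Jd) / (2 * h)

    C = np.empty(len(eps))
    for l in range(len(eps)):
        h = rel_step * eps[l]
        d1 = deriv(l, h)
        d2 = deriv(l, h / 2)
        C[l] = (4 * d2 - d1) / 3 * eps[l] / J0
    return C


def control_mass_action_analytic(pw: PathwaySpec, eps: Sequence[float]) -> np.ndarray:
    """C^J_l = (gamma_l/eps_l) / sum_j (gamma_j/eps_j) for the mass-action chain."""
    pw.check_driving_force()
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise DomainError("eps must be strictly positive")
    g = pw.gammas / eps
    return g / g.sum()


def control_thermodynamic_analytic(pw: PathwaySpec, eps: Sequence[float]) -> np.ndarray:
    """C^J_l ~ 1/(eps_l kcat_l - J) for the thermodynamic chain, with J from
    the implicit product relation; normalized to sum 1."""
    eps = np.asarray(eps, dtype=float)
    J, _ = steady_state(pw, RateLawKind.THERMODYNAMIC, eps)
    cap = eps * np.array([r.kcat_fwd for r in pw.reactions])
    if np.any(cap <= J):
        raise NumericalError(
            "eps_l*kcat_l <= J: inconsistent with a genuine steady state"
        )
    g = 1.0 / (cap - J)
    return g / g.sum()


# ---------------------------------------------------------------------------
# Optimality rules
# ---------------------------------------------------------------------------


def _check_plain_scope(state: OptimalState) -> None:
    if state.diagnostics.get("metabolite_bound_active"):
        raise RuleScopeError(
            "the plain enzyme-control/elasticity rules hold only under the "
            "bare enzyme budget; this optimum has an active metabolite bound "
            "- use generalized_enzyme_control_rule"
        )


def enzyme_control_rule(
    state: OptimalState, profile: ControlProfile
) -> tuple[float, np.ndarray]:
    """Check eps*_l = eps_tot * C^J_l at a flux-maximal state.

    Returns (max relative residual, predicted enzyme profile).  Away from
    the optimum the residual is large: the rule discriminates optimal from
    perturbed profiles.
    """
    _check_plain_scope(state)
    eps = state.eps_star
    eps_tot = float(np.sum(eps))
    pred = eps_tot * profile.flux_control
    residual = float(np.max(np.abs(pred - eps) / np.max(eps)))
    return residual, pred


def generalized_enzyme_control_rule(
    state: OptimalState, profile: ControlProfile, a: float, b: float
) -> float:
    """Check eps*_l = eps_tot* C^J_l - J*(b/a) sum_i C^{s_i}_l at an optimum
    under the joint density constraint a*sum(eps) + b*sum(s) <= rho.

    With b = 0 this reduces to the plain enzyme-control rule.
    """
    if profile.conc_control.size == 0 and state.n > 1:
        raise RuleScopeError("concentration control coefficients unavailable")
    eps = state.eps_star
    eps_tot = float(np.sum(eps))
    conc_sum = profile.conc_control.sum(axis=0) if state.n > 1 else np.zeros(1)
    pred = eps_tot * profile.flux_control - state.J_star * (b / a) * conc_sum
    return float(np.max(np.abs(pred - eps) / np.max(eps)))


def enzyme_elasticity_rule(state: OptimalState, E: np.ndarray) -> np.ndarray:
    """Per-internal-metabolite residuals of sum_j eps_j E_{j,i} = 0.

    Residuals are normalized by sum_j eps_j |E_{j,i}|; equivalently the
    ratio of enzyme levels around metabolite i equals the absolute inverse
    ratio of its elasticities.
    """
    _check_plain_scope(state)
    eps = state.eps_star
    n = state.n
    res = np.empty(max(n - 1, 0))
    for i in range(1, n):
        num = abs(float(eps @ E[:, i]))
        den = float(np.abs(eps) @ np.abs(E[:, i]))
        res[i - 1] = num / den if den > 0 else math.inf
    return res
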
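"""A coarse-grained three-sector cell: transport -> metabolism -> translation.

The growing cell is modelled as an unbranched chain of three lumped
Michaelis-Menten reactions catalysed by the transporter, metabolic and
ribosomal protein sectors, with the external nutrient s_sugar as a fixed
upstream boundary.  Maximizing the steady-state flux (the growth rate mu)
under the protein budget eps_tot and internal metabolite bound s_tot yields
a Monod growth law

    mu = mu_max * s_sugar / (s_sugar + K_Monod),

with, writing D = 1/kcat_t + 1/kcat_m + 1/kcat_r
                 + (sqrt(K_Mm/kcat_m) + sqrt(K_Mr/kcat_r))^2 / s_tot,

    mu_max = eps_tot / D        and        K_Monod = (K_Mt/kcat_t) / D.

mu_max and K_Monod are proportional (ratio eps_tot * kcat_t / K_Mt), so
most kinetic parameters trade off growth rate against nutrient affinity;
only eps_tot (mu_max alone), K_Mt (K_Monod alone), and kcat_t (both,
beneficially) escape the trade-off.

Because transport is irreversible, the cytoplasm is informationally
buffered from the environment: the optimal internal metabolite levels are
independent of s_sugar, and the metabolic and ribosomal sectors grow
linearly through the origin with the flux while the transporter takes the
remainder of the budget.

A thermodynamic variant (saturated but reversible chain) gives
mu = mu_max * (1 - (A/s_sugar)^B) with A = sn/K_eq_tot and
B = ||alpha||_1/||alpha||_1/2; the mass-action variant is exactly linear in
s_sugar and admits no Monod parameters at all.

Growth dilution of intermediates is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allocate import norm_half, norm_l1, solve_michaelis_menten
from .errors import DomainError, InfeasibleError
from .ratelaws import PathwaySpec, RateLawKind, ReactionKinetics

__all__ = [
    "CellModelSpec",
    "GrowthLaw",
    "monod_parameters",
    "growth_rate",
    "sector_allocation",
    "thermo_growth_parameters",
    "thermo_growth_rate",
    "parameter_sweep",
    "classify_parameter",
]

_SWEEPABLE = (
    "kcat_t", "kcat_m", "kcat_r", "K_Mt", "K_Mm", "K_Mr",
    "eps_tot", "s_tot", "s_sugar",
)


@dataclass(frozen=True)
class CellModelSpec:
    """Kinetics and budgets of the three-step cell.

    s_sugar is the external nutrient concentration: a fixed environmental
    parameter, excluded from the internal osmotic budget s_tot.
    """

    kcat_t: float = 1.0
    kcat_m: float = 1.0
    kcat_r: float = 1.0
    K_Mt: float = 1.0
    K_Mm: float = 2.0
    K_Mr: float = 1.0
    eps_tot: float = 1.0
    s_tot: float = 1.0
    s_sugar: float = 1.0

    def __post_init__(self) -> None:
        for name in _SWEEPABLE:
            if not (getattr(self, name) > 0):
                raise DomainError(f"{name} must be strictly positive")

    def to_pathway(self, s_sugar: Optional[float] = None) -> PathwaySpec:
        """The equivalent 3-reaction Michaelis-Menten pathway with fixed s0."""
        s0 = self.s_sugar if s_sugar is None else s_sugar
        return PathwaySpec(
            reactions=(
                ReactionKinetics(kcat_fwd=self.kcat_t, K_S=self.K_Mt),
                ReactionKinetics(kcat_fwd=self.kcat_m, K_S=self.K_Mm),
                ReactionKinetics(kcat_fwd=self.kcat_r, K_S=self.K_Mr),
            ),
            s0=s0,
            eps_tot=self.eps_tot,
            s_tot=self.s_tot,
        )

    @property
    def alphas(self) -> np.ndarray:
        return np.array([1 / self.kcat_t, 1 / self.kcat_m, 1 / self.kcat_r])

    @property
    def cyto_betas(self) -> np.ndarray:
        """beta of the two cytoplasmic steps (metabolism, translation)."""
        return np.array([self.K_Mm / self.kcat_m, self.K_Mr / self.kcat_r])


@dataclass(frozen=True)
class GrowthLaw:
    """Derived growth-law parameters.

    ``monod``: mu = mu_max * s/(s + K_Monod).
    ``thermodynamic``: mu = mu_max * (1 - (A/s)^B) with 0 < B <= 1.
    The mass-action chain is exactly linear in the nutrient concentration,
    so constructing a mass-action GrowthLaw is refused.
    """

    mu_max: float
    law_kind: str
    K_Monod: Optional[float] = None
    A: Optional[float] = None
    B: Optional[float] = None

    def __post_init__(self) -> None:
        if self.law_kind == "mass_action":
            raise DomainError(
                "the mass-action growth curve is linear in s_sugar: "
                "mu_max and K_Monod do not exist for this law"
            )
        if self.law_kind not in ("monod", "thermodynamic"):
            raise DomainError(f"unknown growth law kind {self.law_kind!r}")
        if not (self.mu_max > 0):
            raise DomainError("mu_max must be positive")
        if self.law_kind == "monod" and not (self.K_Monod and self.K_Monod > 0):
            raise DomainError("monod law requires K_Monod > 0")
        if self.law_kind == "thermodynamic":
            if self.A is None or self.B is None or not (0 < self.B <= 1):
                raise DomainError("thermodynamic law requires A > 0 and 0 < B <= 1")


def _denominator(cm: CellModelSpec) -> float:
    root = float(np.sum(np.sqrt(cm.cyto_betas)))
    return float(np.sum(cm.alphas)) + root**2 / cm.s_tot


def monod_parameters(cm: CellModelSpec) -> GrowthLaw:
    """Monod parameters of the optimally allocated three-step cell."""
    D = _denominator(cm)
    return GrowthLaw(
        mu_max=cm.eps_tot / D,
        K_Monod=(cm.K_Mt / cm.kcat_t) / D,
        law_kind="monod",
    )


def growth_rate(
    cm: CellModelSpec, law: Optional[GrowthLaw] = None, s_sugar: Optional[float] = None
) -> float:
    """mu at the given nutrient level (Monod hyperbola).

    Identical, by construction, to the fixed-s0 Michaelis-Menten allocation
    optimum of the 3-step pathway at s0 = s_sugar.
    """
    law = law or monod_parameters(cm)
    s = cm.s_sugar if s_sugar is None else s_sugar
    if s < 0:
        raise DomainError("s_sugar must be non-negative")
    return law.mu_max * s / (s + law.K_Monod)


def sector_allocation(cm: CellModelSpec, mu: float) -> tuple[float, float, float]:
    """Optimal protein sectors (eps_t, eps_m, eps_r) at growth rate mu.

    The cytoplasmic sectors are straight lines through the origin: their
    slopes are the optimal enzyme demands per unit flux, which do not
    depend on s_sugar because the irreversible transporter buffers the
    cytoplasm.  The transporter takes the remaining budget, reaching its
    saturated minimum mu/kcat_t at mu = mu_max.
    """
    law = monod_parameters(cm)
    if mu < 0 or mu > law.mu_max * (1 + 1e-12):
        raise InfeasibleError(
            f"growth rate {mu:g} exceeds mu_max = {law.mu_max:g}"
        )
    betas = cm.cyto_betas
    root_sum = float(np.sum(np.sqrt(betas)))
    d_m = 1 / cm.kcat_m + math.sqrt(betas[0]) * root_sum / cm.s_tot
    d_r = 1 / cm.kcat_r + math.sqrt(betas[1]) * root_sum / cm.s_tot
    eps_m = mu * d_m
    eps_r = mu * d_r
    eps_t = cm.eps_tot - eps_m - eps_r
    return eps_t, eps_m, eps_r


def thermo_growth_parameters(
    kcats: Sequence[float], K_eq_tot: float, sn: float, eps_tot: float
) -> GrowthLaw:
    """Growth law of a saturated reversible (thermodynamic) chain:
    mu = mu_max*(1 - (A/s_sugar)^B), mu_max = eps_tot/||alpha||_1,
    A = sn/K_eq_tot, B = ||alpha||_1/||alpha||_1/2 (equal kcats give B = 1/n)."""
    kcats = np.asarray(kcats, dtype=float)
    if np.any(kcats <= 0) or K_eq_tot <= 0 or sn <= 0 or eps_tot <= 0:
        raise DomainError("all parameters must be strictly positive")
    alpha = 1.0 / kcats
    return GrowthLaw(
        mu_max=eps_tot / norm_l1(alpha),
        law_kind="thermodynamic",
        A=sn / K_eq_tot,
        B=norm_l1(alpha) / norm_half(alpha),
    )


def thermo_growth_rate(law: GrowthLaw, s_sugar: float) -> float:
    """mu(s_sugar) under the thermodynamic growth law; infeasible at s <= A
    (product accumulation drives the chain to equilibrium)."""
    if law.law_kind != "thermodynamic":
        raise DomainError("law must be a thermodynamic growth law")
    if s_sugar <= law.A:
        raise InfeasibleError(
            f"s_sugar = {s_sugar:g} <= A = {law.A:g}: growth infeasible "
            "(no positive overall driving force)"
        )
    return law.mu_max * (1.0 - (law.A / s_sugar) ** law.B)


def classify_parameter(name: str) -> str:
    """How a parameter moves (mu_max, K_Monod): the three exceptions to the
    general trade-off are eps_tot, K_Mt, and kcat_t."""
    if name == "eps_tot":
        return "mu_max_only"
    if name == "K_Mt":
        return "K_Monod_only"
    if name == "kcat_t":
        return "both_beneficial"
    if name == "s_sugar":
        return "environment"
    if name in _SWEEPABLE:
        return "tradeoff"
    raise DomainError(f"unknown cell-model parameter {name!r}")


def parameter_sweep(
    cm: CellModelSpec, parameter: str, grid: Sequence[float]
) -> pd.DataFrame:
    """Sweep one parameter over a grid (typically logarithmic) and tabulate
    (mu_max, K_Monod, mu at the spec's s_sugar) with its classification."""
    if parameter not in _SWEEPABLE:
        raise DomainError(f"unknown cell-model parameter {parameter!r}")
    rows = []
    for value in grid:
        spec = CellModelSpec(**{**cm.__dict__, parameter: float(value)})
        law = monod_parameters(spec)
        rows.append({
            "parameter": parameter,
            "value": float(value),
            "mu_max": law.mu_max,
            "K_Monod": law.K_Monod,
            "mu": growth_rate(spec, law),
        })
    df = pd.DataFrame(rows)
    df.attrs["classification"] = classify_parameter(parameter)
    return df
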
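"""Closed-form optimal enzyme allocation for the solvable rate laws.

For an unbranched pathway at steady state, maximizing the flux J under the
budget sum_i w_i eps_i <= eps_tot is equivalent to minimizing the total
enzyme demand per unit flux, sum_i w_i d_i(s), over the free metabolite
concentrations, where d_i = 1/(rate per unit enzyme of reaction i).  Then

    J* = eps_tot / sum_i w_i d_i(s*)    and    eps*_i = J* d_i(s*).

This module implements the cases where the inner minimization has a closed
form (using the shorthand alpha_i = 1/kcat_i, beta_i = K_M,i/kcat_i,
gamma_i = beta_i * prod_{j>=i} K_eq_j, and the norms ||x||_1 = sum x_i,
||x||_1/2 = (sum sqrt(x_i))^2):

* trivial:          d_i = alpha_i, so J* = eps_tot/||alpha||_1.
* Michaelis-Menten: under sum of free metabolites <= s_tot, the optimal
  substrate levels satisfy s*_{i-1} ~ sqrt(beta_i) and
  d_i = alpha_i + sqrt(beta_i) * (sum_j sqrt(beta_j)) / s_tot.
* thermodynamic:    the overall force theta_tot is split by a Lagrange
  parameter Psi with theta*_i = 2*asinh(sqrt(Psi*alpha_i)), where Psi solves
  theta_tot = 2 * sum_i ln(sqrt(Psi alpha_i) + sqrt(1 + Psi alpha_i)).
* mass-action:      eps*_i ~ sqrt(gamma_i) and
  J* = eps_tot * (s0 K_eq_tot - sn) / ||gamma||_1/2.

Weighted enzyme budgets are absorbed by the effective turnover numbers
kcat_i/w_i: the inner minimization runs on the weighted demands w_i d_i and
the reported enzyme levels are the unweighted d_i * J*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, InfeasibleError, NumericalError, UnboundedMetaboliteError
from .ratelaws import PathwaySpec, RateLawKind, enzyme_demand

__all__ = [
    "OptimalState",
    "NormCache",
    "norm_l1",
    "norm_half",
    "solve_trivial",
    "solve_michaelis_menten",
    "psi_from_theta_tot",
    "solve_thermodynamic",
    "approx_thermodynamic_flux",
    "solve_mass_action",
    "pathway_specific_activity",
]


def norm_l1(x) -> float:
    """||x||_1 = sum_i x_i (for positive vectors)."""
    return float(np.sum(x))


def norm_half(x) -> float:
    """||x||_1/2 = (sum_i sqrt(x_i))^2; >= ||x||_1, equality iff one nonzero."""
    return float(np.sum(np.sqrt(x)) ** 2)


@dataclass(frozen=True)
class NormCache:
    """The alpha/beta/gamma cost vectors of a pathway, precomputed."""

    alpha: np.ndarray
    beta: Optional[np.ndarray] = None
    gamma: Optional[np.ndarray] = None

    @classmethod
    def from_pathway(cls, pw: PathwaySpec, need_beta=False, need_gamma=False):
        return cls(
            alpha=pw.alphas,
            beta=pw.betas if need_beta else None,
            gamma=pw.gammas if need_gamma else None,
        )


@dataclass
class OptimalState:
    """Output of an allocation solver.

    Attributes
    ----------
    eps_star
        Optimal enzyme levels (length n); sums (weighted) to eps_tot.
    s_star
        Metabolite concentrations s_0..s_n (length n+1); NaN where the rate
        law does not constrain a metabolite.
    free_metabolites
        Boolean mask (length n+1): True where the concentration was a free
        optimization variable.
    theta_star
        Per-reaction driving forces; NaN for irreversible laws.
    J_star
        Maximal steady-state pathway flux.
    rate_law
        The rate-law kind solved.
    diagnostics
        Solver metadata (Psi, residuals, iterations, active constraints).
    """

    eps_star: np.ndarray
    s_star: np.ndarray
    free_metabolites: np.ndarray
    theta_star: np.ndarray
    J_star: float
    rate_law: RateLawKind
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.eps_star)


def _finalize(pw: PathwaySpec, kind: RateLawKind, demands: np.ndarray,
              s_star: np.ndarray, free: np.ndarray, theta: np.ndarray,
              diagnostics: dict) -> OptimalState:
    w = pw.weights
    total = float(np.dot(w, demands))
    J = pw.eps_tot / total
    eps = J * demands
    diagnostics.setdefault("weighted_demand_per_flux", total)
    return OptimalState(
        eps_star=eps,
        s_star=s_star,
        free_metabolites=free,
        theta_star=theta,
        J_star=J,
        rate_law=kind,
        diagnostics=diagnostics,
    )


def solve_trivial(pw: PathwaySpec) -> OptimalState:
    """Saturated irreversible chain: eps*_i ~ alpha_i, J* = eps_tot/||alpha||_1.

    Pathway turnover times tau_i = 1/kcat_i are additive: eps_tot/J* = sum tau_i.
    """
    n = pw.n
    demands = pw.alphas.copy()
    s = np.full(n + 1, np.nan)
    if pw.s0 is not None:
        s[0] = pw.s0
    if pw.sn is not None:
        s[-1] = pw.sn
    free = np.zeros(n + 1, dtype=bool)
    return _finalize(pw, RateLawKind.TRIVIAL, demands, s,
                     free, np.full(n, np.nan), {})


def solve_michaelis_menten(pw: PathwaySpec, *, unbounded: str = "raise") -> OptimalState:
    """Irreversible saturable chain under the metabolite bound sum s_i <= s_tot.

    Without the bound the optimum is the unphysical limit s_i -> infinity
    (all enzymes saturated); by default this raises
    :class:`UnboundedMetaboliteError`.  Pass ``unbounded="limit"`` to obtain
    the saturated limit (the trivial-law solution) flagged in the
    diagnostics as a limit rather than an attainable state.

    With a fixed upstream boundary s0, reaction 1 contributes the fixed
    demand alpha_1 + beta_1/s0 and only the downstream substrates enter the
    square-root allocation.
    """
    n = pw.n
    alpha = pw.alphas
    beta = pw.betas
    w = pw.weights
    wbeta = w * beta

    s0_fixed = pw.s0 is not None
    # substrates of reactions: s_0..s_{n-1}; free ones are optimized
    free_mets = list(range(0 if not s0_fixed else 1, n))
    if pw.s_tot is None and free_mets:
        if unbounded == "limit":
            state = solve_trivial(pw)
            state.rate_law = RateLawKind.MICHAELIS_MENTEN
            state.diagnostics["limit"] = "s_tot -> inf (saturated); not an attainable state"
            return state
        raise UnboundedMetaboliteError(
            "Michaelis-Menten allocation without a metabolite bound has no "
            "optimum: the objective improves indefinitely as s_i -> inf. "
            "Provide s_tot, or request the saturated limit explicitly."
        )

    s = np.full(n + 1, np.nan)
    if s0_fixed:
        s[0] = pw.s0
    if pw.sn is not None:
        s[-1] = pw.sn

    demands = alpha.copy()
    if s0_fixed:
        demands[0] = alpha[0] + beta[0] / pw.s0
    if free_mets:
        # reaction j (0-based) consumes metabolite j, so free substrate m
        # belongs to reaction m
        root_sum = float(np.sum(np.sqrt(wbeta[free_mets])))
        for m in free_mets:
            s[m] = pw.s_tot * math.sqrt(wbeta[m]) / root_sum
            demands[m] = alpha[m] + beta[m] / s[m]
    free = np.zeros(n + 1, dtype=bool)
    free[free_mets] = True
    diag = {"metabolite_bound_active": bool(free_mets)}
    return _finalize(pw, RateLawKind.MICHAELIS_MENTEN, demands, s,
                     free, np.full(n, np.nan), diag)


def _effective_alphas(pw: PathwaySpec) -> np.ndarray:
    """alpha scaled by enzyme weights (effective turnover times w_i/kcat_i)."""
    return pw.weights * pw.alphas


def _theta_sum(psi: float, alpha: np.ndarray) -> float:
    x = psi * alpha
    return float(2.0 * np.sum(np.arcsinh(np.sqrt(x))))


def psi_from_theta_tot(pw: PathwaySpec) -> float:
    """Solve theta_tot = 2 sum_i asinh(sqrt(Psi alpha_i)) for the unique Psi > 0.

    The left-hand side is strictly increasing in Psi on [0, inf), so a
    bracketed root search converges to relative tolerance ~1e-14.  Enzyme
    weights enter through the effective alpha_i = w_i/kcat_i.
    """
    pw.check_driving_force()
    theta_tot = pw.theta_tot
    if theta_tot <= 0:
        raise InfeasibleError(f"theta_tot = {theta_tot:g} <= 0")
    alpha = _effective_alphas(pw)
    # bracket in log-space for scale-free relative accuracy
    lo, hi = 1e-12, 1.0
    while _theta_sum(lo, alpha) > theta_tot:
        lo *= 1e-3
        if lo < 1e-300:
            raise NumericalError("Psi bracket underflow")
    while _theta_sum(hi, alpha) < theta_tot:
        hi *= 2.0
        if hi > 1e300:
            raise NumericalError("Psi bracket overflow")
    f = lambda u: _theta_sum(math.exp(u), alpha) - theta_tot
    u = brentq(f, math.log(lo), math.log(hi), xtol=1e-15, rtol=8.9e-16, maxiter=200)
    psi = math.exp(u)
    resid = abs(_theta_sum(psi, alpha) - theta_tot) / theta_tot
    if resid > 1e-12:
        raise NumericalError(f"Psi residual {resid:g} exceeds 1e-12")
    return psi


def solve_thermodynamic(pw: PathwaySpec) -> OptimalState:
    """Reversible saturated chain: split theta_tot optimally via Psi.

    theta*_i = 2*asinh(sqrt(Psi alpha_i)); demand per flux
    d_i = alpha_i/(1 - exp(-theta*_i)) = alpha_i (1 + sqrt(1 + 1/(Psi alpha_i)))/2.
    The allocation depends on the equilibrium constants only through
    K_eq_tot; the internal concentrations are reconstructed from the
    per-reaction K_eq_i chain.
    """
    psi = psi_from_theta_tot(pw)
    n = pw.n
    alpha_eff = _effective_alphas(pw)
    theta = 2.0 * np.arcsinh(np.sqrt(psi * alpha_eff))
    eta_for = -np.expm1(-theta)
    demands = pw.alphas / eta_for
    s = np.full(n + 1, np.nan)
    s[0] = pw.s0
    keq = pw.K_eqs
    for i in range(n):
        s[i + 1] = s[i] * keq[i] * math.exp(-theta[i])
    free = np.zeros(n + 1, dtype=bool)
    free[1:n] = True
    diag = {"psi": psi,
            "theta_residual": abs(float(np.sum(theta)) - pw.theta_tot)}
    return _finalize(pw, RateLawKind.THERMODYNAMIC, demands, s, free, theta, diag)


def approx_thermodynamic_flux(pw: PathwaySpec) -> float:
    """Closed-form approximation to the thermodynamic optimum:

        J* ~ (eps_tot/||alpha||_1) * (1 - exp(-(||alpha||_1/||alpha||_1/2) * theta_tot))

    Exact in both limits theta_tot -> 0 (slope eps_tot/||alpha||_1/2) and
    theta_tot -> inf (plateau eps_tot/||alpha||_1); it has the same shape as
    the thermodynamic rate law of a single reaction.
    """
    pw.check_driving_force()
    theta_tot = pw.theta_tot
    if theta_tot <= 0:
        raise InfeasibleError(f"theta_tot = {theta_tot:g} <= 0")
    alpha = _effective_alphas(pw)
    a1 = norm_l1(alpha)
    ah = norm_half(alpha)
    return (pw.eps_tot / a1) * (-math.expm1(-(a1 / ah) * theta_tot))


def solve_mass_action(pw: PathwaySpec) -> OptimalState:
    """Reversible dilute chain (Waley's case): eps*_i ~ sqrt(gamma_i).

    In the transformed coordinates t_i = s_i * prod_{j>i} K_eq_j the demand
    of step i is gamma_i/(t_{i-1} - t_i), and the optimal drops
    t_{i-1} - t_i are proportional to sqrt(gamma_i), giving

        J* = eps_tot * (s0 K_eq_tot - sn) / ||gamma||_1/2.

    The flux is linear in s0: no saturation, hence no Monod parameters
    exist for this law.
    """
    pw.check_driving_force()
    n = pw.n
    gamma = pw.gammas
    wgamma = pw.weights * gamma
    keq = pw.K_eqs
    t0 = pw.s0 * pw.K_eq_tot
    tn = pw.sn
    span = t0 - tn
    root = np.sqrt(wgamma)
    drops = span * root / root.sum()
    demands = gamma / drops
    t = t0 - np.concatenate(([0.0], np.cumsum(drops)))
    # s_i = t_i / prod_{r>=i} Keq_r (0-based reactions; empty product for i=n)
    tailprod = np.concatenate((np.cumprod(keq[::-1])[::-1], [1.0]))
    s = t / tailprod
    s[0], s[-1] = pw.s0, pw.sn  # exact boundaries
    theta = np.array([math.log(keq[i] * s[i] / s[i + 1]) for i in range(n)])
    free = np.zeros(n + 1, dtype=bool)
    free[1:n] = True
    return _finalize(pw, RateLawKind.MASS_ACTION, demands, s, free, theta,
                     {"t_drops": drops})


def pathway_specific_activity(pw: PathwaySpec) -> tuple[float, np.ndarray]:
    """Pathway specific activity 1/||alpha||_1 and the turnover times alpha_i.

    Turnover times along a pathway are additive: for the trivial law,
    eps_tot/J* = sum_i tau_i (like resistors in series).
    """
    alpha = pw.alphas
    return 1.0 / norm_l1(alpha), alpha
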
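"""Numerical machinery: convex enzyme-cost minimization, steady states,
and stability.

The flux-maximization problem is solved in its equivalent enzyme-cost form:
minimize the total weighted enzyme demand at unit flux,

    q(x) = sum_i w_i / r_i(s_{i-1}, s_i),        s_k = exp(x_k),

over the log-concentrations x of the free metabolites, optionally subject
to the density constraint sum_k s_k <= s_tot.  The objective is convex in
x and the constraint set is convex, so a local solver from a feasible
interior start finds the global optimum; solutions are polished by a
Newton solve of the KKT conditions and cross-checked against a brute-force
grid oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import NonlinearConstraint, brentq, minimize, root

from .allocate import OptimalState
from .errors import (
    DomainError,
    InfeasibleError,
    NoSteadyStateError,
    NumericalError,
    UnboundedMetaboliteError,
)
from .ratelaws import (
    PathwaySpec,
    RateLawKind,
    evaluate_rate,
    rate_gradient,
    rate_per_enzyme,
)

__all__ = [
    "ConvexProblem",
    "min_enzyme_demand",
    "min_enzyme_demand_density",
    "steady_state",
    "jacobian_stability",
    "StabilityReport",
    "grid_oracle",
]


# ---------------------------------------------------------------------------
# Problem assembly
# ---------------------------------------------------------------------------


def _free_metabolites(pw: PathwaySpec, kind: RateLawKind) -> list[int]:
    """Indices (into s_0..s_n) of metabolites the optimizer may vary."""
    n = pw.n
    if kind is RateLawKind.TRIVIAL:
        return []
    if kind is RateLawKind.MICHAELIS_MENTEN:
        # products never enter; substrates are s_0..s_{n-1}
        start = 1 if pw.s0 is not None else 0
        return list(range(start, n))
    # reversible laws need both boundaries fixed
    if pw.s0 is None or pw.sn is None:
        raise InfeasibleError(
            f"rate law {kind.value!r} requires fixed boundary concentrations s0, sn"
        )
    return list(range(1, n))


@dataclass
class ConvexProblem:
    """The assembled enzyme-cost minimization in log-concentration space."""

    pw: PathwaySpec
    kind: RateLawKind
    free: list[int]

    def s_full(self, x: np.ndarray) -> np.ndarray:
        s = np.full(self.pw.n + 1, np.nan)
        if self.pw.s0 is not None:
            s[0] = self.pw.s0
        if self.pw.sn is not None:
            s[-1] = self.pw.sn
        with np.errstate(over="ignore"):
            s[self.free] = np.exp(x)
        return s

    def demands(self, s: np.ndarray) -> np.ndarray:
        out = np.empty(self.pw.n)
        with np.errstate(over="ignore", invalid="ignore"):
            for i, kin in enumerate(self.pw.reactions):
                p = s[i + 1]
                if self.kind is RateLawKind.MICHAELIS_MENTEN or self.kind is RateLawKind.TRIVIAL:
                    p = 0.0  # product does not enter irreversible laws
                r = rate_per_enzyme(self.kind, kin, s[i], p)
                if not (r > 0):
                    return np.full(self.pw.n, np.inf)
                out[i] = 1.0 / r
        return out

    def objective(self, x: np.ndarray) -> float:
        d = self.demands(self.s_full(x))
        if not np.all(np.isfinite(d)):
            return 1e30
        return float(np.dot(self.pw.weights, d))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient dq/dx_k via the rate-law partial derivatives."""
        with np.errstate(over="ignore", invalid="ignore"):
            return self._gradient(x)

    def _gradient(self, x: np.ndarray) -> np.ndarray:
        pw, kind = self.pw, self.kind
        s = self.s_full(x)
        g = np.zeros(len(self.free))
        w = pw.weights
        pos = {m: k for k, m in enumerate(self.free)}
        for i, kin in enumerate(pw.reactions):
            p = s[i + 1]
            if kind in (RateLawKind.MICHAELIS_MENTEN, RateLawKind.TRIVIAL):
                p = 0.0
            r = rate_per_enzyme(kind, kin, s[i], p)
            if r <= 0:
                return np.full(len(self.free), np.nan)
            dr_ds, dr_dp = rate_gradient(kind, kin, s[i], p)
            coef = -w[i] / r**2
            if i in pos:  # substrate s_i is free
                g[pos[i]] += coef * dr_ds * s[i]
            if (i + 1) in pos and kind.reversible:
                g[pos[i + 1]] += coef * dr_dp * s[i + 1]
        return g

    def density(self, x: np.ndarray) -> float:
        with np.errstate(over="ignore"):
            return float(np.sum(np.exp(x)))


def _candidate_starts(prob: ConvexProblem) -> list[np.ndarray]:
    """Neutral interior starting points (none derived from the analytic
    solutions this solver serves as oracle for): equal driving-force drops
    in the K_eq-transformed coordinates, log-linear interpolation between
    the boundaries, and equal shares of the metabolite budget."""
    pw, kind, free = prob.pw, prob.kind, prob.free
    n = pw.n
    if not free:
        return [np.empty(0)]
    candidates = []
    if pw.s_tot is not None:
        share = 0.9 * pw.s_tot / len(free)
        candidates.append(np.log(np.full(len(free), share)))
    if kind is not RateLawKind.MICHAELIS_MENTEN:
        keq = pw.K_eqs
        tail = np.concatenate((np.cumprod(keq[::-1])[::-1], [1.0]))  # prod_{r>=i}
        t0, tn = pw.s0 * tail[0], pw.sn
        t = t0 + (tn - t0) * np.arange(n + 1) / n
        with np.errstate(over="ignore", under="ignore"):
            s = t / tail
        candidates.append(np.log(s[free]))
        # log-linear chain between the fixed boundaries
        lam = np.array(free) / n
        candidates.append(
            (1 - lam) * math.log(pw.s0) + lam * math.log(pw.sn)
        )
    elif pw.s0 is not None:
        candidates.append(np.log(np.full(len(free), pw.s0)))
    out = []
    for x in candidates:
        if not np.all(np.isfinite(x)):
            continue
        if pw.s_tot is not None:
            total = float(np.sum(np.exp(x)))
            if total > 0.95 * pw.s_tot:
                x = x + math.log(0.9 * pw.s_tot / total)
        if np.isfinite(prob.objective(x)):
            out.append(x)
    return out


def _kkt_polish(prob: ConvexProblem, x: np.ndarray, bound_active: bool) -> np.ndarray:
    """Newton-solve the stationarity conditions from the SLSQP solution."""
    pw = prob.pw
    if bound_active:
        def fun(z):
            xx, lam = z[:-1], z[-1]
            return np.concatenate(
                (prob.gradient(xx) + lam * np.exp(xx), [prob.density(xx) - pw.s_tot])
            )
        g = prob.gradient(x)
        lam0 = max(1e-12, -float(np.mean(g / np.exp(x))))
        z0 = np.concatenate((x, [lam0]))
        sol = root(fun, z0, method="hybr", tol=1e-14)
        # hybr may flag "xtol too small" even at full convergence: judge by
        # the achieved KKT residual, not the success flag
        if sol.x[-1] >= 0 and np.max(np.abs(fun(sol.x))) <= np.max(np.abs(fun(z0))):
            return sol.x[:-1]
        return x
    sol = root(prob.gradient, x, method="hybr", tol=1e-14)
    better_grad = np.max(np.abs(prob.gradient(sol.x))) <= np.max(np.abs(prob.gradient(x)))
    if better_grad and prob.objective(sol.x) <= prob.objective(x) * (1 + 1e-9):
        return sol.x
    return x


def _state_from_solution(prob: ConvexProblem, x: np.ndarray, diag: dict) -> OptimalState:
    pw, kind = prob.pw, prob.kind
    s = prob.s_full(x)
    d = prob.demands(s)
    total = float(np.dot(pw.weights, d))
    J = pw.eps_tot / total
    eps = J * d
    n = pw.n
    theta = np.full(n, np.nan)
    if kind.reversible:
        keq = pw.K_eqs
        theta = np.array(
            [math.log(keq[i] * s[i] / s[i + 1]) for i in range(n)]
        )
    free = np.zeros(n + 1, dtype=bool)
    free[prob.free] = True
    diag.setdefault("objective", total)
    return OptimalState(
        eps_star=eps, s_star=s, free_metabolites=free, theta_star=theta,
        J_star=J, rate_law=kind, diagnostics=diag,
    )


def min_enzyme_demand(pw: PathwaySpec, kind: RateLawKind) -> OptimalState:
    """Minimize total weighted enzyme demand at unit flux; return the
    equivalent flux-maximal state (J* = eps_tot/demand, eps*_i = J* d_i).

    Serves both as the Haldane-law solver (no analytic solution exists) and
    as the numerical oracle for the analytic solvers of the other laws.
    """
    for kin in pw.reactions:
        kin.require(kind)
    if kind.reversible:
        pw.check_driving_force()
    free = _free_metabolites(pw, kind)
    if kind is RateLawKind.MICHAELIS_MENTEN and free and pw.s_tot is None:
        raise UnboundedMetaboliteError(
            "Michaelis-Menten enzyme demand decreases indefinitely as "
            "s_i -> inf; a metabolite bound s_tot is required."
        )
    prob = ConvexProblem(pw, kind, free)
    if not free:
        return _state_from_solution(prob, np.empty(0), {"iterations": 0})

    starts = _candidate_starts(prob)
    if not starts:
        raise InfeasibleError("could not construct a feasible starting point "
                              "(driving force or metabolite bound too tight)")
    constraints = []
    if pw.s_tot is not None:
        constraints.append({
            "type": "ineq",
            "fun": lambda x: pw.s_tot - prob.density(x),
            "jac": lambda x: -np.exp(np.clip(x, -700, 700)),
        })
    best_x, best_q, nit = None, np.inf, 0
    for x0 in starts:
        res = minimize(
            prob.objective, x0, jac=prob.gradient, method="SLSQP",
            constraints=constraints,
            options={"ftol": 1e-14, "maxiter": 500},
        )
        q = prob.objective(res.x)
        feasible = pw.s_tot is None or prob.density(res.x) <= pw.s_tot * (1 + 1e-9)
        if np.isfinite(q) and feasible and q < best_q:
            best_x, best_q, nit = res.x, q, int(res.nit)
    if best_x is None:
        raise NumericalError("convex enzyme-demand minimization failed from "
                             "every starting point")
    x = best_x
    bound_active = (
        pw.s_tot is not None and prob.density(x) > pw.s_tot * (1 - 1e-6)
    )
    x = _kkt_polish(prob, x, bound_active)
    grad = prob.gradient(x)
    if bound_active:
        lam = -float(np.mean(grad / np.exp(x)))
        kkt = float(np.max(np.abs(grad + lam * np.exp(x))))
    else:
        kkt = float(np.max(np.abs(grad)))
    diag = {
        "iterations": nit,
        "kkt_residual": kkt,
        "metabolite_bound_active": bool(bound_active),
    }
    return _state_from_solution(prob, x, diag)


def min_enzyme_demand_density(
    pw: PathwaySpec, kind: RateLawKind, a: float, b: float, rho: float
) -> OptimalState:
    """Maximize flux under the joint density constraint a*sum(eps) + b*sum(s) <= rho.

    Enzyme and metabolite levels compete for one budget; at flux J the
    constraint reads a*J*sum(w_i d_i(s)) + b*sum(s) = rho, so

        J(s) = (rho - b*sum(s)) / (a * sum_i w_i d_i(s))

    is maximized over the free metabolite concentrations.  Uniform weights
    a (enzymes) and b (metabolites) only.
    """
    if not (a > 0 and b >= 0 and rho > 0):
        raise DomainError("need a > 0, b >= 0, rho > 0")
    free = _free_metabolites(pw, kind)
    prob = ConvexProblem(pw, kind, free)
    if not free:
        raise InfeasibleError("no free metabolites to optimize under the density bound")

    def negJ(x):
        s_sum = prob.density(x)
        budget = rho - b * s_sum
        if budget <= 0:
            return 1e30
        q = prob.objective(x)
        if not np.isfinite(q):
            return 1e30
        return -budget / (a * q)

    # neutral start inside the budget
    if kind is RateLawKind.MICHAELIS_MENTEN:
        s_guess = 0.25 * rho / b if b > 0 else 1.0
        x0 = np.log(np.full(len(free), s_guess / len(free)))
    else:
        starts = _candidate_starts(prob)
        if not starts:
            raise InfeasibleError("no feasible start under the density bound")
        x0 = starts[0]
    res = minimize(negJ, x0, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    sol = root(lambda x: _grad_fd(negJ, x), res.x, method="hybr", tol=1e-13)
    x = sol.x if (sol.success and negJ(sol.x) <= negJ(res.x) + 1e-15) else res.x
    s = prob.s_full(x)
    d = prob.demands(s)
    J = -negJ(x)
    eps = J * d
    n = pw.n
    theta = np.full(n, np.nan)
    if kind.reversible:
        keq = pw.K_eqs
        theta = np.array([math.log(keq[i] * s[i] / s[i + 1]) for i in range(n)])
    free_mask = np.zeros(n + 1, dtype=bool)
    free_mask[free] = True
    diag = {
        "density_constraint": {"a": a, "b": b, "rho": rho},
        "eps_tot_star": float(np.dot(pw.weights, eps)),
        "metabolite_bound_active": b > 0,
    }
    return OptimalState(eps_star=eps, s_star=s, free_metabolites=free_mask,
                        theta_star=theta, J_star=J, rate_law=kind,
                        diagnostics=diag)


def _grad_fd(f, x, rel=1e-7):
    g = np.empty_like(x)
    for k in range(len(x)):
        h = rel * max(1.0, abs(x[k]))
        e = np.zeros_like(x)
        e[k] = h
        g[k] = (f(x + e) - f(x - e)) / (2 * h)
    return g


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------


def steady_state(
    pw: PathwaySpec, kind: RateLawKind, eps: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Steady-state flux and metabolite profile for given enzyme levels.

    * mass-action: closed-form linear-chain solution
      J = (s0 K_eq_tot - sn) / sum_i(gamma_i/eps_i).
    * thermodynamic: unique J in (0, min_i eps_i kcat_i) solving
      prod_i (1 - J/(eps_i kcat_i)) = sn/(s0 K_eq_tot), by bracketed root
      search.
    * Michaelis-Menten: J is set by the first reaction at fixed s0; each
      downstream substrate follows by inverting its rate law, failing with
      the bottleneck reaction named when capacity is insufficient.
    * Haldane: ODE relaxation of the chain followed by a Newton polish.
    """
    eps = np.asarray(eps, dtype=float)
    n = pw.n
    if len(eps) != n or np.any(eps <= 0):
        raise DomainError("eps must be n strictly positive enzyme levels")
    kcat = np.array([r.kcat_fwd for r in pw.reactions])

    if kind is RateLawKind.TRIVIAL:
        v = eps * kcat
        if np.max(v) - np.min(v) > 1e-9 * np.max(v):
            i = int(np.argmin(v))
            raise NoSteadyStateError(
                "trivial law admits a steady state only if all eps_i*kcat_i "
                f"coincide; reaction {i + 1} is the bottleneck"
            )
        s = np.full(n + 1, np.nan)
        s[0], s[-1] = pw.s0 or np.nan, pw.sn or np.nan
        return float(np.mean(v)), s

    if kind is RateLawKind.MICHAELIS_MENTEN:
        if pw.s0 is None:
            raise DomainError("Michaelis-Menten steady state requires fixed s0")
        s = np.full(n + 1, np.nan)
        s[0] = pw.s0
        if pw.sn is not None:
            s[-1] = pw.sn
        J = evaluate_rate(kind, pw.reactions[0], eps[0], pw.s0, 0.0)
        for i in range(1, n):
            cap = eps[i] * kcat[i]
            if cap <= J:
                raise NoSteadyStateError(
                    f"reaction {i + 1} capacity eps*kcat = {cap:g} cannot carry "
                    f"the upstream influx J = {J:g}: no steady state"
                )
            s[i] = J * pw.reactions[i].K_S / (cap - J)
        return float(J), s

    pw.check_driving_force()
    keq = pw.K_eqs
    if kind is RateLawKind.MASS_ACTION:
        gamma = pw.gammas
        J = (pw.s0 * pw.K_eq_tot - pw.sn) / float(np.sum(gamma / eps))
        s = np.empty(n + 1)
        s[0] = pw.s0
        for i in range(n):
            # v_i = eps_i/beta_i (s_i - s_{i+1}/Keq_i) = J
            s[i + 1] = keq[i] * (s[i] - J * pw.betas[i] / eps[i])
        s[-1] = pw.sn
        return float(J), s

    if kind is RateLawKind.THERMODYNAMIC:
        ratio = pw.sn / (pw.s0 * pw.K_eq_tot)  # in (0, 1)
        cap = eps * kcat
        jmax = float(np.min(cap))

        def f(J):
            return float(np.sum(np.log1p(-J / cap))) - math.log(ratio)

        J = brentq(f, 0.0, jmax * (1 - 1e-15), xtol=1e-300, rtol=8.9e-16)
        s = np.empty(n + 1)
        s[0] = pw.s0
        for i in range(n):
            s[i + 1] = keq[i] * s[i] * (1.0 - J / cap[i])
        s[-1] = pw.sn
        return float(J), s

    # Haldane: relax the chain dynamics, then Newton-polish.
    return _haldane_steady_state(pw, eps)


def _haldane_rates(pw: PathwaySpec, eps: np.ndarray, s: np.ndarray) -> np.ndarray:
    return np.array([
        evaluate_rate(RateLawKind.HALDANE, kin, eps[i], s[i], s[i + 1])
        for i, kin in enumerate(pw.reactions)
    ])


def _haldane_steady_state(pw: PathwaySpec, eps: np.ndarray) -> tuple[float, np.ndarray]:
    n = pw.n
    if n == 1:
        s = np.array([pw.s0, pw.sn], dtype=float)
        return float(_haldane_rates(pw, eps, s)[0]), s

    keq = pw.K_eqs
    tail = np.concatenate((np.cumprod(keq[::-1])[::-1], [1.0]))
    t0, tn = pw.s0 * tail[0], pw.sn
    t = t0 + (tn - t0) * np.arange(n + 1) / n
    s = t / tail

    def rhs(_t, y):
        sf = np.concatenate(([pw.s0], np.exp(y), [pw.sn]))
        v = _haldane_rates(pw, eps, sf)
        return (v[:-1] - v[1:]) / np.exp(y)  # d(ln s)/dt

    y = np.log(s[1:n])
    horizon = 1.0
    for _ in range(60):
        sol = solve_ivp(rhs, (0.0, horizon), y, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise NoSteadyStateError("Haldane relaxation failed to integrate")
        y = sol.y[:, -1]
        sf = np.concatenate(([pw.s0], np.exp(y), [pw.sn]))
        v = _haldane_rates(pw, eps, sf)
        spread = np.max(np.abs(v - v[-1]))
        if spread < 1e-9 * max(abs(v[-1]), 1e-300):
            break
        horizon *= 2.0
    else:
        raise NoSteadyStateError(
            "Haldane chain did not relax to a steady state "
            f"(rate spread {spread:g}); reaction "
            f"{int(np.argmin(eps * np.array([r.kcat_fwd for r in pw.reactions]))) + 1} "
            "is the likely bottleneck"
        )

    def balance(y):
        sf = np.concatenate(([pw.s0], np.exp(y), [pw.sn]))
        v = _haldane_rates(pw, eps, sf)
        return v[:-1] - v[1:]

    polish = root(balance, y, method="hybr", tol=1e-14)
    if polish.success:
        y = polish.x
    sf = np.concatenate(([pw.s0], np.exp(y), [pw.sn]))
    v = _haldane_rates(pw, eps, sf)
    return float(np.mean(v)), sf


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool


def jacobian_stability(
    pw: PathwaySpec, kind: RateLawKind, eps: Sequence[float], s: Sequence[float]
) -> StabilityReport:
    """Numeric Jacobian of the internal-metabolite dynamics at a steady state.

    Central differences; ``stable`` means all eigenvalue real parts < 0,
    with a +/-1e-10 band reported as ``marginal``.
    """
    eps = np.asarray(eps, dtype=float)
    s = np.asarray(s, dtype=float)
    n = pw.n

    def rates(sf):
        out = np.empty(n)
        for i, kin in enumerate(pw.reactions):
            p = sf[i + 1]
            if kind in (RateLawKind.MICHAELIS_MENTEN, RateLawKind.TRIVIAL):
                p = 0.0
            out[i] = evaluate_rate(kind, kin, eps[i], sf[i], p)
        return out

    v = rates(s)
    if np.max(np.abs(v - np.mean(v))) > 1e-6 * max(abs(np.mean(v)), 1e-300):
        raise NoSteadyStateError("jacobian_stability requires a steady state input")

    internal = list(range(1, n))
    if not internal:
        return StabilityReport(np.empty(0), True, False)

    def f(si):
        sf = s.copy()
        sf[internal] = si
        vv = rates(sf)
        return vv[:-1] - vv[1:]

    m = len(internal)
    jac = np.empty((m, m))
    base = s[internal]
    for k in range(m):
        h = 1e-6 * base[k]
        up, dn = base.copy(), base.copy()
        up[k] += h
        dn[k] -= h
        jac[:, k] = (f(up) - f(dn)) / (2 * h)
    eig = np.linalg.eigvals(jac)
    re = eig.real
    marginal = bool(np.any(np.abs(re) <= 1e-10))
    stable = bool(np.all(re < 0))
    return StabilityReport(eig, stable, marginal)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def grid_oracle(pw: PathwaySpec, kind: RateLawKind, resolution: int = 30) -> OptimalState:
    """Exhaustive log-grid search over the free metabolites (<= 3 of them).

    Independent of the convex solver; its best grid point must agree with
    :func:`min_enzyme_demand` to within one grid cell.
    """
    free = _free_metabolites(pw, kind)
    if len(free) > 3:
        raise DomainError("grid_oracle refuses more than 3 free metabolites")
    prob = ConvexProblem(pw, kind, free)
    if not free:
        return _state_from_solution(prob, np.empty(0), {"oracle": "grid"})

    anchors = [v for v in (pw.s0, pw.sn, pw.s_tot) if v is not None]
    scale = float(np.exp(np.mean(np.log(anchors)))) if anchors else 1.0
    lo, hi = math.log(scale * 1e-4), math.log(scale * 1e3)
    if pw.s_tot is not None:
        hi = min(hi, math.log(pw.s_tot))
    axes = [np.linspace(lo, hi, resolution)] * len(free)
    best_q, best_x = np.inf, None
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    for x in pts:
        if pw.s_tot is not None and np.sum(np.exp(x)) > pw.s_tot:
            continue
        q = prob.objective(x)
        if q < best_q:
            best_q, best_x = q, x
    if best_x is None:
        raise InfeasibleError("grid oracle found no feasible point")
    return _state_from_solution(prob, best_x, {
        "oracle": "grid", "resolution": resolution,
        "cell_width_log": (hi - lo) / (resolution - 1),
    })
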
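"""Seeded random pathway generator for tests and benchmarking.

Kinetic constants are drawn log-uniformly (kcat in [1, 100], K_M in
[0.01, 10], K_eq in [0.1, 1000] by default) and, for reversible laws, the
boundary concentrations are constructed so that the overall driving force
theta_tot is uniform in [0.5, 10] - feasible by construction.  Identical
seed and configuration give an identical pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .ratelaws import PathwaySpec, RateLawKind, ReactionKinetics

__all__ = ["FixtureConfig", "generate_fixture"]


@dataclass(frozen=True)
class FixtureConfig:
    seed: int
    n: int
    law: RateLawKind
    kcat_range: tuple[float, float] = (1.0, 100.0)
    K_range: tuple[float, float] = (0.01, 10.0)
    Keq_range: tuple[float, float] = (0.1, 1000.0)
    theta_tot_range: tuple[float, float] = (0.5, 10.0)
    eps_tot: float = 1.0
    s_tot_per_step: float = 1.0  # metabolite budget, scaled by n where needed

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        for name in ("kcat_range", "K_range", "Keq_range", "theta_tot_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise DomainError(f"{name} must satisfy 0 < lo <= hi")


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size))


def generate_fixture(cfg: FixtureConfig) -> PathwaySpec:
    """Draw one random pathway; deterministic under the seed."""
    rng = np.random.default_rng(cfg.seed)
    law = cfg.law
    n = cfg.n
    kcat = _loguniform(rng, *cfg.kcat_range, n)
    K_S = _loguniform(rng, *cfg.K_range, n)
    K_P = _loguniform(rng, *cfg.K_range, n)
    Keq = _loguniform(rng, *cfg.Keq_range, n)
    theta_tot = float(rng.uniform(*cfg.theta_tot_range))

    reactions = []
    for i in range(n):
        kwargs = {"kcat_fwd": float(kcat[i])}
        if law in (RateLawKind.MICHAELIS_MENTEN, RateLawKind.MASS_ACTION,
                   RateLawKind.HALDANE):
            kwargs["K_S"] = float(K_S[i])
        if law.reversible:
            kwargs["K_eq"] = float(Keq[i])
        if law is RateLawKind.HALDANE:
            kwargs["K_P"] = float(K_P[i])
            # reverse turnover via the Haldane relationship
            kwargs["kcat_rev"] = float(kcat[i] * K_P[i] / (K_S[i] * Keq[i]))
        reactions.append(ReactionKinetics(**kwargs))

    s0 = sn = s_tot = None
    if law.reversible:
        s0 = float(_loguniform(rng, 0.1, 10.0, 1)[0])
        keq_tot = float(np.prod(Keq))
        sn = s0 * keq_tot * math.exp(-theta_tot)
    if law is RateLawKind.MICHAELIS_MENTEN:
        s_tot = cfg.s_tot_per_step * n
    if law is RateLawKind.HALDANE:
        # generous enough not to preclude the thermodynamically feasible band
        s_tot = None

    return PathwaySpec(
        reactions=tuple(reactions),
        s0=s0,
        sn=sn,
        eps_tot=cfg.eps_tot,
        s_tot=s_tot,
    )
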
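"""Shared pathway builders for the test suite."""

import numpy as np
import pytest

from enzalloc import FixtureConfig, PathwaySpec, RateLawKind, ReactionKinetics, generate_fixture


def reactions_from_arrays(kcat, K_S=None, K_eq=None, K_P=None, kcat_rev=None):
    """Build a reaction tuple from parallel parameter arrays."""
    n = len(kcat)
    def pick(arr, i):
        return None if arr is None else float(arr[i])
    return tuple(
        ReactionKinetics(
            kcat_fwd=float(kcat[i]),
            K_S=pick(K_S, i),
            K_eq=pick(K_eq, i),
            K_P=pick(K_P, i),
            kcat_rev=pick(kcat_rev, i),
        )
        for i in range(n)
    )


@pytest.fixture
def haldane_fig3_kinetics():
    """The illustrative Haldane parameter set: Keq = K_S = kcat = 1, K_P = 10."""
    return ReactionKinetics(kcat_fwd=1.0, K_S=1.0, K_P=10.0, K_eq=1.0)


@pytest.fixture
def thermo_two_step():
    """Two-step saturated reversible pathway, kcat = (3, 100), Keq = 1."""
    def make(theta_tot: float, k2: float = 100.0) -> PathwaySpec:
        return PathwaySpec(
            reactions=reactions_from_arrays([3.0, k2], K_eq=[1.0, 1.0]),
            s0=1.0,
            sn=float(np.exp(-theta_tot)),
            eps_tot=1.0,
        )
    return make


def fixture_pathway(seed: int, n: int, law: RateLawKind) -> PathwaySpec:
    return generate_fixture(FixtureConfig(seed=seed, n=n, law=law))
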
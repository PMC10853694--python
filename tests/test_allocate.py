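"""Closed-form allocation solvers: worked examples, limits, invariants."""

import math

import numpy as np
import pytest

from enzalloc import (
    PathwaySpec,
    RateLawKind,
    ReactionKinetics,
    approx_thermodynamic_flux,
    evaluate_rate,
    norm_half,
    norm_l1,
    pathway_specific_activity,
    psi_from_theta_tot,
    solve_mass_action,
    solve_michaelis_menten,
    solve_thermodynamic,
    solve_trivial,
)
from enzalloc.errors import InfeasibleError, UnboundedMetaboliteError

from conftest import fixture_pathway, reactions_from_arrays

ANALYTIC = {
    RateLawKind.TRIVIAL: solve_trivial,
    RateLawKind.MICHAELIS_MENTEN: solve_michaelis_menten,
    RateLawKind.THERMODYNAMIC: solve_thermodynamic,
    RateLawKind.MASS_ACTION: solve_mass_action,
}


def _steady_state_residual(pw, kind, state):
    """Max relative deviation of the per-reaction rates from J*."""
    worst = 0.0
    for i, kin in enumerate(pw.reactions):
        s, p = state.s_star[i], state.s_star[i + 1]
        if kind in (RateLawKind.TRIVIAL,):
            s = p = 1.0
        if kind is RateLawKind.MICHAELIS_MENTEN:
            p = 0.0
            if math.isnan(s):
                continue  # saturated limit
        v = evaluate_rate(kind, kin, state.eps_star[i], s, p)
        worst = max(worst, abs(v / state.J_star - 1.0))
    return worst


# ---------------------------------------------------------------------------
# trivial
# ---------------------------------------------------------------------------


def test_trivial_symmetric_and_single():
    pw = PathwaySpec(reactions=reactions_from_arrays([1.0, 1.0]), eps_tot=1.0)
    st = solve_trivial(pw)
    assert st.J_star == pytest.approx(0.5)
    np.testing.assert_allclose(st.eps_star, [0.5, 0.5])
    pw1 = PathwaySpec(reactions=reactions_from_arrays([5.0]), eps_tot=2.0)
    assert solve_trivial(pw1).J_star == pytest.approx(10.0)


def test_trivial_heterogeneous_kcats():
    pw = PathwaySpec(reactions=reactions_from_arrays([1.0, 2.0, 4.0]), eps_tot=1.0)
    st = solve_trivial(pw)
    assert st.J_star == pytest.approx(4.0 / 7.0, rel=1e-12)
    np.testing.assert_allclose(st.eps_star, [4 / 7, 2 / 7, 1 / 7], rtol=1e-12)


def test_pathway_specific_activity_additive_turnover_times():
    pw = PathwaySpec(reactions=reactions_from_arrays([1.0, 2.0, 4.0]), eps_tot=1.0)
    psa, tau = pathway_specific_activity(pw)
    assert psa == pytest.approx(solve_trivial(pw).J_star / pw.eps_tot)
    assert np.sum(tau) == pytest.approx(pw.eps_tot / solve_trivial(pw).J_star)
    pw2 = PathwaySpec(reactions=reactions_from_arrays([1.0, 1.0]))
    assert pathway_specific_activity(pw2)[0] == pytest.approx(0.5)
    pw3 = PathwaySpec(reactions=reactions_from_arrays([7.0]))
    assert pathway_specific_activity(pw3)[0] == pytest.approx(7.0)


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------


def test_mm_symmetric_two_step():
    pw = PathwaySpec(
        reactions=reactions_from_arrays([1.0, 1.0], K_S=[1.0, 1.0]),
        eps_tot=1.0, s_tot=4.0,
    )
    st = solve_michaelis_menten(pw)
    np.testing.assert_allclose(st.s_star[:2], [2.0, 2.0], rtol=1e-12)
    np.testing.assert_allclose(st.eps_star, [0.5, 0.5], rtol=1e-12)
    assert st.J_star == pytest.approx(1.0 / 3.0, rel=1e-12)
    assert _steady_state_residual(pw, RateLawKind.MICHAELIS_MENTEN, st) < 1e-12


def test_mm_reduces_to_trivial_when_saturation_is_cheap():
    pw = PathwaySpec(
        reactions=reactions_from_arrays([1.0, 2.0], K_S=[1e-12, 1e-12]),
        eps_tot=1.0, s_tot=1.0,
    )
    st = solve_michaelis_menten(pw)
    tr = solve_trivial(pw)
    assert st.J_star == pytest.approx(tr.J_star, rel=1e-5)


def test_mm_large_metabolite_budget_approaches_pathway_specific_activity():
    pw = PathwaySpec(
        reactions=reactions_from_arrays([1.0, 2.0], K_S=[1.0, 0.5]),
        eps_tot=1.0, s_tot=1e9,
    )
    st = solve_michaelis_menten(pw)
    assert st.J_star == pytest.approx(1.0 / norm_l1(pw.alphas), rel=1e-4)


def test_mm_without_bound_raises_paradox():
    pw = PathwaySpec(reactions=reactions_from_arrays([1.0, 1.0], K_S=[1.0, 1.0]))
    with pytest.raises(UnboundedMetaboliteError):
        solve_michaelis_menten(pw)
    limit = solve_michaelis_menten(pw, unbounded="limit")
    assert "limit" in limit.diagnostics
    assert limit.J_star == pytest.approx(0.5)


def test_mm_fixed_s0_variant_excludes_first_reaction_from_sqrt_term():
    kcat, ks = [2.0, 1.0, 3.0], [0.5, 1.0, 2.0]
    pw = PathwaySpec(reactions=reactions_from_arrays(kcat, K_S=ks),
                     s0=4.0, eps_tot=1.0, s_tot=2.0)
    st = solve_michaelis_menten(pw)
    alpha, beta = pw.alphas, pw.betas
    expected_demand_1 = alpha[0] + beta[0] / 4.0
    assert st.eps_star[0] / st.J_star == pytest.approx(expected_demand_1, rel=1e-12)
    root = math.sqrt(beta[1]) + math.sqrt(beta[2])
    expected_J = 1.0 / (expected_demand_1 + alpha[1] + alpha[2] + root**2 / 2.0)
    assert st.J_star == pytest.approx(expected_J, rel=1e-12)
    assert _steady_state_residual(pw, RateLawKind.MICHAELIS_MENTEN, st) < 1e-12


# ---------------------------------------------------------------------------
# thermodynamic and Psi
# ---------------------------------------------------------------------------


def test_psi_single_reaction_closed_form():
    # theta = 2*asinh(sqrt(Psi*alpha)) inverts to Psi = kcat*sinh^2(theta/2)
    pw = PathwaySpec(
        reactions=reactions_from_arrays([1.0], K_eq=[math.exp(2.0)]),
        s0=1.0, sn=1.0,
    )
    assert psi_from_theta_tot(pw) == pytest.approx(math.sinh(1.0) ** 2, rel=1e-12)


def test_psi_vanishes_with_driving_force():
    pw = PathwaySpec(
        reactions=reactions_from_arrays([1.0, 2.0], K_eq=[1.0, 1.0]),
        s0=1.0, sn=math.exp(-1e-6),
    )
    assert psi_from_theta_tot(pw) < 1e-3


def test_psi_infeasible_without_positive_driving_force():
    pw = PathwaySpec(
        reactions=reactions_from_arrays([1.0], K_eq=[1.0]), s0=1.0, sn=2.0)
    with pytest.raises(InfeasibleError):
        psi_from_theta_tot(pw)


def test_psi_residual_on_heterogeneous_pathway(thermo_two_step):
    from enzalloc.allocate import _effective_alphas, _theta_sum
    for theta_tot in (0.1, 1.0, 5.0):
        for k2 in (100.0, 2.0):
            pw = thermo_two_step(theta_tot, k2)
            psi = psi_from_theta_tot(pw)
            resid = abs(_theta_sum(psi, _effective_alphas(pw)) - theta_tot)
            assert resid < 1e-12 * theta_tot


def test_thermodynamic_single_reaction():
    pw = PathwaySpec(reactions=reactions_from_arrays([2.0], K_eq=[10.0]),
                     s0=1.0, sn=2.0, eps_tot=3.0)
    st = solve_thermodynamic(pw)
    theta_tot = math.log(10.0 / 2.0)
    assert st.eps_star[0] == pytest.approx(3.0)
    assert st.J_star == pytest.approx(3.0 * 2.0 * (1 - math.exp(-theta_tot)), rel=1e-12)


def test_thermodynamic_limits(thermo_two_step):
    # theta_tot -> inf: J -> eps_tot/||alpha||_1
    big = thermo_two_step(60.0)
    assert solve_thermodynamic(big).J_star == pytest.approx(
        1.0 / norm_l1(big.alphas), rel=1e-6)
    # theta_tot -> 0: J -> eps_tot*theta_tot/||alpha||_1/2, theta_i ~ sqrt(alpha_i)
    small = thermo_two_step(1e-5)
    st = solve_thermodynamic(small)
    assert st.J_star == pytest.approx(1e-5 / norm_half(small.alphas), rel=1e-3)
    ratio = st.theta_star[0] / st.theta_star[1]
    assert ratio == pytest.approx(math.sqrt(100.0 / 3.0), rel=1e-3)


def test_thermodynamic_allocation_invariant_under_keq_redistribution():
    """Only K_eq_tot matters: moving equilibrium constants between steps
    changes the internal concentrations but not eps* or J*."""
    kcat = [3.0, 7.0, 1.5]
    base = PathwaySpec(reactions=reactions_from_arrays(kcat, K_eq=[2.0, 5.0, 1.0]),
                       s0=1.0, sn=0.5, eps_tot=1.0)
    shuffled = PathwaySpec(reactions=reactions_from_arrays(kcat, K_eq=[10.0, 0.5, 2.0]),
                           s0=1.0, sn=0.5, eps_tot=1.0)
    a, b = solve_thermodynamic(base), solve_thermodynamic(shuffled)
    assert a.J_star == pytest.approx(b.J_star, rel=1e-10)
    np.testing.assert_allclose(a.eps_star, b.eps_star, rtol=1e-10)
    np.testing.assert_allclose(a.theta_star, b.theta_star, rtol=1e-10)


def test_thermodynamic_reconstructed_chain_hits_sn(thermo_two_step):
    pw = thermo_two_step(2.5)
    st = solve_thermodynamic(pw)
    assert st.s_star[-1] == pytest.approx(pw.sn, rel=1e-10)
    assert np.sum(st.theta_star) == pytest.approx(pw.theta_tot, rel=1e-12)


def test_approx_thermodynamic_limits_and_slope(thermo_two_step):
    pw_big = thermo_two_step(50.0)
    assert approx_thermodynamic_flux(pw_big) == pytest.approx(
        1.0 / norm_l1(pw_big.alphas), rel=1e-10)
    pw_small = thermo_two_step(1e-8)
    # slope at zero equals eps_tot/||alpha||_1/2
    assert approx_thermodynamic_flux(pw_small) / 1e-8 == pytest.approx(
        1.0 / norm_half(pw_small.alphas), rel=1e-6)


def test_approx_close_to_exact_on_reference_pathways(thermo_two_step):
    """The one-parameter approximation stays within a few percent of the
    exact Psi solution across the physiological range of driving forces."""
    for k2 in (100.0, 2.0):
        for theta in np.linspace(0.1, 10.0, 25):
            pw = thermo_two_step(float(theta), k2)
            exact = solve_thermodynamic(pw).J_star
            approx = approx_thermodynamic_flux(pw)
            assert abs(approx / exact - 1.0) < 0.05


# ---------------------------------------------------------------------------
# mass-action
# ---------------------------------------------------------------------------


def test_mass_action_single_reaction_full_budget():
    pw = PathwaySpec(reactions=reactions_from_arrays([2.0], K_S=[0.5], K_eq=[4.0]),
                     s0=1.0, sn=2.0, eps_tot=3.0)
    st = solve_mass_action(pw)
    assert st.eps_star[0] == pytest.approx(3.0)
    assert st.J_star == pytest.approx(3.0 * (2.0 / 0.5) * (1.0 - 2.0 / 4.0), rel=1e-12)


def test_mass_action_flux_decreases_quadratically_with_length():
    s0, sn = 10.0, 1.0
    js = {}
    for n in (1, 2, 4, 8):
        pw = PathwaySpec(
            reactions=reactions_from_arrays([1.0] * n, K_S=[1.0] * n, K_eq=[1.0] * n),
            s0=s0, sn=sn, eps_tot=1.0)
        js[n] = solve_mass_action(pw).J_star
    for n in (2, 4, 8):
        assert js[n] == pytest.approx(js[1] / n**2, rel=1e-12)


def test_mass_action_sqrt_scaling_of_improved_enzyme():
    kcat, ks, keq = [1.0, 2.0, 1.5], [1.0, 0.5, 2.0], [2.0, 1.0, 3.0]
    pw = PathwaySpec(reactions=reactions_from_arrays(kcat, K_S=ks, K_eq=keq),
                     s0=5.0, sn=1.0, eps_tot=1.0)
    base = solve_mass_action(pw)
    a = 9.0
    kcat2 = list(kcat)
    kcat2[1] *= a
    pw2 = PathwaySpec(reactions=reactions_from_arrays(kcat2, K_S=ks, K_eq=keq),
                      s0=5.0, sn=1.0, eps_tot=1.0)
    improved = solve_mass_action(pw2)
    # relative to the untouched enzymes, the improved one shrinks by sqrt(a)
    ratio_before = base.eps_star[1] / base.eps_star[0]
    ratio_after = improved.eps_star[1] / improved.eps_star[0]
    assert ratio_after == pytest.approx(ratio_before / math.sqrt(a), rel=1e-12)
    assert improved.J_star > base.J_star


def test_mass_action_infeasible_driving_force():
    pw = PathwaySpec(reactions=reactions_from_arrays([1.0], K_S=[1.0], K_eq=[1.0]),
                     s0=1.0, sn=2.0)
    with pytest.raises(InfeasibleError):
        solve_mass_action(pw)


# ---------------------------------------------------------------------------
# cross-law invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("law", list(ANALYTIC))
def test_budget_and_steady_state_invariants(law):
    for seed in range(6):
        pw = fixture_pathway(seed, seed % 5 + 1, law)
        st = ANALYTIC[law](pw)
        assert np.sum(st.eps_star) == pytest.approx(pw.eps_tot, rel=1e-9)
        assert np.all(st.eps_star > 0)
        assert st.J_star > 0
        assert _steady_state_residual(pw, law, st) < 1e-8
        if law is RateLawKind.MICHAELIS_MENTEN:
            free = st.free_metabolites
            assert np.sum(st.s_star[free]) == pytest.approx(pw.s_tot, rel=1e-9)


@pytest.mark.parametrize("law", list(ANALYTIC))
def test_flux_is_homogeneous_in_enzyme_budget(law):
    pw = fixture_pathway(3, 4, law)
    st1 = ANALYTIC[law](pw)
    st2 = ANALYTIC[law](pw.with_(eps_tot=2 * pw.eps_tot))
    assert st2.J_star == pytest.approx(2 * st1.J_star, rel=1e-12)
    np.testing.assert_allclose(st2.eps_star, 2 * st1.eps_star, rtol=1e-12)


def test_flux_monotone_in_kcat_and_budgets():
    pw = fixture_pathway(2, 3, RateLawKind.MICHAELIS_MENTEN)
    base = solve_michaelis_menten(pw).J_star
    faster = list(pw.reactions)
    faster[1] = ReactionKinetics(kcat_fwd=2 * faster[1].kcat_fwd, K_S=faster[1].K_S)
    assert solve_michaelis_menten(pw.with_(reactions=tuple(faster))).J_star >= base
    assert solve_michaelis_menten(pw.with_(s_tot=2 * pw.s_tot)).J_star >= base

    pwt = fixture_pathway(2, 3, RateLawKind.THERMODYNAMIC)
    jt = solve_thermodynamic(pwt).J_star
    more_force = pwt.with_(sn=pwt.sn / 10.0)
    assert solve_thermodynamic(more_force).J_star > jt


def test_weighted_budget_equals_effective_kcat_rescaling():
    """A weighted budget sum w_i eps_i <= eps_tot matches the plain solve
    with kcat_i/w_i after un-scaling the enzyme levels."""
    w = (2.0, 0.5, 1.5)
    kcat, ks, keq = [1.0, 2.0, 1.5], [1.0, 0.5, 2.0], [2.0, 1.0, 3.0]
    pw = PathwaySpec(reactions=reactions_from_arrays(kcat, K_S=ks, K_eq=keq),
                     s0=5.0, sn=1.0, eps_tot=1.0, enzyme_weights=w)
    st = solve_mass_action(pw)
    assert float(np.dot(w, st.eps_star)) == pytest.approx(1.0, rel=1e-12)
    # effective-kcat construction: eps'_i = w_i*eps_i with kcat'_i = kcat_i/w_i
    # (so alpha, beta, gamma all pick up the weight factor)
    kcat_eff = [k / wi for k, wi in zip(kcat, w)]
    pw_eff = PathwaySpec(reactions=reactions_from_arrays(kcat_eff, K_S=ks, K_eq=keq),
                         s0=5.0, sn=1.0, eps_tot=1.0)
    st_eff = solve_mass_action(pw_eff)
    assert st.J_star == pytest.approx(st_eff.J_star, rel=1e-12)
    np.testing.assert_allclose(st.eps_star * np.asarray(w), st_eff.eps_star, rtol=1e-12)
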
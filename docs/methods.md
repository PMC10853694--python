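# Methods

## Problem and conventions

All solvers treat the same object: an unbranched chain of n uni–uni
reactions at steady state (equal flux J through every step), with one
dedicated enzyme per reaction. The basic optimization maximizes J subject
to the enzyme budget Σ w_i ε_i ≤ ε_tot; some variants add a bound on the
total free-metabolite concentration Σ s_i ≤ s_tot (an osmotic/crowding
proxy) or a joint density bound a·Σε + b·Σs ≤ ρ. Because every rate law is
linear in its enzyme level, flux maximization is equivalent to minimizing
the total enzyme demand at unit flux, Σ w_i d_i(s) with
d_i = 1/(rate per unit enzyme); all solvers work in that form and convert
back via J* = ε_tot/Σ w_i d_i(s*), ε*_i = J*·d_i(s*).

Units are deliberately agnostic: ε may be a molar or a mass concentration,
with kcat read as a turnover number or a specific activity respectively;
the code only requires consistency and never converts. The driving force
θ = ln(K_eq s/p) is dimensionless (RT dropped). A zero product
concentration maps to θ = +∞ and a thermodynamic efficiency of 1 rather
than an error, so irreversible limits are first-class inputs. Weighted
enzyme budgets are absorbed into effective turnover numbers kcat_i/w_i
before optimization and the reported ε are un-scaled afterwards;
metabolite weights are supported only as the uniform b of the joint
density constraint.

## Analytic solvers

* **Trivial** (saturated, irreversible): d_i = α_i = 1/kcat_i. Turnover
  times are additive along the chain, like series resistors; the pathway
  specific activity is 1/Σα_i.
* **Michaelis–Menten** with metabolite bound: minimizing Σw_i(α_i + β_i/s_{i−1})
  under Σs = s_tot gives s*_{i−1} ∝ √(w_iβ_i) and
  d_i = α_i + √(β_i/w_i)·Σ_j√(w_jβ_j)/s_tot (for unit weights:
  d_i = α_i + √β_i·Σ_j√β_j/s_tot). Without the bound the demand
  decreases monotonically in every s, so the "optimum" is the saturated
  limit s → ∞, which is not a realizable state (its control coefficients
  are undefined); the solver raises a dedicated error, with an explicit
  opt-in to obtain the limiting (trivial-law) numbers flagged as a limit.
  With a fixed upstream s₀, reaction 1 contributes the constant demand
  α₁ + β₁/s₀ and only the downstream substrates enter the square-root
  allocation; free boundary metabolites count toward s_tot, fixed ones do
  not.
* **Thermodynamic**: splitting θ_tot across reactions by a Lagrange
  multiplier gives θ*_i = 2 asinh(√(Ψα_i)) where Ψ solves
  θ_tot = 2Σ asinh(√(Ψα_i)). The left side is strictly increasing in Ψ, so
  the root is unique; it is found by bracket expansion (upward doubling
  from [1e−12, 1], downward widening if needed) followed by Brent's method
  on ln Ψ, to relative residual below 1e−12. The identity
  1/(1−e^(−θ*_i)) = (1 + √(1 + 1/(Ψα_i)))/2 connects the Ψ-form of the
  demands to the direct form; internal concentrations are reconstructed
  from the per-reaction K_eq chain, and the allocation itself depends on
  the equilibrium constants only through their product. The closed-form
  approximation J ≈ (ε_tot/‖α‖₁)(1 − e^(−(‖α‖₁/‖α‖₁/₂)θ_tot)) is exact in
  both driving-force limits; across θ_tot ∈ [0.1, 10] and chains up to
  n = 8 the tests bound its error by 5% (observed worst ≈ 2.6%).
* **Mass-action**: in the transformed coordinates t_i = s_i·∏_{r≥i}K_eq_r
  the chain becomes a resistor ladder with drops t_{i−1} − t_i ∝ √(w_iγ_i),
  hence ε*_i ∝ √γ_i and J* = ε_tot(s₀K_eq,tot − sₙ)/‖γ‖₁/₂. Flux is linear
  in s₀ (no saturation), falls as 1/n² for identical-γ chains, and an
  a-fold kcat improvement lowers that enzyme's optimal share only by √a.

Several printed forms of these solutions are typographically ambiguous in
their radicals; the forms implemented here are the ones that follow from
the Lagrangian derivations, and the convex optimizer below is the arbiter:
the test suite requires every analytic solver to match it to relative 1e−6
on 100 seeded random pathways per law (n = 1..8) before the forms are
trusted.

## Convex solver and steady states

The Haldane law has no known closed-form optimum, so `numopt` minimizes the
demand objective over the log-concentrations x_i = ln s_i of the free
metabolites — the objective is convex in x, and the density constraint
Σ exp(x_i) ≤ s_tot is convex too. The implementation uses SLSQP
(ftol 1e−14) from up to three neutral starting points (equal
driving-force drops in t-space, log-linear interpolation between the
boundaries, equal shares of 0.9·s_tot), keeps the best feasible result,
and then Newton-polishes the stationarity conditions (with the bound's
multiplier as an extra unknown when the constraint is active) via a hybrid
root solver. The polish is accepted on a measured reduction of the KKT
residual, not on the solver's success flag, which is pessimistic at full
convergence. Divergence toward the Michaelis–Menten paradox (no bound) is
detected up front and raised as an error rather than chased numerically.
An exhaustive log-grid oracle (≤ 3 free metabolites) provides an
independent brute-force check: the convex solution must never be worse and
must lie within one grid cell.

Steady states at given enzyme levels use closed forms where they exist
(mass-action: linear chain; Michaelis–Menten: sequential inversion from the
fixed s₀, naming the bottleneck reaction if capacity is insufficient),
a bracketed root of ∏(1 − J/(ε_i kcat_i)) = sₙ/(s₀K_eq,tot) for the
thermodynamic law, and ODE relaxation (LSODA on d ln s/dt with doubling
horizons, convergence when the rate spread falls below 1e−9 relative)
plus a Newton polish for the Haldane law. Stability is assessed from the
central-difference Jacobian of the internal-metabolite dynamics
(relative step 1e−6); eigenvalue real parts within ±1e−10 are flagged
marginal.

## Control analysis

Elasticities are analytic partial derivatives of each rate law (the same
routines back the convex solver's gradients), giving the bidiagonal matrix
E_{j,i} = ∂v_j/∂s_i. Control coefficients are computed from the
stoichiometric and elasticity matrices: C^s = −(N E)⁻¹N and
C^J = E C^s + I, reported in the reaction-scaled convention
(C^J_l = (∂J/∂ε_l)ε_l/J sums to 1; C^{s_i}_l = (∂s_i/∂ε_l)ε_l/J sums to 0
over l). This route reaches machine precision, which matters because the
theorem residuals are asserted at 1e−9; an independent finite-difference
implementation (central differences with one Richardson step) is kept for
cross-checks. For the trivial law, and for the Michaelis–Menten chain
without a fixed upstream concentration, control coefficients are not
defined and a typed error is raised instead of NaNs.

At plain-budget optima the enzyme-control rule ε*_l = ε_tot·C^J_l and the
enzyme-elasticity rule Σ_j ε_j E_{j,i} = 0 are verified to 1e−6 and shown
to fail under 10% perturbations (the rules discriminate). Under the joint
density constraint, the generalized rule
ε*_l = ε*_tot·C^J_l − J*(b/a)Σ_i C^{s_i}_l holds with the per-flux
concentration-control convention above; its derivation uses the
concentration-control summation theorem Σ_l C^{s_i}_l = 0, and it is
checked at 1e−5 against optima of the density solver (which maximizes
J(s) = (ρ − bΣs)/(aΣd(s)) directly — a ratio of concave over convex, so it
is polished by a derivative root as well). The rule is implemented for
uniform weights a and b only; heterogeneous per-molecule weights are out
of scope.

## Cell model

The three-sector cell is literally the fixed-s₀ Michaelis–Menten pathway
with n = 3; the Monod law is derived, not assumed, and the test suite
asserts the growth curve equals the allocation optimum to 1e−8 across the
nutrient range. s_sugar is an environmental parameter excluded from the
internal metabolite budget. Because transport is irreversible, the optimal
cytoplasmic metabolite levels are independent of the nutrient, so the
metabolic and ribosomal sectors are exact lines through the origin in μ;
the sector routine evaluates those analytic slopes rather than
re-optimizing per μ (re-optimization is used only as a test oracle). The
saturated transporter's minimal abundance is μ_max/kcat_t — the
transporter's own turnover number, the only choice consistent with the
steady state. The thermodynamic growth variant
μ = μ_max(1 − (A/s)^B) follows from the driving-force approximation with
θ_tot = ln(s/A); the mass-action variant is exactly linear in the nutrient,
so the growth-law constructor refuses to produce Monod parameters for it.
Growth dilution of intermediates, overflow metabolism and multiple carbon
sources are outside the model.

## Synthetic data

The fixture generator draws kinetic constants log-uniformly (kcat ∈ [1, 100],
K_M ∈ [0.01, 10], K_eq ∈ [0.1, 1000]) and constructs boundary
concentrations so the overall driving force is uniform in [0.5, 10] —
feasible by construction, spanning near-equilibrium to strongly forward
chains. Michaelis–Menten fixtures carry a metabolite budget of one
concentration unit per reaction. Generation is deterministic under the
seed. These fixtures emulate the *spread* of kinetic constants in
enzyme databases, not their correlations (e.g. kcat/K_M couplings),
regulation, or measurement noise; passing the oracle-equivalence and rule
tests therefore demonstrates mathematical correctness of the solvers
across parameter scales, not predictive accuracy for any real pathway.

## Numerical choices and limitations

Tolerances: Haldane-relationship consistency 1e−9 relative; Ψ residual
1e−12; oracle equivalence 1e−6 (absorbs solver noise); theorem residuals
1e−9; generalized rule 1e−5 (limited by the derivative-free density
solver). Degenerate n = 1 pathways are handled by every code path and used
as smoke tests. Branched networks, moiety conservation, regulation with
varying effector levels, scaled (logarithmic) control coefficients and
stochastic kinetics are out of scope. Multi-substrate reactions are
supported only through the reduction of bi-bi convenience kinetics with
fixed co-reactant concentrations to effective uni–uni constants
(kcat⁺' = kcat⁺(b/K_B)/(1+b/K_B), K_S' = K_S(1+b/K_B+q/K_Q)/(1+b/K_B),
symmetrically for the product side, K_eq' = K_eq·b/q), which reproduces
the full rate exactly for all free substrate/product values.
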
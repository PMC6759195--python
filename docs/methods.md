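# Methods

`kfitlab` implements a two-step pipeline for parameterizing mechanistic
kinetic models of metabolic networks from ¹³C labeling data: flux
elucidation by ¹³C metabolic flux analysis (MFA) on a stoichiometric
model with atom mappings, followed by kinetic parameterization of the
*same* network against the elucidated flux distributions.  This note
records the models, the numerical choices, and what the synthetic test
harness does and does not demonstrate.

## 1. Flux elucidation (¹³C-MFA)

**Model.** Intracellular fluxes `v` satisfy `S v = 0` over the internal
metabolites.  The flux space is parameterized as `v = v0 + N α`, where
`N` is an orthonormal null-space basis of the internal stoichiometry
augmented with equality rows pinning the glucose uptake to the 100-unit
basis (all fluxes are mmol per 100 mmol wild-type glucose uptake) and
fixing knocked-out reactions to zero.  Reversible reactions carry an
additional exchange flux `ξ ∈ [0, 200]`; directional fluxes are
`fwd = max(v,0)+ξ`, `rev = max(-v,0)+ξ`.  Irreversibility enters as the
linear constraint `v_i ≥ 0` and fluxes are boxed at ±1000 units.

**Labeling simulation.** Isotope propagation uses elementary metabolite
unit (EMU) decomposition: the minimal set of EMUs reaching the measured
fragments is traced backwards through the atom maps, condensations
become convolution nodes, and the MIDs solve cascaded linear systems
blocked by EMU size.  Symmetric metabolites are expressed as weighted
atom-map variants (e.g. two 0.5-weighted mappings).  Measured MIDs are
assumed corrected for natural isotope abundance.  The package carries an
independent reference simulator (`kfitlab.isotopomer`) that integrates
the full 2^n positional-isotopomer system to steady state; EMU results
match it to < 1e-9 on all fixture networks, and MIDs are invariant under
global flux rescaling (both properties are tested).

**Fitting.** The objective is the variance-weighted SSR of simulated
minus measured MIDs plus measured-rate residuals.  Each of the randomly
initialized multi-starts (default 100) samples a feasible `α` uniformly
inside its LP-derived bounding box and minimizes SSR with SLSQP under
the linear feasibility constraints.  Two optima count as the same
solution when every net flux agrees within `max(0.1 unit, 1%)`; a fit is
accepted only when at least 50% of starts converge to the best solution.

**Confidence intervals.** Profile likelihood: for each reaction the flux
is pushed to its extremes subject to `SSR ≤ SSR* + χ²₁(0.95) = SSR* +
3.84`.  A per-reaction SD for downstream weighting is derived as
`(CI_hi − CI_lo) / (2·1.96)`.  On a single-split network where the
response is linear in the free flux the profile interval matches the
closed-form regression interval within 5%; over repeated noise
realizations the fitted SSR concentrates at its χ²(DOF) expectation
(DOF = measurements − free fluxes) and the 95% interval covers the truth
at near-nominal rate (40–60 replicates in the tests; thresholds 0.85 ≤
mean SSR/DOF ≤ 1.15 and coverage ≥ 0.87 allow ~3σ of binomial noise).

**Flux projection.** Distributions elucidated on one network are
projected onto another by a linear program minimizing the total absolute
excursion outside the source 95% confidence intervals subject to steady
state on the target — used when a reduced network supplies the flux
data.

## 2. Elementary decomposition and anchoring

Every enzyme-assigned reaction becomes an ordered-sequential mechanism:
substrates bind one at a time (declared binding order, stoichiometry
declaration order by default), one conversion step releases the first
product, and remaining products are released in order; a uni-uni
reaction is `E + A ⇌ EA ⇌ E + P` (2 steps, 4 rate constants).  Biomass
precursor drains decompose as single-substrate mechanisms whose
conversion step returns free enzyme.  Inhibitions add dead-end steps:
competitive inhibitors bind free enzyme, uncompetitive inhibitors the
terminal substrate-loaded complex, noncompetitive both (so a
noncompetitive regulation contributes 4 inhibitor constants, and the
constant count per regulation mix is exposed via
`ElementaryNetwork.counts()`).

The free parameters are the wild-type fractional abundances `e` of each
enzyme's complexes (simplex per enzyme, bounds 1e-3 < e < 1) and the
reverse elementary flux `v_r ∈ (0, 1e4)` of every step at the wild-type
state.  Concentrations are scaled so every wild-type concentration is 1
(boundary species stay fixed at 1 in mutants; absolute units enter only
through metabolomic scaling of Km/Vmax).  Anchoring assigns each
main-path step the reaction's net flux (series mechanism; dead-end
inhibitor steps carry zero net flux), so the forward flux is
`v_net + v_r` and

    k_fwd = (v_net + v_r) / e_in ,   k_rev = v_r / e_out ,

making the wild-type training distribution an exact steady state by
construction (`anchor ∘ steady_state` is the identity, tested to 1e-8).
`v_net + v_r ≤ 0` is rejected; derived constants must stay below 1e6.

## 3. Steady-state evaluation

Mutant states (enzyme levels scaled per enzyme; knockout = level 0) are
found by iterative decomposition: at fixed metabolite concentrations
each enzyme's complex balances are *linear* and solved exactly (with the
free-enzyme row replaced by the conservation Σe = level); a damped
Newton step in log-concentration space then drives the metabolite
balances to closure, with the Jacobian obtained analytically by implicit
differentiation of the per-enzyme linear solves.  Newton steps are
capped at 5 log-units per coordinate and halved on residual increase
(up to 40 halvings); the iteration budget is 10,000 but convergence
typically takes < 20 iterations.  A state is converged when every
metabolite balance residual is below 1e-6 flux units; concentrations
crossing 1e9 raise a clean `Unstable` signal and stalls raise
`NonConvergent` — both mean "discard this parameter set/start".
Local stability is judged from the eigenvalues of the analytic
linearization projected off the enzyme-conservation null space
(tolerance 1e-9 on the leading real part).  The solver agrees with
long-time stiff (BDF) integration of the full mass-action ODE system to
within 1e-6 on every flux and concentration across 25 random stable
parameter sets (tested); metabolites floating to large values behind a
knockout (dead branches) are permitted and flagged in the output.

## 4. Outer parameterization (kinetic fitting)

**Training data.** Mutant flux distributions are rescaled to the
wild-type basis by the ratio of absolute glucose uptakes, and weighting
SDs follow the floor rule `SD = max(1.0, 0.05 |v|, SD_MFA)` so narrow,
small fluxes are not over-weighted.  An exclusion list removes
unresolvable fluxes from the residual set.

**Search.** Optimization variables are per-enzyme softmax logits for `e`
and `log(v_r − v_min)` for the reverse fluxes, where `v_min = max(0,
−v_net)` keeps forward fluxes positive under negative wild-type flux.
Each multi-start draw takes `e` from a flat Dirichlet (clipped to the
1e-3 bound) and `v_r` log-uniform over one to ~300 flux units — the
scale of the data's net fluxes on the 100-unit basis; drawing across the
full (1e-3, 1e4) bound range is available via `vr_log_range=(-3, 4)` but
lands in productive basins far less often, so the flux-scaled default is
the package's choice for desk-scale recovery.  The local search is a
Levenberg–Marquardt loop on the weighted residuals with *analytic*
Jacobians (implicit-function steady-state sensitivities chained through
the anchoring equations), per-component steps capped at 10, soft hinge
penalties (weight 10, log scale) enforcing the `e`, `v_r` and `k`
bounds, and failed inner evaluations treated as rejected steps (damping
×10).  On stalls the damping is reset (up to 8 times) as long as the
previous round improved — empirically this converts near-basin stalls
into full convergence.  Termination: gradient maximum < 1e-6, or three
consecutive relative improvements < 1e-8 after resets are exhausted.

**Acceptance.** The best model is accepted when at least one other local
minimum lies within 10% of its SSR and it yields stable steady states
for the requested validation perturbations.  The recovery rate is the
fraction of starts whose mean squared deviation of predicted fluxes from
the best model is ≤ 0.05 per reaction flux.  Leave-one-out
cross-validation refits without one strain, accumulating starts until
the SSR beats the full fit or the recovery rate drops below the full
fit's, then reports the held-out strain's prediction SSR and uptake.

## 5. Downstream analyses

**King–Altman.** Steady-state rate laws are derived per mechanism by
spanning-tree enumeration on the enzyme-complex multigraph (every step
contributes a forward and reverse directed edge; binding edges carry
their metabolite concentration).  Complex fractions are sums over trees
directed toward each complex; the net rate follows from the conversion
step.  After normalizing the coefficient of the full substrate monomial
to 1, *each distinct denominator term* is reported as one Km parameter
and the forward numerator coefficient times total enzyme as Vmax.
Derived laws match the numeric complex-balance solve to < 1e-8
relative error at random constants and concentrations, and reduce
symbolically to their uninhibited forms at zero inhibitor concentration.

**Sensitivities.** The Jacobian `J = ∂r/∂k` of the (unweighted) flux
residuals with respect to all elementary constants is computed
analytically (validated against central differences); `H = J'WJ`,
covariance = pseudo-inverse of `H` with singular values below
1e-10·σ_max treated as null directions (rank deficiency is structural:
each `k` is a ratio of two anchoring variables), `SD = sqrt(diag)`,
`CV(%) = 100·SD/|k|`.  Parameters with weight in the null space are
reported as unidentifiable.  The covariance with respect to the
optimization variables themselves can be obtained by passing the
corresponding transform Jacobians to the same machinery.

**Regulation essentiality.** Each regulation's inhibitor binding step
yields an association constant `ka = k_fwd/k_rev`; its SD follows by the
delta method from the covariance of the two constants.  A regulation is
nonessential when `value − SD ≤ 0` (one-SD range reaching zero) for all
of its binding steps.

**Km/Vmax ranges.** Within all models whose SSR is within 10% of the
optimum, each Km term is scaled to absolute units by the wild-type
concentrations of the metabolites missing from its monomial, evaluated
with every scaling concentration one SD below and one SD above its
metabolomic mean; the range is the min/max over that model-by-extreme
grid.  Parameters lacking metabolomic data are skipped and logged.
Elementary-constant ranges are mean ± SD across the same models.

**Perturbation and yields.** An x-fold gene-expression change is
modeled as an x-fold enzyme-level change (0 = knockout).  Yield is the
target reaction flux divided by the glucose uptake flux in the perturbed
state (mol/mol); target reactions are explicit user inputs (proxy drains
are expected to overpredict), and percent overprediction is
`100·(pred − exp)/exp`.

## 6. Synthetic study conditions

The toy generator builds carbon-balanced atom-mapped networks: an uptake
reaction for a 3-carbon substrate, `n` branch motifs each offering two
parallel 2-step routes (one permuting carbons 2 and 3, so partial
fragments make the split identifiable under a [1,2-¹³C] tracer), a
terminal cleavage into 2- and 1-carbon biomass precursors with sink
drains, and seeded placement of one regulation per inhibition mode.
Defaults: 2 branch points → 12 reactions, 10 metabolites, 3 single-
enzyme-knockout strains (alternating branch routes) — small enough that
the full suite runs in minutes, large enough that knockouts re-route
flux.  Ground truths sample `e` from Dirichlet(2) and `v_r` log-uniform
over 0.1–300 flux units and are accepted only when the wild type and
every planned knockout converge to a stable state.  Simulated training
fluxes receive multiplicative Gaussian noise (CV 0.05 by default,
truncated at ±4σ) with SDs set consistently and then floored; simulated
MIDs receive additive Gaussian noise (SD 0.003, the typical precision of
GC-MS mass isotopomer measurements).  All randomness is seeded.

What passing these tests shows: the estimator recovers generating
parameters/fluxes under its own model assumptions, the two independent
simulation routes agree, and the rule set (weighting, acceptance,
essentiality) is implemented exactly.  What it does not show: robustness
to model misspecification (wrong atom maps, missing regulations,
non-ordered mechanisms), natural-abundance or measurement-bias effects
in real MS data, or the multimodality scale of genome-sized networks,
where recovery rates below 1% per start are expected and cluster-scale
multi-start counts (hundreds, as in the original study design) are
required.

## 7. Problem sizes used in the shipped checks

Toy network (12 reactions / 10 metabolites / 3 regulations / 3 knockout
strains); 20 kinetic multi-starts for recovery; 25 parameter sets for
solver-vs-ODE equivalence; 40–60 noisy replicates for the MFA
statistics; 2–10 MFA multi-starts per fit.  These sizes were chosen so
the whole suite runs on a single CPU in well under half an hour while
every check retains enough replication to be statistically meaningful.
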
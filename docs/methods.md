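# Methods

## The model family

`endodiff` models the five-day directed differentiation of induced
pluripotent stem cells (iPSCs) into definitive endoderm (DE) as a small
compartmental ODE system for spatially homogeneous population densities
(cells/mm² of growth surface). A candidate model combines three
independent choices — 3 × 3 × 3 = 27 candidates in total:

**Lineage.** How many discrete states lie between iPSC (`ns`) and DE
(`nd`), both defined by CD117/CD184 flow-cytometry gates, plus a
cumulative dead-cell pool (`nq`):

- `M1`: direct differentiation (states `ns, nd, nq`);
- `M2`: one pooled single-positive transition state `nt`;
- `M3`: two parallel transition states `nt1` (CD117⁺/CD184⁻) and `nt2`
  (CD117⁻/CD184⁺).

Divisions are symmetric: a dividing cell of state *j* produces two
daughters that either both stay in *j* (probability *p*, "self-renewal")
or both advance to the next state (probability 1 − *p*). With per-capita
division rate *b_j(n_j) = β_j f(n_j)* this gives the per-capita
differentiation rate *2(1 − p) b_j(n_j)*. Death is first-order with
constant rate *δ_j* and feeds the monotone dead pool. For M1:

    dns/dt = b_s ns − δ_s ns − 2(1 − p_sd) b_s ns
    dnd/dt = b_d nd − δ_d nd + 2(1 − p_sd) b_s ns
    dnq/dt = δ_s ns + δ_d nd

M2 chains a transition compartment between `ns` and `nd`; M3 splits the
transition flux with branching probability *p_t1*. Rates are assumed
independent of medium composition (the protocol holds nutrients and
growth factors in excess).

**Growth law.** The per-capita growth factor *f(n)* is exponential
(*f = 1*), logistic (*f = 1 − n/n_max*) or Gompertz (*f = ln(n_max/n)*),
with a single shared carrying capacity *n_max* (cells/mm²) for the
saturating laws, each compartment crowding against its own density.

**Error model.** Observations are Gaussian around the model mean *g*
with standard deviation ε: additive (*ε = a*), proportional
(*ε = b·g*) or combined (*ε = a + b·g*). The error parameters are
inferred jointly with the structural ones.

Parameter counts: M1/M2/M3 carry 5/8/12 structural parameters under
exponential growth, +1 (*n_max*) for the saturating laws, +1 or +2 error
parameters.

### Reference parameter set

The package ships the maximum-likelihood estimates (and 95% profile
confidence intervals) of the Gompertz M1 model with combined error
inferred from the in vitro study it models (`model_core.REFERENCE_PARAMS`):
β_s = 10.119 d⁻¹, p_sd = 0.498, δ_s = 0.522 d⁻¹, β_d = 0.188 d⁻¹,
δ_d = 0.473 d⁻¹, n_max = 718.6 cells/mm², a = 116.5 cells/mm², b = 0.343.
These are the defaults for the synthetic-study generator, the sensitivity
analysis and the protocol scans.

## Numerical choices

- **Integration.** `scipy.integrate.solve_ivp` (RK45) at rtol 1e-8 /
  atol 1e-10 is the reference route. A numba-compiled Dormand–Prince 5(4)
  integrator plus likelihood kernel provides the hot path used inside
  optimization loops, Sobol sampling and scans; a regression test pins the
  two routes together below 1e-6 relative. Runaway steps (blow-up with
  out-of-bound parameters) are flagged, never silent.
- **Gompertz at n → 0.** The growth term *n·ln(n_max/n)* → 0; the log is
  evaluated with *n* floored at 1e-12 so it never overflows.
- **Nonnegativity.** States are clipped to 0 when rates are evaluated,
  and the derivative of a nonpositive state is floored at 0 (projection).
  The projection matters above carrying capacity, where the
  symmetric-division transfer rate *2(1 − p) β f(n)* turns negative: without
  it an empty compartment integrates to a persistent negative "debt" and
  trajectories depend on where the integrator restarts (the ROCK-inhibitor
  scenario restarts at the exposure boundary). Above-capacity dynamics
  should still be read with care: the negative transfer rate is a model
  artifact of the symmetric-division construction, and the package's
  defaults keep day-0 states below capacity.
- **Likelihood.** −2ℓ = Σ (z − g)²/ε² + Σ 2 ln ε, up to the constant
  m·ln 2π. A floor σ_min = 1e-6 cells/mm² prevents infinite weights when a
  proportional error model meets a zero mean; floor activations are counted
  and reported. Replicate initial conditions are fixed to day-0
  measurements (day-0 rows never enter the sums); all parameters are pooled
  across replicates.
- **Search space.** Rates in [1e-4, 1e2] d⁻¹ and n_max in
  [n_max_u/25, n_max_u] are searched in log10; ratios in [0, 1] and error
  parameters (a ∈ [0, n_max_u], b ∈ [0, 10]) linearly. n_max_u ≈ 5658.8
  cells/mm² is a confluent monolayer of 15-µm circular cells. The bounds
  for a and b are the package's own choice (generous boxes covering the
  reference estimates); no principled prior bound exists for them.
- **Optimization.** Multistart: Latin-hypercube start points
  (`scipy.stats.qmc`, random-cd optimized), each start running a
  differential-evolution phase (rand/1/bin, dithered mutation ∈ [0.5, 1],
  recombination 0.9) followed by Nelder–Mead polish. A second simplex
  descent starts from the raw start point: the likelihood surface has a
  broad shallow ridge attractor (small β_s, large n_max, p_sd slightly
  below ½) separated by a barrier from the narrow, deep generating basin,
  and the DE population is often captured by the ridge while a direct
  simplex walk can follow the curved valley into the needle. `budget` is
  the approximate number of objective evaluations per start (split
  50/25/25 across the three phases); package default 100 000 with 100
  starts, scaled down in tests (budgets 800–8000, 16–25 starts) to keep the
  full 27-model study at desk scale.
- **Model selection.** Candidates are compared by BIC = k·ln(m_s) − 2ℓ
  where ℓ = −LOCS/2 on the held-out selection set and LOCS is the loss over
  common states (`ns`, `nd`, `nq`) — the observables every lineage shares —
  so that wider lineages are not judged on states only they observe. m_s
  counts individual (replicate, time, state) selection records over common
  states; the count is reported so alternative conventions are auditable.
  The dropped m·ln 2π constant cancels in rankings. Stratified splitting
  assigns whole time points (all states together) of each replicate to
  train/select/test at 3/1/1.
- **Profile likelihood.** PL(ψ) re-maximizes ℓ over the remaining
  parameters on a grid (21 points per side, ±1 decade for log-scale
  parameters, full [0, 1] for ratios), warm-starting each inner
  optimization from the neighbouring grid point and extending the grid
  adaptively until the threshold ℓ_max − χ²₁(0.95)/2 ≈ ℓ_max − 1.921 is
  crossed or the search box is hit (then the CI is unbounded and the
  parameter flagged non-identifiable). The ½ on the χ² quantile is the
  standard likelihood-ratio construction on the ℓ scale. CI endpoints are
  linearly interpolated between grid points.
- **Local structural identifiability.** A numerical local surrogate for a
  global differential-algebra analysis: central finite-difference
  sensitivities of every observable at every output time w.r.t. each
  structural parameter, scaled to relative sensitivities, stacked, and
  rank-tested via SVD (threshold 1e-8 × largest singular value). Full rank
  ⇒ locally identifiable at that point. This is deliberately weaker than
  the global symbolic analysis it stands in for, and is labelled as such.
- **Sobol sensitivity.** `scipy.stats.sobol_indices` (Saltelli 2010
  estimators over Sobol' quasirandom matrices). `n_samples` counts total
  model evaluations; the base sample is the largest power of two with
  n·(d+2) ≤ n_samples (40 000 requested ⇒ 4096 × 8 = 32 768 evaluations at
  d = 6). Default bounds are the reference 95% CIs with negative rate
  bounds clipped to 0 (a rate cannot be negative). Failed integrations are
  counted and mean-imputed; above 1% the run aborts.
- **Design study.** The sampling-period design simulates the assumed
  model, adds multiplicative noise N = n(1 + ε·η), refits, and scores
  e = ‖Θ̂ − Θ*‖₂/‖Θ̂‖₂ over structural parameters. Because the noise level
  is chosen by the designer, the fit pins the proportional error
  coefficient to ε (floored at 0.01 so the noise-free case keeps finite
  weights and negligible shrinkage bias) — weighted least squares with the
  correct weights. One noise realization per period by default.
- **Derived outputs.** T_max is the earliest time on a 0.01-day grid
  attaining the DE-density maximum; yield per input cell = n_d(T_max)/n_p;
  DE ratio = n_d/(n_s + n_d) at T_max. The ROCK-inhibitor scenario scales
  (δ_s, δ_d) by (m_s, m_d) on [0, τ] and restarts the integrator at τ with
  a continuous state.
- **Durbin–Watson.** `statsmodels` implementation; residuals ordered by
  replicate id, then time, then (ns, nd, nq). The ordering is a convention
  (configurable), as the statistic depends on it.

## The synthetic-study generator

`synthetic_data.generate_study` emulates the measurement design of the in
vitro study: two plating populations (900 000 and 300 000 cells per well
of a 12-well plate, 380 mm²/well) with 4 and 2 replicates, daily sampling
over five days, live states gated by CD117/CD184 plus the cumulative dead
count. Per replicate:

1. the day-0 state comes from an affine plating map with multiplicative
   Gaussian scatter (10% relative) — the scattered state itself is the
   day-0 record, because the pipeline anchors each replicate's trajectory
   to its day-0 values and excludes them from the likelihood;
2. the generating model (default: Gompertz M1 combined error at the
   reference estimates) is integrated;
3. days ≥ 1 are observed through the error model, with negative draws
   clipped to 0.

The default plating map attaches 25% of plated cells by day 0, 90/10
between the iPSC and DE gates. The fraction is set so that every default
day-0 density stays below the reference carrying capacity: above it the
saturating growth laws suppress differentiation and the model's protocol
predictions (DE peak rising with plating population, T_max ≈ 2 days)
no longer hold, so the study's real day-0 densities must also have been
below capacity. All map parameters, scatter, days, replicate counts and
the generating model are configurable.

**What the generator does not emulate.** Flow-gating misclassification,
counting (Poisson-type) noise, batch effects between replicates beyond
day-0 scatter, lysed dead cells escaping the dead count, and
medium-composition dynamics. Passing recovery tests on this generator
therefore show the inference machinery is correct under the model's own
assumptions — not that the model is correct for real cultures.

**Known limitation — clipping bias.** At the reference noise scale
(a ≈ 117 cells/mm², b ≈ 0.34) the Gaussian error model puts substantial
mass below zero wherever means are small; clipping shifts those means
upward and halves their spread. Fits to clipped data systematically
underestimate the additive error floor `a`, and the clipped zeros make
small-`a`/large-`b` modes artificially attractive. Monte-Carlo mean
checks in the tests use a small-noise configuration where clipping is
negligible.

**Known limitation — practical identifiability at the study scale.** At
the reference noise level and study size (6 replicates × 5 days), the
joint likelihood is multimodal: a broad ridge (β_s ≈ 3, n_max ≈ 2800,
p_sd ≈ 0.46) explains synthetic datasets within a few percent and
frequently beats the generating basin in likelihood. The global MLE
therefore hops between modes across regenerated studies, and single-seed
parameter estimates should not be over-interpreted; the BIC family-level
selection is robust to this (all modes belong to the same lineage).

## Problem sizes

Tests and the acceptance script run the same pipeline at reduced
multistart budgets chosen as the package's own desk-scale defaults: 27
candidates × 25 starts × ~800 objective evaluations for the ranking
study, 20 starts × 2500 for single-model fits, 40 000 model evaluations
for Sobol indices, 0.01-day grids for derived-output scans. The
full-fidelity settings (100 starts, 10⁵ evaluations per start) are the
package defaults for real analyses.
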
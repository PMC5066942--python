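# Methods

## Model equations and assumptions

Cells are well-mixed bags of `k` chemicals on the unit simplex. All
structure lies in the catalytic network `P(i,j,l)` (reaction `X_i → X_j`
catalysed by `X_l` at rate `ε x_i x_l^α`), the diffusibility flags `σ_i`,
and four environmental parameters: exterior nutrient concentration `C`,
medium volume `V_med`, membrane diffusion `D`, and medium–exterior exchange
`D_med` (defaulting to `D`). Growth is identified with net chemical influx,
`μ = Σ_i D σ_i (x_i^med − x_i)`, and the dilution term `−x_i μ` makes
`Σ_i x_i = 1` an exact invariant of the continuous dynamics — the single
most useful correctness probe of the integration (see Numerical choices).
Only the nutrient exchanges with the exterior; other diffusible species
leave cells only into the shared medium, which is what couples the cells.

Assumptions worth keeping in mind: mass-action kinetics with a single
global `ε` and `α`; no reverse reactions; no spatial structure; volume
proportional to total chemical content; the network is identical in every
cell (differentiation is purely dynamical, not genetic).

## The three variants

**N-cell model.** Population simulation with volume growth `dv/dt = μv`,
division at volume doubling, and uniform-random elimination whenever the
population exceeds the carrying capacity `N`. The founder cell has a
uniform-Dirichlet composition (seeded), unit volume, and the medium starts
empty; transients are discarded in all analyses.

**r1cell / r2cell.** One cell, or two cell groups with fixed volume split
`r1 : 1−r1`, volumes pinned (dilution retained), sharing the medium through
`V = V_med / v`. The r1cell initial composition is the uniform vector with
a small antisymmetric perturbation (relative size `split_size = 1e-3`) on
chemicals 1 and 2. This matters: the built-in networks have an exact
1↔2 / 3↔4 exchange symmetry, so the symmetric subspace is dynamically
invariant, and a start exactly on it can never reach an attractor that
lives off it (the phase-III limit cycle would be misread as a fixed
point). The r2cell "small" split applies the same perturbation with
opposite signs in the two groups; the "large" split starts the groups at
type-like compositions (mass concentrated on {X1, X3} and {X2, X4}
respectively) to probe the differentiated branch and the bistable phase.

**Fixed-ratio model.** As r2cell at arbitrary `r1`, initialised from the
large split so the run tracks the differentiated branch; its group-1 growth
rate defines `F(r1)`. The coexistence drift `dr/dt = r(1−r)[F(r) − F(1−r)]`
is built by interpolation on a symmetric grid, and the stability index is
the central difference `[F(1/2+δ) − F(1/2−δ)]/2δ` with `δ = 0.05`, with the
sign confirmed at `δ/2` before being reported. The closed-form expression
for `F′(1/2)` in terms of composition derivatives is not evaluated; the
finite difference is treated as primary and the δ-halving as its
cross-check.

## Parameters and defaults

| symbol | default | meaning |
|---|---|---|
| N | 100 | carrying capacity of the medium |
| k | 6 (built-ins), 20 (ensemble) | number of chemical species |
| α | 2 | catalytic order; differentiation and its payoff need α ≥ 2 |
| ε | 1 | common rate constant |
| C | 0.15 | exterior nutrient concentration |
| V_med | 100 | medium volume (full model) |
| V | — | medium-to-cell volume ratio (reduced models); small V = strong coupling |
| D, D_med | 1, = D | membrane and exterior diffusion coefficients |
| η | 1e-6 | division noise: daughters' compositions multiplied by (1 + ηu), u ~ U[−1,1], renormalised |
| t_max | 1e4 | horizon (reduced and full defaults) |

η exists because two exactly identical daughters would stay identical
forever; 1e-6 is far below every composition scale in the results, so it
only sets *when* differentiation nucleates, not *what* it looks like. The
random ensemble defaults (`k=20`, `ρ=4` outgoing reactions per substrate,
diffusibility probability 0.15, nutrient never a product or catalyst, no
autocatalysis `j = l`, uniform sampling without replacement over the
remaining valid (product, catalyst) pairs) are the study conditions; the
only sampling freedom the ensemble description leaves open — the
distribution over valid pairs — is resolved as uniform, the minimal
assumption.

## Numerical choices

- **Integrator.** `scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-8`,
  `atol = 1e-10`. The simplex deviation stays below 1e-7 in every test run
  at these tolerances (typically ~1e-14). A fixed-step RK4 reference
  integrator is kept in the package and pinned against the adaptive solver
  (relative error < 1e-6 over 100 time units on a two-reaction toy).
- **Division timing.** A cell divides the instant `v = 2 v_birth`, located
  by the solver's terminal event. Checking only at step boundaries looks
  harmless but is not: the overshoot compounds multiplicatively across
  generations into an upward drift of birth volumes (the total cellular
  volume roughly sextupled by t = 3e4 in an early version), which distorts
  the medium depletion and every growth comparison downstream.
- **Divisions-per-cell.** Each cell carries a lineage counter (daughters
  inherit the parent's count plus one); the reported series is the
  population mean, and growth rates are its slope over the final half of a
  run. The alternative — cumulative division events divided by population —
  is biased between capped and uncapped populations: at carrying capacity
  with uniform random elimination the event rate per cell equals μ, while
  an isolated cell divides at μ/ln 2, a structural 1.44× mismatch that
  would contaminate the interacting-versus-isolated comparison. The
  lineage counter divides at μ/ln 2 in both settings.
- **Attractor classification.** Over the final quarter of the sampled
  window: fixed point if every component's range is below 1e-6, limit cycle
  if the range exceeds 1e-3 *and* is not contracting (second half ≥ 0.9× of
  the first half's range); a contracting range below 1e-3 is a fixed point
  still being approached (this covers algebraically slow relaxation, e.g.
  with D = 0 where catalysts deplete as a power law). Otherwise the horizon
  is doubled once, then an unresolved-attractor error is raised.
- **Differentiation.** Per-cell compositions are time-averaged over the
  final half (longer than any observed oscillation period), clustered by
  single linkage in L1 with cutoff 0.1 (differentiated states differ by
  O(1) in L1, so the cutoff is uncritical; it is a reported config knob).
  Clusters below 5% of the population are reported as stragglers rather
  than types — snapshots of a dividing population always contain a few
  transiently intermediate cells, and counting each as a "type" makes the
  type count fragile. The population counts as differentiated when at least
  two major clusters are separated by more than twice the within-cluster
  dispersion.
- **Concentration floor.** After each integration segment concentrations
  are clipped at zero and the clipped mass is accumulated in the trajectory
  diagnostics (zero in all test runs at default tolerances).
- **Category dead band.** The (a)/(b)/(d) boundaries use a 2% dead band
  around R_μ = 1 to absorb estimator noise.

## What the generator and defaults do and do not emulate

The synthetic networks and parameter defaults reproduce the study
conditions: nutrient-limited, well-mixed, strongly coupled populations of
identical cells. Passing tests therefore demonstrate the dynamical
phenomena — interaction-induced differentiation, oscillation death,
cooperative growth in the equal-volume comparison, and the
stable/unstable coexistence dichotomy — under exactly those idealisations.
They say nothing about thermodynamic realism (reactions are irreversible
and unimolecular-with-catalyst), about spatially structured aggregates, or
about networks whose rate constants vary across reactions.

## Problem sizes

Reduced-model runs integrate to t = 1e4 (extended once to 2e4 when an
attractor is ambiguous) and average over the final half. Full-population
runs in the tests use N = 100 to t = 1e4, by which point differentiation is
established and growth statistics are steady; the simplex-conservation
check in the acceptance script uses t = 1e3, ample for hundreds of
divisions. The stability indices use four fixed-ratio runs plus four at
the halved step.

## Known limitations and open edges

- At the full-model worked-example parameters (C = 0.15, V_med = 100,
  D = 1, N = 100) the per-cell division rate of the interacting population
  comes out ~10% *below* the isolated cell's: the 100-cell population
  (total cellular volume ≈ 1.4 V_med) depletes the medium nutrient by
  ~9%, and network 1's division-of-labor gain at this nutrient level
  (+13% in the equal-volume r2cell-vs-r1cell comparison, which is where
  the growth-enhancement ratio R_μ is defined and which this package
  reproduces) does not cover that crowding penalty. The full-model
  interacting-vs-isolated comparison conflates the two effects; the
  reduced comparison isolates the division-of-labor gain.
- The phase-IV bistability boundary is located by simulation from two
  initial splits, not by linear stability analysis; near phase boundaries
  the classification inherits the attractor-classifier tolerances.
- `F(r)` is not probed near r ∈ {0, 1}, where the minority group's
  differentiated state ceases to exist; the default grid is [0.1, 0.9].
- Oscillation-phase comparisons use cross-correlation lags of the most
  variable chemical; for strongly anharmonic waveforms the 5%-of-period
  asynchrony threshold is heuristic.
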
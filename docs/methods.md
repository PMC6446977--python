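# Methods

## Model and assumptions

`plasdyn` integrates a deterministic mass-action model of a well-mixed,
effectively clonal bacterial population in which a single conjugative
plasmid circulates. Three compartments of relative density are tracked:
plasmid-free cells F, non-adapted plasmid bearers P, and adapted bearers
A that carry a compensatory mutation reducing the plasmid's fitness cost.
All growth-linked processes (growth, segregational loss, conjugation,
mutation) are throttled by resource availability
f = 1 − (F + P + A)/k, so the population saturates logistically at the
carrying capacity k.

The assumptions worth keeping in mind:

* **Relative densities.** k = 1 by convention; compartments are fractions
  of the maximum attainable density. Conjugation rates measured in
  absolute units (ml cell⁻¹ h⁻¹) convert by multiplication with the
  absolute capacity (`to_relative_conjugation_rate`), and back by
  division (`adjust_conjugation_rate`).
* **Antibiotics kill only plasmid-free cells.** The plasmid confers
  resistance, and the killing rate υ never exceeds 1 h⁻¹, a range in
  which inhibition of resistant cells is negligible. The model is not
  valid for antibiotic pressures strong enough to inhibit resistant
  bearers too.
* **Compensation affects growth only.** The mutation reduces the growth
  cost α by a factor (1 − β) and, through the growth-coupled segregation
  term, the effective segregation flux; it does not change conjugation
  itself. Mechanisms that ameliorate cost by reducing transfer (e.g.
  T4SS deletions) are outside scope.
* **Determinism.** Mutation is a continuous flux proportional to
  replication events, not a discrete stochastic event. Consequences of
  small-number stochasticity (mutation timing, loss of rare lineages)
  are not represented.
* **Variants are a tag, not separate models.** The chromosomal and
  plasmid-mutation variants share one vector field; they differ only in
  the destination of transconjugants of adapted donors and in the
  transfer-coupled mutation flux f χ γ F P (plasmid variant only). The
  no-mutation baseline is the same field with χ = 0. This makes the
  equivalence properties (identical trajectories at χ = 0; collapse of
  P + A onto the baseline at β = 0) testable by construction.

The transfer-coupled mutation flux is implemented exactly as the
stoichiometry prints it — a P → A correction flow with no effect on F —
rather than as a branching of the conjugation flux; at χ ≪ 1 the two
formulations are numerically indistinguishable.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| k | carrying capacity | 1 | relative density |
| ψ | maximal growth rate | 1 | h⁻¹ |
| α | plasmid cost | 0.2 | fraction of ψ |
| β | amelioration strength | 0.9 | fraction of α |
| ω | dilution/mortality | 0.1 | h⁻¹ |
| υ | antibiotic killing of F | 0 | h⁻¹ |
| τ | segregational loss | 10⁻³ | per division |
| γ | conjugation rate | 0.02 | per (rel. density · h) |
| χ | compensatory mutation | 10⁻⁶ | per replication |

The defaults describe a moderately costly, slowly conjugating,
well-compensated plasmid in a slowly diluted habitat — the kind of
configuration reported for natural isolates — and put the system in the
interesting regime: γ = 0.02 is far below the raw conjugation threshold
γ_low = αψ(1−τ) = 0.1998, but just above the compensated threshold
0.01998, so the fate of the plasmid hinges on compensation and selection.
Under these defaults one generation corresponds to roughly 10 h (a 4,000
h run is ~400 generations); the conversion is display-only and never
enters computation.

## Numerical integration

* LSODA (stiff/non-stiff switching) with an analytic 3×3 Jacobian;
  rtol = 10⁻⁸, atol = 10⁻¹².
* The vector field is never clamped: negative excursions are bounded by
  the solver tolerance and self-correct, because any compartment near
  zero has a locally stable zero in the regimes the scan visits.
  Post hoc, magnitudes below atol are reported as exact zeros.
* Steady state is detected on the exact vector field, not on finite
  differences of output samples: a terminal solver event fires the first
  time max(|dF/dt|, |dP/dt|, |dA/dt|)/k drops below 10⁻⁹ h⁻¹ (for an
  absolute capacity of 10⁹ cells, less than one cell per hour). Runs
  that never meet the criterion before the 10⁷ h cap return
  `converged=False` — a value, not an exception — and are excluded from
  persistence summaries. The cap exists only to terminate pathological
  washout scenarios; in practice all scanned runs converge.
* Persistence means a steady-state bearer fraction strictly above 10⁻³.
  The threshold separates two well-isolated modes: scanned outcomes pile
  up either below 10⁻⁶ or above 10⁻³, with well under 2% of runs in
  between.
* The steady tolerance matters in one specific way: with a looser
  criterion (10⁻⁷) the detector can stop during the quiet phase in which
  F and P have equilibrated but A is still invading exponentially from a
  tiny mutation seed (χ ~ 10⁻⁸), misreporting a persistent run as
  extinct. On a 500-set batch this flips ~1% of verdicts, always in that
  direction; at 10⁻⁹ the invasion keeps the derivative above threshold
  and the runs classify correctly. This is why 10⁻⁹ is the default and
  the classification is treated as stable at that setting.

## Trajectory summaries

`time_to_peak` returns the earliest sampled time at which P + A attains
its maximum, on a dense output grid (≥ 2,000 points; ties broken towards
the earliest time). When the bearer fraction saturates into a plateau
instead of passing through a hump, the strict argmax lands wherever
solver noise happens to peak on the plateau; the optional `rel_tol`
argument instead reports the arrival time at the plateau — the earliest
time within a relative distance of the maximum. The mutation-rate sweep
(χ from 10⁻⁹ to 10⁻³ at υ = 10⁻², both mutation variants) uses
rel_tol = 0.05, i.e. "within 5% of the most prevalent state". Under that
definition the sweep shifts the peak by a roughly constant ~160
generations per six decades of χ (the shift is logarithmic in χ, as
expected for exponential growth from a χ-proportional seed), which
corresponds to a ~3-fold change in the peak time.

`phase_plane` draws random initial (F, P) pairs uniformly with
F + P ≤ k (rejection sampling, seeded), integrates each to steady state,
and confirms that all starts reach the same attractor — the steady-state
results are a property of the parameters, not of the initial state. The
standard initial condition elsewhere is F = P = k(1 − ω)/2, A = 0: half
of the total density the population approaches in steady state.

## The global scan

`run_experiment_II` emulates a broad survey of plausible plasmid–host
pairs and environments: n parameter sets drawn by Latin hypercube over

* ψ ∈ [0, 2] and α, β, ω, γ ∈ [0, 1], uniform;
* υ ∈ [10⁻⁴, 1] and χ ∈ [10⁻⁹, 10⁻³], uniform in log₁₀ (sampling the
  raw scale would over-represent high rates);
* τ = 0.5ˣ with x uniform on [1, 20] — covering 0.5 down to ~10⁻⁶, with
  x interpretable as a plasmid copy number.

Each set is run to steady state under all three variants (the
no-mutation arm forces χ = 0 while keeping the sampled value on record)
and under two regimes: the sampled υ, and υ = 0 with otherwise identical
parameters — a paired design that isolates the effect of antibiotic
selection without re-sampling. The default n is 10,000; the bundled
read-outs and tests use 1,000–5,000, at which scale the persistence
percentages are stable to a couple of percentage points.

What the generator does *not* emulate: correlations between traits (cost
and conjugation rate are drawn independently, though real plasmids trade
them off), temporal fluctuation of υ or ω, multi-species host
communities, and stochastic mutation supply. Passing scan-based tests
therefore demonstrates properties of the deterministic mass-action model
across a broad parameter box — not predictions for any particular
empirical system.

Main-effect curves bin the converged runs of one regime into 20
equal-width bins on the parameter's sampling scale (log₁₀ for υ and χ,
the exponent x for τ); bins supporting fewer than 10 runs for some
variant are merged with a neighbour. Per-bin counts are reported so any
smoother can be applied downstream.

## The amelioration-equivalence read-out

`beta_equivalence` quantifies the headline advantage of plasmid-borne
compensation: the chromosomal variant's persistence percentage is read
off its β main-effect curve at β = 0.75, and the returned value is the
smallest β at which the plasmid variant's curve (linearly interpolated
between bin midpoints) attains that same percentage. Around the
equivalence point both curves are shallow (slopes of order 20–30
percentage points per unit β against a per-bin standard error of ~3
percentage points at 250 runs per bin), so the read-out amplifies bin
noise strongly: at n = 5,000 its sampling standard deviation is about
0.08 in β, and it tightens towards the large-sample value of ≈ 0.25
only for scans in the tens of thousands of sets. Smoothed variants
(monotone or logistic fits of the curves) were considered and rejected:
they either retain the variance or bias the crossing upward by
0.05–0.07. The desk-scale read-out uses n = 5,000 and 20 bins and
should be interpreted with that spread in mind.

## Problem sizes

The bundled test suite integrates single runs over 10²–10⁴ h horizons,
uses a shared 1,000-set scan for the structural and threshold checks and
a 5,000-set scan for the equivalence read-out, and batches of 20–500
random parameter sets for the property tests. `scripts/acceptance.py`
re-runs the χ sweep (6 integrations) and a fresh 5,000-set scan from the
given seed.

## Known limitations

* The conjugation threshold γ_low is an exclusion criterion only;
  the package deliberately does not attempt a full invasion analysis or
  eigenvalue-based stability classification of the fixed points.
* Persistence classification near the detection threshold inherits the
  steady-state criterion's behaviour for slow invasions (see above);
  tolerances looser than 10⁻⁹ h⁻¹ are not recommended.
* The equivalence read-out's seed-to-seed spread at n = 5,000 is about
  ±0.08 in β (one standard deviation); treat single-seed values
  accordingly.
* No stochastic (individual-based) variant, no antibiotic action on
  plasmid bearers, no multi-plasmid or multi-host extensions.
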
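# Methods

## Estimator

The package implements the line-intersect (Van Wagner) estimator. A piece
tallies toward its plot when its central axis crosses a transect; per-plot
volume (m³/ha) and carbon (Mg C/ha) are

```
V_i = pi^2/(8 L) * sum (DI^2 - DH^2) CR
y_i = pi^2/(8 L) * sum (DI^2 - DH^2) CR * BD * DR * CC
```

with diameters in cm, L in m, `BD` in g/cm³ (≡ Mg/m³). No additional unit
constant is needed: the cm²·(g/cm³)/m combination expands to per-hectare
values, which the test suite verifies dimensionally against an independent
closed form. The collapse ratio multiplies the *net* cross-section
`DI² − DH²`, not the gross term.

Tally thresholds: decay classes 1–4 require diameter strictly greater than
7.6 cm and length over 15 cm; class-5 pieces (no longer round) qualify by
extent instead — length over 152 cm with at least 13 cm exposed (the
height bound is inclusive, reading "at least" literally). The estimator
applies the same volume formula to all five classes. Non-qualifying pieces
are silently excluded, since qualification is a field tally rule rather
than a data error. Optional length/height fields, when absent, are treated
as satisfied — the field crew already applied the rule when tallying.

## Error models

All error models are empirical; nothing is fitted parametrically to the
paired data.

- **Continuous variables** (intersect diameter, cavity diameter): the model
  is the pooled list of QA − production differences; a perturbation adds a
  uniformly resampled difference (with replacement, independently per
  piece) to the measured value. Pooling across plots, sizes and classes
  follows QA practice of reporting pooled agreement statistics. The cavity
  model is built only from pairs where both crews recorded a cavity.
- **Class variables** (decay class, species): row-conditional confusion
  tables keyed by the production value, storing QA values with
  multiplicity; a perturbation is a uniform draw over the row, which
  reproduces the empirical conditional distribution exactly. Production
  values never seen in the paired data fall back to the group-level
  (hardwood/softwood) aggregate row for species, and to identity
  otherwise, keeping sampling total without inventing rates.
- **Outlier guard**: pairs disagreeing on diameter by more than 50 cm
  (configurable) are dropped before model building; such disagreements are
  transcription errors, not measurement error.
- **Matching**: a greedy nearest-position matcher (ties broken by diameter
  gap, then tally order) pairs two crews' tallies of one transect within
  position/diameter tolerances. It is deliberately simple plumbing; paired
  tables built by construction (the synthetic generator) or externally are
  the primary input path.

Perturbation rules during propagation: a diameter drawn below the 7.6 cm
tally threshold is clamped to the threshold (the field tally decision is
fixed; pieces are never dropped mid-simulation), configurable to `drop`.
Cavity perturbations apply only to pieces recorded hollow and are clamped
to `[0, DI]`; there is no false-positive/false-negative hollowness model
because blind remeasurements provide no data on it. When the decay class
is perturbed, the piece's collapse-ratio and density-reduction parameters
follow the *drawn* class (nominal values if those sources are inactive,
draws for the new class if active), so class confusion propagates
indirectly into volume. When a species draw crosses the
hardwood/softwood boundary, the carbon-concentration group follows the
drawn species.

## Reference tables and sampling

- **Density**: initial density `BD` is fixed per species; uncertainty
  enters through the reduction factor `DR`, drawn from a normal with the
  tabulated (mean, SE) truncated below at 0 (inverse-CDF implementation).
  The truncated normal is the simplest two-parameter family consistent
  with tables that publish only a mean and SE, and truncation prevents
  negative physical quantities. Resolution is species → genus (unweighted
  mean over congeners present in the table) → hardwood/softwood/unknown
  group default (mean over the group), with the tier recorded per lookup.
- **Collapse ratio**: uniform draws from the pool of observed ratios per
  decay class; the no-uncertainty baseline uses the class pool mean.
  Ratios slightly above 1 are legal (fresh logs can stand taller than
  wide); 1.5 is a sanity cap.
- **Carbon concentration**: 49% (hardwood), 52% (softwood), 51% (unknown)
  with SEs 0.43%/0.42%/0.42%, drawn truncated-normal per piece.

The packaged default density/collapse tables are synthetic fixtures shaped
like the published literature (densities and reduction factors declining
with decay class; collapse medians falling from ~1.0 in class 1 to ~0.5 in
class 5). They keep the package runnable and its outputs in a realistic
range but are not measured data.

## Monte Carlo engine

Each iteration perturbs every piece through the active sources and
recomputes both metrics; inactive sources hold nominal values (measured
value, class-mean CR, mean DR, mean CC). Defaults: 10,000 iterations.
Summaries per plot × configuration × metric: mean, median, quartiles,
2.5/97.5 percentiles (linear-interpolation quantiles, stated explicitly
for bit-reproducibility), IQR, and the 95% CI width `p97.5 − p2.5`. The
cross-plot mean distribution (the per-iteration mean over plots, pseudo-plot
`__mean__`) summarises the landscape the way multi-plot uncertainty figures
do. The no-uncertainty baseline runs the identical code path with every
source inactive and includes collapse and hollowness.

Randomness: a root seed spawns one substream per (plot, iteration) —
`default_rng([seed, plot_index, iteration])` — so results are independent
of plot iteration order and safe to parallelise. With degenerate error
models (all-zero difference pools, identity confusion rows, zero SEs,
singleton collapse pools) every iterate equals the baseline bitwise; this
identity is asserted in the tests.

Attribution runs the engine once with all sources and once per single
source under the same seed policy, tabulating per-source CI widths, their
root-sum-of-squares (quadrature) combination, and the all-sources Monte
Carlo width. For independent, near-linear sources the two agree closely;
the acceptance checks bound the relative gap at 15% on a 50-plot
landscape and observe ~0.3–1.5%.

## Synthetic data generator

The generator defines the study conditions under which the package is
tested:

- 4 × 14.6 m transects (L = 58.4 m); Poisson(6.5) pieces per plot
  (≈ 520 pieces / 79 plots in the motivating inventory);
- diameters lognormal (median 12.5 cm, σ = 0.45 → mean ≈ 14 cm, upper
  tail reaching ~56 cm), rejection-truncated above the 7.6 cm threshold;
- decay-class probabilities (0.07, 0.17, 0.52, 0.22, 0.02), peaked at
  class 3;
- hollowness probability by class (0, 0.023, 0.037, 0.108, 0) —
  concentrated in classes 3–4, ~5% overall — with cavity diameter a
  uniform 0.2–0.6 fraction of DI;
- a 16-taxon species pool (≈73% hardwood including sentinels) mapped to
  the packaged density table;
- crew errors generated in continuous space and then rounded to the
  2.54 cm (1 inch) recording grid, which reproduces the discrete
  difference atoms seen in paired audit data; production diameter SD
  1.3 cm, cavity SD 1.5 cm;
- production decay-class confusion with diagonals
  (0.89, 0.51, 0.77, 0.65, 0.57) and off-diagonal mass biased toward
  class 3; species identification correct with p = 0.79, else the
  unknown-group sentinel (0.15), a congeneric/group species (0.05), or
  plain unknown (0.01).

The QA crew is simulated as observing truth exactly (before rounding),
treating the expert audit crew as the reference; both crews' error
settings are configurable. Under this one-sided model the paired
agreement rates equal the configured confusion diagonals, which the tests
verify. Truth records store each piece's realized CR/DR/CC draws, and the
stored true volume/carbon are computed by the estimator itself, so truth
self-consistency is exact by construction.

What the generator does **not** emulate: spatial autocorrelation between
plots, omission errors (pieces overlooked by one crew — no data exist to
model them), false hollowness calls, within-plot species clustering, and
the rounding of *truth* itself (true diameters are continuous). Passing
coverage tests therefore show that the propagation machinery is
calibrated when its error models match the generating process — not that
any real inventory's error models are correct.

## Numerical and design choices

- Quantiles: NumPy's linear interpolation between order statistics.
- Truncated-normal draws use `ndtri` (inverse normal CDF) on a rescaled
  uniform; SE = 0 short-circuits to the mean exactly.
- Degenerate inputs: empty plots and empty landscapes produce zero
  estimates and header-only outputs rather than errors; a zero-width
  interval counts as covering truth only when it equals truth.
- The Model/Results interface (`UncertaintyModel.fit()` →
  `UncertaintyResults`, `.attribute()` → `AttributionResults`) wraps the
  functional engine (`run_mc`, `ci95`, `quadrature_combine`,
  `attribute_sources`), which remains public.
- Problem sizes in the shipped checks: the quadrature comparison uses 50
  plots × 4,000 iterations and the coverage study 200 plots × 2,000
  iterations; percentile estimates at these sizes are stable to well
  within the tolerances tested. The degenerate-identity and atom-
  enumeration checks run the full 10,000 iterations.

## Known limitations

- Regional/state scaling and spatial sampling error across a plot network
  are out of scope; estimates and intervals are per plot (or the simple
  cross-plot mean).
- Standing dead trees, stumps, and fine woody debris are not modelled.
- The simplified matcher is not the inventory program's production
  matching algorithm.
- Real reference tables (density compilations, collapse-ratio studies)
  must be supplied by the user for real-data analyses; the packaged
  defaults are synthetic.
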
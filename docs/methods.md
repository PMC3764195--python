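# Methods

## Population model

The simulator follows the *internal age* of every cell in a synchronized
culture: a cell's position along its own cycle, in minutes. Two sources of
heterogeneity are modeled, matching how density-gradient synchronization
actually behaves:

- **Harvest-age spread.** Harvesting collects all high-density swarmer
  cells regardless of how long ago they were born, so initial internal ages
  are uniform on `[0, harvest_age_max]`. The default window is the full
  swarmer (G1) phase `[0, t_S]`.
- **Cycle-length variability.** Each cell's total cycle length is an
  independent draw from Normal(t_C, cv·t_C), defaults t_C = 137 min and
  cv = 0.35. The draw is truncated below at t_S by rejection (about 1.6% of
  the mass at defaults). Truncation serves two purposes: a cycle shorter
  than t_S would let a newborn stalked daughter divide instantaneously
  (ill-founded recursion), and negative or near-zero cycle lengths are
  unphysical. The truncation shifts the effective mean cycle length up by
  ~1.4% (139 min); we accept this rather than re-centering, because the
  truncation is part of the model definition, not an estimation artifact.

Division is asymmetric: at its division instant a cell is replaced by a
swarmer daughter at internal age 0 and a stalked daughter at internal age
t_S = 0.25·t_C (default 34.25 min), each with a freshly drawn cycle length,
independent of the mother and of each other. The stalked offset is an
*absolute* number of minutes by default, because the age intervals that
define the deconvolution are absolute 20-min bins; a `proportional` mode
(offset = fraction of the daughter's own drawn cycle length) is available
as a configuration option for users who prefer that reading, without any
claim about which the original analysis used.

Time stepping resolves divisions at their exact instant within a step and
applies the residual step time to the daughters, recursively for cascading
divisions, so results are step-size independent; the test suite checks
exact agreement (population size and sorted age lists) with an event-queue
simulator over ten cycles.

### Composition matrix

At each measurement time (default 0–180 min by 20) the population is binned
into half-open age intervals `[edge_k, edge_k+1)`, seven 20-min intervals by
default (0–140 min, covering the 137-min cycle). Ages at or beyond the last
edge are clamped into the last interval so slow cells stay accounted for
and every row sums to exactly 1. Intervals are 0-based internally and
reported 1-based in user-facing output. One seeded generator drives the
whole simulation; identical seeds give bit-identical matrices. With the
default 10⁵ cells a matrix builds in ~0.15 s and its Monte Carlo
uncertainty is negligible relative to measurement noise.

### Growth-rate relation

For the deterministic two-daughter rule the population grows asymptotically
at rate λ solving `1 = exp(−λ t_C) + exp(−λ (t_C − t_S))` (an Euler–Lotka
characteristic equation; t_S = 0 reduces to λ = ln2/t_C). The root is
bracketed on `(0, ln2/(t_C − t_S)]` and solved to machine precision. The
inverse (cycle length from a measured growth rate, offset a fixed fraction
f of the cycle) uses the identity that λ·t_C depends only on f, so
t_C = x(f)/λ exactly. Because λ is asymptotic, the simulation-vs-relation
consistency check regresses log cell count on time over 12 cycles after a
3-cycle burn-in that lets the initial harvest-window age distribution relax.

## Deconvolution

The linear system `p = F c` is solved jointly over all timepoints (10
equations, 7 unknowns at defaults). Choices the source analysis left open,
decided here:

- **Non-negativity.** Concentrations are physical, so the default solver is
  non-negative least squares (`scipy.optimize.nnls`); unconstrained least
  squares is available via a flag. A rank-deficient system under ordinary
  least squares raises unless explicitly overridden; the singular-value
  ratio of `F` (≈7 at default parameters) is always reported.
- **Replicates.** Replicate series are averaged per timepoint before
  solving, matching the population-average definition of the measured
  quantity. A bootstrap-over-replicates option (resample replicates with
  replacement, re-solve) provides uncertainty bands; it is an addition of
  this package, not part of the original procedure.
- **No regularization.** Nothing beyond non-negativity; the system is well
  conditioned and smoothing would bias the sharp transition peak.

The single-cell trace is the stage profile read as a piecewise-constant
function of internal age on `[0, t_C]` — the swarmer daughter's trajectory;
a stalked daughter enters the same curve at age t_S, under the assumption
that stage concentrations do not depend on a cell's origin.

## Unit conversion

Intracellular concentration = amount / total cell volume, with cells per
sample from a through-origin CFU-vs-OD regression (zero cells at zero OD;
ordinary regression with intercept behind a flag) and per-cell volume from
the *median* (not mean) of per-cell volumes — robust to segmentation
outliers. Cell volume uses the spherocylinder model
`V = π(w/2)²(L−w) + (4/3)π(w/2)³`, the standard rod approximation for
contour-measured bacteria; a pure cylinder option is provided. 1 µm³ =
10⁻¹⁵ L, 1 pmol = 10⁻¹² mol; results are reported in nM.

## Synthetic data

The generator emulates a synchrony time series: a known stage profile is
pushed through a simulated composition matrix and perturbed with
independent multiplicative lognormal noise per replicate per timepoint
(mean-1 multipliers; LC-MS/MS error scales roughly with signal and keeps
concentrations positive). Defaults are 3 replicates at 10% CV — the
original experiments were triplicates, and 10% is a typical LC-MS/MS
day-to-day CV; neither value was printed, so these are package choices.

The default `fig7_like` truth profile is
(75, 275, 160, 120, 100, 90, 85) nM across the seven intervals. Its
anchored features are: swarmer interval below 100 nM, a 275 nM peak in
interval 2 (the swarmer-to-stalked transition window), a slow monotone
decline through the stalked phase, and minimum at the newborn swarmer. The
intermediate values are package defaults, fixed by one additional
consistency condition: weighted by the stable age distribution of an
asynchronous exponential culture (density ∝ e^{−λa}, doubled for ages above
t_S where stalked newborns join), the profile averages 132 nM, matching the
~130 nM measured in unsynchronized wild-type populations. All generator
parameters and seeds are written to a manifest next to every output.

What the synthetic data does *not* emulate: systematic LC-MS/MS biases
(extraction efficiency, matrix effects), correlated noise between
timepoints of one replicate culture, contamination of the harvested band by
stalked cells, or any spatial/micro-pool structure of c-di-GMP within a
cell. Passing recovery tests therefore demonstrates that the inversion is
sound when the population model is approximately right — not that the model
captures every property of a real synchrony experiment.

## Benchmarks and problem sizes

The recovery benchmark generates measurements with one composition matrix
and inverts with an independently simulated one (different Monte Carlo
seed, same parameters), the realistic mismatch of an actual analysis. At
study conditions — 100 experiments, 10⁵ cells per matrix, 3 replicates,
10% noise — the transition-peak interval is recovered in ≥95% of runs and
the median RMSE is ~10% of the truth's 200 nM dynamic range; the whole
benchmark takes ~15 s on one CPU. Unit tests run reduced sizes (10³–10⁴
cells) where only shapes or coarse moments are being checked.

## Known limitations

- The composition matrix is itself a Monte Carlo estimate; at small
  `n_cells` its sampling error propagates into the profile. Use ≥10⁵ cells
  for analysis work.
- The 20-min interval resolution caps how sharp a reconstructed peak can
  be; a concentration spike narrower than one interval is averaged down.
- Late age intervals get little weight from early timepoints and are the
  least constrained part of the profile (visible as wobble in noisy
  single-experiment reconstructions).
- The normal/uniform heterogeneity assumptions are simplifications; the
  model offers no goodness-of-fit test of them beyond the residual norm.
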
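# Methods

## Labeling model

The generator treats each granule cell independently: a cell is GFP⁺
(learning-tagged) with probability `p_gfp`, and Fos⁺ (recall-activated)
with probability `rho` if it is GFP⁺ and `(p_fos − rho·p_gfp)/(1 − p_gfp)`
otherwise, so that `p_fos` is the Fos⁺ marginal exactly. This is the
minimal generative model consistent with the product-of-marginals chance
formula: under it the population reactivation rate is `100·rho`, the
expected observed overlap is `100·rho·p_gfp`, and `rho = p_fos` reproduces
independence, where the observed/chance ratio has expectation 1 (the ratio
`o·h/(g·f)` is conditionally unbiased given the marginal counts, because
`E[o | g, f] = g·f/h` when labels are independent).

Feasibility requires `rho·p_gfp ≤ p_fos` and
`(p_fos − rho·p_gfp)/(1 − p_gfp) ≤ 1`; violating parameters raise with the
violated bound named. Defaults are `p_gfp = p_fos = 0.05` (a ~5% ensemble),
`rho = 0.30` (a typical control-level reactivation), and a 50/50 split
between the two blades of the granule-cell layer. The hierarchy is
animal → slice → region; between-animal and within-animal (slice-level)
jitter of `rho` are exposed as Gaussian-sd parameters defaulting to 0,
since the study design does not pin those variance components down. All
randomness descends from one integer seed through `SeedSequence` spawning;
identical seeds give bit-identical tables and images.

## Image rendering

Nuclei are isotropic Gaussian blobs (sd `nucleus_radius` = 4 px, truncated
at 3 sd) placed by rejection sampling inside two parabolic bands emulating
the upper and lower blades (label mask: 0 outside, 1 lower, 2 upper).
Placement enforces a minimum center distance of 4 radii — at that spacing
the intensity saddle between neighbours stays below any sensible threshold,
so each nucleus is its own connected component — and keeps centers 1.5 sd
clear of the band boundary so ROI clearing never clips a supra-threshold
footprint. Densities that cannot be placed within a bounded number of
retries raise; at the default 768×768 frame about 300 cells per slice fit
comfortably. Each stack has 3 planes 2 µm apart; a nucleus at continuous
depth `z` contributes to plane `k` with weight
`exp(−(k−z)²·z_step²/(2·z_sigma_um²))`. Channels share peak intensity 200
over background 20 with Gaussian noise sd 5 — a deliberately clean SNR:
the renders exercise the pipeline's geometry and bookkeeping, not
segmentation robustness. Real tissue adds illumination gradients, touching
nuclei, autofluorescence and staining variability that these synthetic
slices do not model, so passing image tests validate the measurement
chain, not segmentation performance on real data.

## Detection stage

Per plane, background is estimated by grey-opening with a disk footprint
(`background_radius` = 50 px, computed on a downsampled copy for large
radii — the standard fast approximation to rolling-ball subtraction) and
subtracted; the z-stack is then max-projected, cleared outside the ROI,
and thresholded (Otsu over positive pixels by default, or a fixed value).
Connected components use 8-connectivity, 0-based row-major coordinates,
and must have pixel area **strictly greater** than `min_particle_size`
(default 50). Signals are confirmed as cells when their footprint
intersects a Hoechst particle by at least `colocalization_min_fraction`
(default 0.5) of the smaller footprint; dual-channel colocalization uses
the same criterion with greedy one-to-one matching by descending
intersection size and deterministic index tie-breaks. An optional
single-plane-support rule drops projected particles that are
supra-threshold in no individual plane (off by default).

One caveat worth noting: the detection count is only monotone
non-increasing in the threshold once nuclei are resolved. Below the
resolving threshold, merged clusters split into several valid particles as
the threshold rises, so the count can increase; the property test asserts
monotonicity in the resolved regime.

## Census

Total (Hoechst⁺) cells come either from direct counting of Hoechst
detections (the default on synthetic data, where it is feasible) or from a
linear area→count calibration fitted by OLS, accepted as valid only with
≥ 15 ROIs and R² > 0.80 — models failing the rule are returned flagged,
with a warning, and refuse estimation unless overridden. Calibrations
carry a provenance tag because they must be refitted whenever sectioning
or staining conditions change. When a whole-ROI estimate has to be split
into blades, it is allocated proportionally to blade pixel area with
largest-remainder rounding: applying `slope·area + intercept` per blade
would count the intercept twice and break the upper + lower = total
invariant, which the tabulation asserts on every output. Blade assignment
is by the region label under the detection centroid, with
nearest-blade fallback (logged) for centroids in neither band.

## Rates and aggregation

Chance overlap is computed per slice and then averaged (matching per-slice
quantification), not from animal-pooled counts; the observed/chance group
comparison uses one per-animal ratio of the averaged rates. Slices where a
statistic is undefined (GFP⁺ = 0 for the reactivation rate; both sets
empty for the similarity index) are excluded from that statistic's average
with a log entry, never zero-filled. Batch normalization divides each
animal's value by the mean of the control animals in the same batch, so
controls average to 1 per batch; a batch without controls is an error.

## Inference

The decision rule is: Shapiro–Wilk on every sample (on the paired
differences for paired designs) at alpha = 0.05; normal →
pooled-variance Student's *t* (paired or unpaired; Welch behind a flag),
non-normal → exact Wilcoxon signed-rank (paired) or Mann–Whitney
(independent); Pearson for correlations. Constant vectors are treated as
non-normal (logged) rather than raised.

The exact nulls are the package's core numerics. The signed-rank statistic
is the **sum of signed ranks** `W = S⁺ − S⁻ = 2S⁺ − n(n+1)/2`
(range ±n(n+1)/2, same parity as n(n+1)/2 when untied); its null is built
by a subset-sum dynamic program over the ranks, and the two-tailed p is
`P(|W′| ≥ |W|)` by full enumeration up to n = 25. Zero differences are
removed before ranking (counted in the log); ties midrank and the DP then
runs over doubled midranks — still a full enumeration, but conditional on
the tie pattern, so the result is flagged non-exact. The Mann–Whitney null
`P(U = u)` is the Gaussian-binomial recurrence
`f(i, j, u) = f(i−1, j, u−j) + f(i, j−1, u)`; with `u* = min(U, mn−U)` the
two-tailed p is `P(U′ ≤ u*) + P(U′ ≥ mn−u*)`, clamped at 1, exact for
m + n ≤ 40 on tie-free data; tied data fall back to the tie-corrected
continuity-corrected normal approximation, flagged. Both DPs are verified
in the test suite against brute-force enumeration (all 2ⁿ sign vectors;
all C(m+n, m) labelings) and against scipy's exact modes on random data.

Note that an exact p computed from a summary (m, n, U) triple assumes
tie-free data; published values computed from tied raw data by approximate
methods can differ in the third decimal, which no reanalysis from the
summary statistic alone can reconcile.

## Intensity analyses

Per-cell integrated intensity is pixel area × mean intensity over the
detection footprint on the background-subtracted image; channel sets are
normalized to their mean (so normalized means are 1, and correlations are
unchanged — Pearson is scale-invariant). The thresholded group comparison
takes all marker-positive cells per slice, samples k ∈ [10, 15]
sub-threshold cells (seeded, uniform k; slices with fewer than 10
sub-threshold cells are skipped with a log entry), averages the
target-channel **mean** intensity per group per slice, then per animal,
and divides by the animal's negative-group mean. The marker threshold is
required configuration with no default, as it depends on staining.

## Problem sizes

The shipped tests and acceptance script use 300-cell renders (3 noisy
slices + 1 noiseless), 200 replicate cohorts of 6 animals × 3 slices ×
2000 cells for parameter recovery, 100 replicates for the independence
check, and exhaustive oracle sweeps to n = 10 (signed-rank) and
m + n = 12 (U). These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping a full run in well under a minute for
the count-level parts and a few seconds per rendered slice.

## Known limitations

- Connected-component counting assumes resolvable nuclei; there is no
  watershed splitting of touching cells (out of scope, as is any 3-D or
  learned segmentation).
- The renderer does not model illumination fields, tile stitching,
  chromatic shift between channels, or antibody/staining variability.
- The exact Mann–Whitney path requires tie-free data; percent-scale animal
  averages rarely tie, but heavily discretized inputs will route to the
  flagged approximation.
- Behavioral readouts, viral expression kinetics and DNA-methylation
  landscapes are outside the package's scope.
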
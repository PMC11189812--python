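# Methods

This note documents the models, defaults and numerical choices behind
`iegmap`, and what the synthetic-data generators do and do not emulate.

## Cell-count classification and forward models

### Data model

Input is a rectangular table of nonnegative IEG⁺ cell counts: one row per
animal, one column per parcellated region (22 regions by default, labelled
with Allen-atlas-style abbreviations), with a treatment group per animal
(three groups of 5 by default: vehicle, drug, enantiomer).

### z-scoring

Each region is standardized across **all** animals of the full cohort
(sample SD, denominator n−1), not per comparison pair. Standardizing on the
joint cohort preserves cross-group scale when rows are later subset to a
pair; the constants (mean, SD in cells) are retained for reporting. A
zero-variance region is refused by name rather than silently producing
infinities — with n = 15 animals this is a realistic failure mode.

### Linear SVM (backward model)

Each two-group comparison is decoded with a soft-margin linear SVM
(default C = 1; features are already z-scored so no further scaling is
applied; the intercept is fitted but does not enter the forward model).
The dual problem is solved by libsvm's deterministic SMO (scikit-learn
`SVC`, `tol = 1e-10`). The fit is performed once on a canonical ±1 encoding
anchored to the first row's class; the returned (W, b) are sign-oriented to
the requested positive class. This makes label-flip antisymmetry *exact*:
swapping which class is positive negates (W, b) bit-for-bit, so |A| rankings
are flip-invariant by construction. Correctness of the optimizer is checked
in the test suite against an independently solved dual quadratic program
(SLSQP on the box-constrained dual with the equality constraint), comparing
primal objective against dual optimum via strong duality.

### Forward-model (activation-pattern) transform

Decoder weights are not interpretable region-by-region; the forward model

A = Σₓ W Σŝ⁻¹ with Σŝ = Wᵀ Σₓ W

is. Σₓ is the unbiased (n−1) sample covariance of the features the decoder
was fitted on — the z-scores of the two groups in the comparison, classes
pooled without per-class centering. For a binary decoder K = 1, so Σŝ is a
positive scalar and the matrix inverse degenerates to scalar division;
Σŝ ≤ 0 (degenerate W or rank-deficient data) raises an error rather than
producing a sign-flipped or infinite pattern. A `covariance_on="raw"`
switch estimates Σₓ from raw counts of the same animals instead, for
sensitivity analysis. Regions are ranked by |A| descending with ties broken
by the declared region order (stable sort), so rankings are reproducible.

### Statistical power of region nomination — an honest accounting

With one planted effect region, the |A| ranking reduces (for training-
separable fits, whose decision values saturate at the margins) to ranking
regions by the absolute z-space group-mean difference. Two consequences
matter at the study's scale (5 + 5 animals, 22 regions):

- each null region's mean-difference noise has SD √(2/5) ≈ 0.63 in its own
  z units, so the expected maximum over 21 null regions is ≈ 1.5;
- the planted shift inflates the effect region's *own* cohort SD (a
  between-group variance term 2e²/9 for an effect of e within-group SDs in
  one of three groups, plus the count-variance growth at the shifted mean),
  so a planted e attenuates to e/√(1 + 2e²/9 + …) in z units — bounded by
  ≈ 2.1 even as e → ∞.

A 2-SD planted effect therefore attenuates to ≈ 1.3–1.5 against a null max
of ≈ 1.5: measured recovery is ~52–56% (and ~64% for an oracle ranking by
the exact statistic on Gaussian data), while the zero-effect null nominates
any given region ≈ 1/22 ≈ 5% of the time. Recovery above 95% requires a
planted effect of roughly 6 within-group SDs or more animals. The
acceptance suite asserts the 2-SD condition and reports this honestly; the
worked example and plumbing tests use well-powered designs (n = 20, 4 SD)
where nomination is essentially deterministic.

### Anteroposterior binning

IC cells are histogrammed over +2.50 to −1.00 mm (anterior → posterior) in
ten equal 0.35-mm bins by default (configurable edges). Bin i covers
(edge_{i+1}, edge_i] — upper (anterior) edge inclusive — so the aIC
aggregate is exactly the cells in (+1.45, +2.50], spanning the first three
bins. Cells outside the edge span are tallied in an overflow bucket, never
dropped. The aIC boundary (+1.45 mm) is anatomical; the mIC/pIC split of
the remaining extent is not standardized, and this package labels bins
4–6 (+1.45 to +0.40] as mIC and bins 7–10 (+0.40 to −1.00] as pIC.

## Photometry

### airPLS baseline

The baseline is the solution of a weighted Whittaker smoother
(w + λDᵀD)z = w·y with a difference penalty of order 2, iterating weight
re-estimation from the negative residuals: samples above the running
baseline get weight 0, samples below are weighted exp(t·|dᵢ|/|d₋|₁) at
iteration t, and iteration stops when |d₋|₁ < ratio·|y|₁ (ratio = 1e-3) or
after max_iter = 15 passes. The linear systems are solved with a banded
Cholesky factorization (`scipy.linalg.solveh_banded`), so a 10-minute
100 Hz trace costs milliseconds per iteration.

The default smoothness penalty is **λ = 1e9**. For an order-2 penalty the
smoother's equivalent bandwidth is ≈ λ^(1/4) samples; at 100 Hz, λ = 1e9
gives ≈ 1.8 s — deliberately between the calcium-transient decay (~1 s) and
the minutes-scale drift. Much smaller λ lets the "baseline" follow the
transients themselves (evoked responses are then subtracted away), which is
why values quoted for ~10³-point spectroscopy traces do not transfer to
minutes of 100 Hz photometry. λ, order, max_iter and ratio are all exposed
in the config and CLI.

On noisy traces any lower-envelope baseline estimator sits O(σ) below the
true drift. This offset is slowly varying, so it cancels in the evoked
statistic (a within-trace difference) and is absorbed by baseline-segment
z-scoring; drift-recovery accuracy is therefore assessed on noise-free
drift + transient traces, where the fitted baseline recovers the planted
cubic drift to ≈ 2% RMSE of its range.

### Correction, smoothing, z-scoring

corrected = raw − baseline, optionally followed by a centered moving
average (width 0.5 s when enabled; **off by default** so window algebra in
tests is exact — the smoothing dialect is a free choice and nothing
downstream depends on it). z = (corrected − μ_base)/σ_base with μ, σ (ddof
= 1) taken over the designated home-cage baseline segment, so the
baseline-segment z has mean 0 and SD 1 exactly (to ~1e-15 in practice). A
zero baseline-segment SD (e.g. a constant trace) raises a degenerate-input
error instead of returning infinities.

### Event selection and evoked responses

A bout is *nonsequential* if it is the first of the session or its onset is
at least 10 s (inclusive boundary) after the **end of the immediately
preceding bout in the full log** — not the previously kept bout. The filter
is idempotent. Evoked response per bout: Δz = mean z over [onset, onset+3 s)
minus mean z over [onset−3 s, onset), onset aligned to the nearest sample;
the pre-window excludes and the post-window includes the onset sample. Δz
is invariant to adding a constant to the whole trace. Bouts whose windows
are truncated by the recording edge are skipped with a logged warning and
a reported skip count, not zero-padded.

### Session statistics

Per animal and stimulus label, the mean Δz over kept bouts; the paired
two-sided t contrast (scipy `ttest_rel`) between mouse and object means
across animals, with zero-variance paired differences flagged as degenerate
(all-zero differences report t = 0, p = 1); and the Spearman rank
correlation (average ranks for ties, two-sided p) between per-event Δz and
contact duration, with constant inputs flagged rather than raised. Under
the null (no planted transients) the paired contrast's measured type-I
error at α = 0.05 is ≈ 0.05 over 2000 simulated 7-animal cohorts.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` and are
byte-deterministic; every planted quantity is returned in a ground-truth
object so downstream estimators can be scored.

**Counts.** Negative binomial per region (mean 300 cells, dispersion θ = 20,
variance μ + μ²/θ, i.e. between-animal CV ≈ 23%) — overdispersed as
biological count tables are, independent across regions and animals. A
group effect adds effect_size × √(μ + μ²/θ) to the designated group's mean
in the chosen regions. Region-level count variability of the real data is
unpublished; these defaults are placeholders with realistic overdispersion,
not a fit to the study.

**IC coordinates.** Cells uniform (or profile-weighted: per-interval
weights or a density callable) along the anteroposterior extent +2.50 to
−1.00 mm; mediolateral and dorsoventral coordinates fill a plausible
insular envelope and are not used by any analysis.

**Photometry.** trace = f₀ + drift + noise + transients. Drift is a random
cubic scaled to a configurable span (5 units ≈ 5σ of noise by default) over
the recording; noise is white Gaussian; transients are unit-peak
difference-of-exponentials kernels (rise 0.2 s, decay 1.0 s — a generic
fast calcium-indicator shape) or steps (for exact window algebra), with
amplitudes in z units (multiples of the noise SD) per stimulus label. The
5-min home-cage baseline segment precedes the session and contains no
events. Auto-generated schedules alternate mouse/object bouts spaced so the
nonsequential filter keeps them all; a per-event lognormal latent
multiplier (SD 0.3) jitters amplitudes and, through a coupling exponent,
scales bout durations with response strength — planting the positive
response-duration correlation the Spearman analysis estimates.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: no photobleaching-specific decay shape (drift is
polynomial, not exponential), no motion or hemodynamic artifacts (the
single-wavelength design has no isosbestic channel to regress), no
correlated region noise or per-animal global IEG expression factors, no
behavioral structure beyond the bout schedule, and no imaging,
segmentation or registration errors upstream of the count table. Tests
demonstrate algorithmic correctness and statistical calibration under the
stated noise model, not robustness to those artifacts.

## Problem sizes and runtime

Simulation studies use: 200 replicates for recovery rates, 100 random
datasets for the forward-model oracle, 50 problems for the SVM reference,
20 seeds for drift recovery, 1000 random logs for the filter oracle, and
2000 seven-animal cohorts for type-I calibration; photometry traces are
100 Hz and minutes long (60k–90k samples). The full test suite and the
acceptance script each run in roughly a minute on one CPU.
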
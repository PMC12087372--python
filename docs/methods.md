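# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `wmhcentiles`, at the level of detail a
maintainer or reviewer needs. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Response scale and volumetry

All modeling happens on `y = log10(v + 0.001)` with `v` in mL. The
offset is one 1 mm³ template voxel, so an empty mask maps to exactly
−3 and the transform is invertible via `max(10^y − 0.001, 0)`. Volumetry
is integer voxel counting scaled by the voxel volume (taken from the
NIfTI header, product of spacings; 0.001 mL default): results are exact,
with no floating-point tolerance beyond the final multiply.

Masking rules: a mask voxel survives WM restriction iff its WM
probability is ≥ 0.30 ("below 30%" is removed, so the boundary is kept);
tract membership is probability ≥ 0.10. Both thresholds are inclusive by
the same reading and are parameters. Tract volumes are computed on the
WM-restricted mask. Grids must match exactly; no silent resampling — a
dimension mismatch is an error, because resampling belongs upstream with
registration. Non-binary masks are binarized at > 0.5 with a warning.

## Quantile regression

For each sex and each quantile level τ the model is
`Q_τ(y | age) = b(age)ᵀ β_τ`, fit by minimizing the check loss
`Σ ρ_τ(yᵢ − b(ageᵢ)ᵀβ)`. The minimizer is computed exactly via linear
programming. We solve the dual — maximize `yᵀa` subject to
`Xᵀa = (1−τ)Xᵀ1`, `a ∈ [0,1]ⁿ` — which has only p equality constraints
and is several-fold faster than the primal at the sample sizes used
here. The primal coefficients are recovered from the zero-residual
(interior-dual) observations by least squares; whole-year ages produce
tied design rows, which is why the interior set can exceed p. Optimality
is verified by the duality gap (tolerance 1e−7 relative), with a primal
LP fallback on any degeneracy. Minimizers of the check loss can be
non-unique; correctness is defined by the attained loss, and the test
suite checks it against a brute-force oracle and against an independent
IRLS solver.

### Age basis

The "degrees of freedom" δ is the number of spline columns beyond the
intercept. A full B-spline basis of δ+1 functions (degree `min(3, δ)`,
interior knots at equally spaced quantiles of the training ages,
boundary knots at the 1st/99th age percentiles) is a partition of unity;
the first function is dropped in favour of an explicit intercept. δ = 1
reduces to the affine model, and the basis has linear precision at any
δ. Evaluation outside the boundary knots extrapolates the boundary
polynomial; evaluation outside the declared age domain (default 40–85,
the densely sampled range) is flagged, not forbidden.

An alternative `knot_rule="search"` places a single interior knot by
profiling the τ = 0.5 check loss over distinct training ages (degree
δ−1). It exists because quantile-placed knots land far from a localized
change of regime — see "Known limitations" on late-onset tract curves.

### Quantile crossing

Curves for different τ are fit independently and need not be ordered.
Before any evaluation, export or scoring, fitted values are monotonely
rearranged across τ at each age (pointwise sort). This changes nothing
but the ordering of the per-age value multiset and guarantees
nondecreasing percentile rows in every exported table.

### Degrees-of-freedom comparison

`compare_df` refits nested bases and reports per-τ loss reductions plus
a one-sided p-value from a subject-level bootstrap of the loss
difference (resample subjects, refit both models, recentre the
resampled reductions at the observed one). The recommendation mechanizes
only the significance step; the returned losses are meant to be
inspected, since pure loss comparisons will always favour the larger
basis in-sample.

### Bootstrap bands

Bands are pointwise 2.5th/97.5th percentiles of curves re-estimated on
participant resamples (resampling unit: the subject, drawn from the full
pooled list so stratum sizes vary as they would in resampled studies).
Knots are held at the full-sample basis across resamples — the standard
choice for curve bootstraps, and what makes B = 1000 affordable.
Resamples that drop a sex stratum below the fitting floor (50) are
redrawn and counted. Percentile bands are widened, when necessary, to
contain the full-sample point estimate, making the band invariant
`lower ≤ point ≤ upper` a guarantee. Coverage of the true median at
interior ages is checked by simulation in the test suite.

## Scoring

Table references store volumes at percentiles {5,…,95} on a 5-year age
grid. To score (age, sex, v): transform v, linearly interpolate the
log-scale table rows in age, map percentiles to normal-equivalent
deviates `z_p = Φ⁻¹(p/100)`, build a monotone piecewise-cubic (PCHIP)
interpolant from log-volume to z, and return `100·Φ(z(log v))`. The NED
axis keeps the percentile scale smooth where centiles crowd together;
PCHIP through the knots reproduces every tabulated cell exactly.
Volumes outside the p5–p95 envelope are censored (`<5` / `>95`) rather
than extrapolated — the reference does not tabulate beyond that range,
and tail extrapolation on six knots would be invention. Ages 18–97 are
accepted; outside the table's 40–85 grid the nearest row is used and the
score flagged as extrapolated. Non-integer ages are accepted (the
source studies rounded ages; interpolation is a usability choice).
The packaged table is checksummed (SHA-256) on load and validated for
strict monotonicity in both directions.

## Pattern classification

A tract's median curve is classified on ages ≤ 85 of a grid covering at
least [45, 85]: pattern 3 if it never exceeds baseline + ε (baseline
= −3 exactly, the zero-volume transform; ε default 0.05); otherwise
pattern 2 if the first departure age is ≥ 60 (`onset_cut`), else
pattern 1. ε and `onset_cut` operationalize what is fundamentally a
visual judgment and are exposed as parameters. Left/right tracts are
classified independently.

Curve summaries can come from fitted per-tract models
(`summaries_from_models`) or from windowed empirical quantiles
(`summaries_from_volumes`; default 5-year windows, matching the 5-year
age strata conventional in this literature). The empirical route is a
consistent estimator near sharp onsets and is what the pattern-recovery
checks use.

## Synthetic data generator

The generator defines the study conditions the pipeline is validated
under:

- **Median structure**: `y = intercept + 0.0316·age + 0.0632·1{female}
  (+ 0.30·1{stroke}) + noise`. The slope makes absolute volume double
  every ~10 years; the sex offset equals two years of aging; the
  intercept anchors the female median at age 40 to exactly 0.39 mL. The
  stroke offset exists to exercise the exclusion sensitivity path.
- **Noise**: skew-normal on the log10 scale (shape 1.5), centred at its
  median so the linear predictor is the conditional median, and rescaled
  to a normal-equivalent scale: `noise_scale = 0.4588` fixes the
  10th–90th spread at `2·z₀.₉·noise_scale` ≈ 15-fold on the volume scale
  for any skew; shape 1.5 puts the interquartile ratio near 4. The
  residual family of real WMH data is unknown; skew-normal is a
  stand-in with the right gross asymmetry, not an inference.
- **Cohorts**: ages uniform integers per cohort (real cohorts are not
  uniform — a documented simplification); the default study design is
  five cohorts with staggered, partially disjoint ranges covering 18–97,
  densest at 40–90, with 52.2% females and 1.6% stroke history. Each
  subject draws from an RNG substream keyed by (seed, cohort name,
  index), so records are stable under cohort reordering.
- **Tracts**: the total volume is allocated by fixed weights — 70% to
  the six pattern-1 tracts, 30% to the eight pattern-2 tracts, none to
  the six pattern-3 tracts — with pattern-2 allocation zero before age
  60 and ramping linearly to full over 15 years.
- **Images**: a toy template (ellipsoidal WM probability blob, elongated
  tract maps) and per-subject masks grown as random contiguous blobs:
  each tract's share inside its exclusive thresholded region, the
  remainder in non-tract WM, so volumetry round-trips to the generative
  volumes within one voxel per compartment. Morphology is schematic and
  not a contract.

What passing tests on these data do **not** show: robustness to
segmentation error, registration error, scanner effects, non-uniform
age sampling within cohorts, or real residual distributions — none of
which are simulated.

## Problem sizes in the checks

Recovery and pattern checks run at ~5,000 subjects per sex (the scale at
which sex-specific centile estimation stabilizes); the bootstrap
coverage simulation uses 200 replicates × B = 200 at n = 500, a
deliberately scaled-down design whose nominal behaviour is the point;
`compare_df` calibration tests use n = 400–600 with B = 60. The CLI
demo defaults to 600 subjects.

## Known limitations

- **Smoothing bias at sharp onsets.** For late-onset (pattern-2) tracts
  the true median on the offset-log scale jumps from −3 to ≈ −2.3 within
  a year of onset and rises concavely afterwards. Any 2-df fit —
  quadratic, or broken-stick with a profiled knot — places its departure
  from baseline ~5 years before the true onset (the check-loss-optimal
  knee trades the flat segment against the concave rise). Onset ages
  read off low-df fitted curves are therefore systematically early, and
  classification of such fits against a hard 60-year cutoff mislabels
  late-onset tracts as total-like. Use the empirical windowed-quantile
  summaries for onset evidence; fitted curves for smooth centile
  display.
- **Tolerance of surface recovery.** At 5,000 per sex the maximum
  absolute error of the p90 curve over a 46-year grid has substantial
  Monte-Carlo spread (sampling noise of quantile regression in a
  low-density tail); single-seed recovery results near 0.05 log10-mL
  should be read as typical-scale, not as a guaranteed bound.
- No study-site correction is implemented (disjoint cohort age ranges
  make site and age confounded by design); the registration-method
  style sensitivity is available as an additive categorical covariate.
- Cross-sectional only; no longitudinal modeling, no alternative
  centile families (LMS/GAMLSS), no segmentation or registration.
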
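# wmhcentiles

Normative, age- and sex-specific centile modeling of cerebral white
matter hyperintensity (WMH) volumes.

WMH are the bright lesions seen on FLAIR MRI and the canonical imaging
marker of cerebral small vessel disease. Their volume rises roughly
exponentially with age — the median doubles about every ten years — but
the interindividual spread at any age is enormous: a person at the 90th
percentile typically carries ~15 times the volume of a person at the
10th. A raw volume is therefore hard to interpret; what a clinician or
researcher wants is a percentile for age and sex, the way pediatric
growth charts are read. This package provides that machinery:

- **volumetry** — exact voxel-counting of total and tract-wise WMH
  volumes from binary masks on a common template grid, with white-matter
  masking (voxels below 30% WM probability removed), probabilistic tract
  regions (10% threshold, 20 JHU-style tracts), and the
  `log10(v + 0.001)` transform (0.001 mL ≈ one 1 mm³ voxel, so an empty
  mask maps to −3).
- **normative_model** — sex-stratified quantile regression of
  `y = log10(v + 0.001)` on a B-spline basis of age. For quantile level
  τ, coefficients minimize the check (pinball) loss
  `Σᵢ ρ_τ(yᵢ − b(ageᵢ)ᵀβ)`, `ρ_τ(u) = u·(τ − 1{u<0})`, solved exactly as
  a linear program (HiGHS, dual formulation). Default centiles are
  τ ∈ {.05, .10, .25, .50, .75, .90, .95}; spline degrees of freedom
  δ = 4 for total volume and δ = 2 for tracts; quantile crossing is
  repaired by monotone rearrangement across τ at each age. Pointwise 95%
  confidence bands come from a participant-level bootstrap (1000
  iterations by default).
- **scoring** — places an individual (age, sex, volume) on a normative
  surface. Ships the published reference table for total WMH volume
  (ages 40–85 in 5-year steps, percentiles 5–95, both sexes) and scores
  against it — or against any model you fit — by monotone (PCHIP)
  interpolation on the normal-equivalent-deviate axis. Volumes outside
  the p5–p95 envelope are reported censored (`<5` / `>95`).
- **patterns** — classifies tract-wise centile curves into the three
  regional accumulation patterns: (1) total-like from middle age,
  (2) late-onset after ~60, (3) persistently rare.
- **synthetic_data** — a generative model of multi-cohort study data
  (log-linear median growth, female offset, wide right-skewed spread,
  pattern-structured tract allocation, voxel-level toy images) so the
  whole pipeline is testable end to end without patient data.

## Worked example

Score a 72-year-old woman with 8.4 mL of WMH against the packaged
reference:

```sh
$ wmhcentiles score --age 72 --sex female --volume-ml 8.4
female, age 72, 8.4 mL: ~76th percentile for age and sex
```

So about one woman in four of her age has more WMH than she does —
elevated, but well within the reference range. The same lookup from
Python:

```python
>>> from wmhcentiles import scoring as sc
>>> table = sc.load_packaged_table("female")
>>> table.value(70, 50), table.value(75, 50)   # median at 70 and 75, mL
(3.32, 5.0)
>>> s = sc.score_individual(72, "female", 8.4, table)
>>> round(s.percentile, 1)
75.8
```

A volume below the 5th or above the 95th reference centile is censored
rather than extrapolated:

```sh
$ wmhcentiles score --age 64 --sex male --volume-ml 17.8
male, age 64, 17.8 mL: above the 95th percentile for age and sex
```

The full pipeline on synthetic data — simulate a multi-cohort study, fit
centile models, export a normative table, score every subject, classify
tract patterns:

```sh
wmhcentiles run --out-dir demo --n 2000 --seed 7
```

which writes `subjects.csv`, `model.json`, `normative_table.csv`,
`scores.csv`, `tract_curves.csv`, `tract_patterns.csv` and `run.json`
(every file carries a provenance header with version, seed and config
hash). Individual stages are available as `simulate`, `volumes`, `fit`,
`export-table`, `score`, `score-image` and `classify-patterns`.

## Limitations

The packaged reference derives from predominantly white, population-based
cohorts imaged at 1×1×1 mm in MNI-152 space; percentiles for ages
outside 40–85 are flagged as extrapolated and should be read cautiously.
Scoring assumes volumes already normalized to template space. This
package deliberately reports percentiles, not a "brain age": with a
15-fold normal spread, an age-equivalent framing misleads.
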
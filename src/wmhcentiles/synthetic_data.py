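"""Synthetic cohorts and voxel-level WMH masks with realistic age structure.

The generator reproduces the statistical skeleton of population WMH data:
log10-transformed total volume grows linearly with age (volume roughly
doubles every 10 years), females carry a constant positive offset, and
interindividual spread is wide and right-skewed (the 90th percentile sits
about 15-fold above the 10th, the 75th about 4-fold above the 25th).
Regional volumes are allocated to named tracts following three curve
patterns: total-like tracts, late-onset tracts that stay empty before age
60, and tracts that essentially never carry lesions.

Noise is skew-normal on the log10 scale, centred at its median (so the
linear predictor IS the conditional median) and rescaled to a
normal-equivalent scale: for any skew, the 10th-90th percentile spread of
the noise equals ``2 * z_{0.90} * noise_scale``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, skewnorm

from .tracts import JHU_TRACT_NAMES, TRACT_PATTERNS
from .volumetry import (
    LabelVolume,
    ProbabilityVolume,
    back_transform,
    log_offset_transform,
)

_Z90 = float(norm.ppf(0.90))


@lru_cache(maxsize=64)
def _skewnorm_unit(skew: float) -> tuple[float, float]:
    """Median and normal-equivalent scale unit of a standard skew-normal."""
    med = float(skewnorm.ppf(0.5, skew))
    spread = float(skewnorm.ppf(0.9, skew) - skewnorm.ppf(0.1, skew))
    return med, spread / (2.0 * _Z90)

#: Male log10(v+0.001) at age 0, anchored so the female median at age 40 is
#: exactly 0.39 mL under the default slope and sex offset.
DEFAULT_INTERCEPT = float(np.log10(0.391) - 40 * 0.0316 - 0.0632)

#: Age (years) at which late-onset (pattern 2) tracts begin accumulating WMH.
PATTERN2_ONSET_AGE = 60
#: Years over which a pattern-2 tract ramps from empty to its full allocation.
PATTERN2_RAMP_YEARS = 15


def _default_tract_weights() -> dict[str, tuple[int, float]]:
    """Allocation weights: pattern-1 tracts carry 70% of regional burden,
    pattern-2 tracts 30%, pattern-3 tracts none. Weights sum to 1 over the
    tracts with nonzero weight."""
    n1 = sum(1 for p in TRACT_PATTERNS.values() if p == 1)
    n2 = sum(1 for p in TRACT_PATTERNS.values() if p == 2)
    out: dict[str, tuple[int, float]] = {}
    for name, pat in TRACT_PATTERNS.items():
        w = 0.70 / n1 if pat == 1 else (0.30 / n2 if pat == 2 else 0.0)
        out[name] = (pat, w)
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Design of one population cohort (cohorts may have disjoint age ranges)."""

    name: str
    n: int
    age_min: int
    age_max: int
    female_fraction: float = 0.522
    stroke_fraction: float = 0.016

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort {self.name!r}: n must be >= 1")
        if self.age_min > self.age_max:
            raise ValueError(
                f"cohort {self.name!r}: age_min {self.age_min} > age_max {self.age_max}"
            )
        for fname in ("female_fraction", "stroke_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"cohort {self.name!r}: {fname}={v} outside [0,1]")


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the generative model for log10 total WMH volume.

    ``intercept`` is the male conditional median (log10-mL, offset scale) at
    age 0; defaults are anchored so the female median at age 40 is 0.39 mL
    and doubles roughly every 10 years (slope 0.0316 log10-mL/yr). The sex
    offset equals two years of aging. ``noise_scale`` is the
    normal-equivalent scale of the skew-normal residual (10-90 spread
    ~15-fold on the volume scale); ``noise_skew`` is the skew-normal shape.
    """

    intercept: float = DEFAULT_INTERCEPT
    slope_per_year: float = 0.0316
    sex_offset: float = 0.0632
    noise_scale: float = 0.4588
    noise_skew: float = 1.5
    stroke_offset: float = 0.30
    tract_weights: Mapping[str, tuple[int, float]] = field(
        default_factory=_default_tract_weights
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        weights = [w for (_p, w) in self.tract_weights.values()]
        if any(w < 0 for w in weights):
            raise ValueError("tract allocation weights must be nonnegative")
        nonzero = sum(w for w in weights if w > 0)
        if weights and nonzero > 0 and abs(nonzero - 1.0) > 1e-9:
            raise ValueError(
                f"tract allocation weights must sum to 1 over nonzero tracts, got {nonzero}"
            )

    # Normal-equivalent rescaling of the skew-normal quantile function.
    def _noise_unit(self) -> tuple[float, float]:
        return _skewnorm_unit(self.noise_skew)

    def noise_quantile(self, u) -> np.ndarray:
        """Quantile function of the centred, rescaled residual distribution."""
        med, unit = self._noise_unit()
        return (skewnorm.ppf(u, self.noise_skew) - med) * (self.noise_scale / unit)

    def sample_noise(self, rng: np.random.Generator, size=None) -> np.ndarray:
        med, unit = self._noise_unit()
        draw = skewnorm.rvs(self.noise_skew, size=size, random_state=rng)
        return (draw - med) * (self.noise_scale / unit)

    def median_log10(self, age: float, sex: str, stroke: bool = False) -> float:
        """Conditional median of log10(volume + 0.001)."""
        y = self.intercept + self.slope_per_year * age
        if sex == "female":
            y += self.sex_offset
        if stroke:
            y += self.stroke_offset
        return y

    def quantile_log10(self, age: float, sex: str, tau: float) -> float:
        """Generative conditional quantile surface (non-stroke subjects)."""
        return self.median_log10(age, sex) + float(self.noise_quantile(tau))


def pattern_age_factor(pattern: int, age: float) -> float:
    """Fraction of a tract's full allocation realized at a given age."""
    if pattern == 1:
        return 1.0
    if pattern == 2:
        if age < PATTERN2_ONSET_AGE:
            return 0.0
        return min(1.0, (age - PATTERN2_ONSET_AGE) / PATTERN2_RAMP_YEARS)
    if pattern == 3:
        return 0.0
    raise ValueError(f"unknown pattern {pattern}")


@dataclass(frozen=True)
class SyntheticSubject:
    id: str
    cohort: str
    age: int
    sex: str
    history_of_stroke: bool
    true_total_log10: float
    true_tract_log10: dict[str, float]

    @property
    def total_ml(self) -> float:
        return back_transform(self.true_total_log10)

    def tract_ml(self, tract: str) -> float:
        return back_transform(self.true_tract_log10[tract])


def generate_cohort(
    specs: Sequence[CohortSpec],
    params: GenerativeParams | None = None,
    seed: int | None = None,
) -> list[SyntheticSubject]:
    """Draw subjects for a set of cohorts.

    Ages are uniform integers on each cohort's range. Each subject has its
    own RNG substream keyed by (seed, cohort name, subject index), so a
    subject's record is invariant to reordering or resizing other cohorts.
    """
    if not specs:
        raise ValueError("at least one CohortSpec is required")
    if len({s.name for s in specs}) != len(specs):
        raise ValueError("cohort names must be unique")
    params = params if params is not None else GenerativeParams()
    seed = params.seed if seed is None else seed

    subjects: list[SyntheticSubject] = []
    for spec in specs:
        ckey = zlib.crc32(spec.name.encode("utf-8")) % (2**31)
        for j in range(spec.n):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ckey, j]))
            age = int(rng.integers(spec.age_min, spec.age_max + 1))
            sex = "female" if rng.random() < spec.female_fraction else "male"
            stroke = bool(rng.random() < spec.stroke_fraction)
            noise = float(params.sample_noise(rng))
            y = params.median_log10(age, sex, stroke) + noise
            total_ml = back_transform(y)
            tract_log10 = {}
            for tract, (pat, w) in params.tract_weights.items():
                v = total_ml * w * pattern_age_factor(pat, age)
                tract_log10[tract] = log_offset_transform(v)
            subjects.append(
                SyntheticSubject(
                    id=f"{spec.name}-{j:05d}",
                    cohort=spec.name,
                    age=age,
                    sex=sex,
                    history_of_stroke=stroke,
                    true_total_log10=y,
                    true_tract_log10=tract_log10,
                )
            )
    return subjects


def default_study_cohorts(n_total: int = 3000, seed_names: bool = False) -> list[CohortSpec]:
    """A compact stand-in for a multi-cohort pooled study: five cohorts with
    staggered, partially disjoint age ranges jointly covering ages 18-97,
    densest at 40-90."""
    fractions = [0.10, 0.25, 0.30, 0.25, 0.10]
    ranges = [(18, 45), (40, 62), (55, 78), (70, 90), (80, 97)]
    specs = []
    for i, (frac, (lo, hi)) in enumerate(zip(fractions, ranges)):
        specs.append(CohortSpec(name=f"cohort{i + 1}", n=max(1, round(n_total * frac)),
                                age_min=lo, age_max=hi))
    return specs


def subjects_to_frame(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Tabulate subjects: id,cohort,age,sex,history_of_stroke,total_volume_ml
    plus one mL column per tract."""
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "cohort": s.cohort,
            "age": s.age,
            "sex": s.sex,
            "history_of_stroke": s.history_of_stroke,
            "total_volume_ml": s.total_ml,
        }
        for tract in s.true_tract_log10:
            row[f"{tract}_ml"] = s.tract_ml(tract)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy atlas and voxel placement


def generate_toy_atlas(
    dims: tuple[int, int, int],
    n_tracts: int,
    seed: int = 0,
    tract_names: Sequence[str] | None = None,
) -> tuple[ProbabilityVolume, dict[str, ProbabilityVolume]]:
    """A small synthetic template: an ellipsoidal WM probability blob and
    ``n_tracts`` elongated tract probability maps seeded inside its core.

    Stands in for a template-space WM prior plus a probabilistic tract
    atlas; geometry is schematic, only the probabilistic structure matters.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 8 for d in dims):
        raise ValueError(f"grid dims must be three values >= 8, got {dims}")
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    if tract_names is None:
        if n_tracts > len(JHU_TRACT_NAMES):
            raise ValueError(f"at most {len(JHU_TRACT_NAMES)} default tract names")
        tract_names = JHU_TRACT_NAMES[:n_tracts]
    if len(tract_names) != n_tracts:
        raise ValueError("tract_names length must equal n_tracts")

    rng = np.random.default_rng(seed)
    idx = np.indices(dims).astype(float)
    center = (np.array(dims, dtype=float) - 1.0) / 2.0
    semi = np.array(dims, dtype=float) * 0.42
    r = np.sqrt(sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3)))
    wm = np.clip(1.3 * (1.0 - r), 0.0, 1.0)
    wm_prob = ProbabilityVolume(wm, name="wm")

    core = np.argwhere(wm >= 0.6)
    tracts: dict[str, ProbabilityVolume] = {}
    for name in tract_names:
        c = core[rng.integers(len(core))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rel = np.stack([idx[i] - c[i] for i in range(3)])
        along = sum(rel[i] * direction[i] for i in range(3))
        perp2 = sum(rel[i] ** 2 for i in range(3)) - along**2
        half_len = max(dims) * 0.30
        sigma = 1.0 + rng.random() * 0.8
        prob = np.exp(-perp2 / (2 * sigma**2)) * np.clip(
            1.0 - np.abs(along) / half_len, 0.0, 1.0
        )
        prob = np.clip(prob, 0.0, 1.0)
        inside = (prob >= 0.10) & (wm >= 0.30)
        if not inside.any():  # pragma: no cover - core seeding makes this rare
            raise RuntimeError(f"degenerate tract {name!r}; change seed or dims")
        tracts[name] = ProbabilityVolume(prob, name=name)
    return wm_prob, tracts


def _grow_blob(
    region: np.ndarray, n_vox: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow a contiguous-ish random blob of n_vox voxels inside a boolean region."""
    out = np.zeros_like(region, dtype=bool)
    if n_vox == 0:
        return out
    candidates = np.argwhere(region)
    if n_vox > len(candidates):
        raise ValueError(
            f"requested {n_vox} voxels but region budget is {len(candidates)}"
        )
    seed_vox = tuple(candidates[rng.integers(len(candidates))])
    out[seed_vox] = True
    frontier = [seed_vox]
    placed = 1
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while placed < n_vox:
        new_frontier = []
        rng.shuffle(frontier)
        for vox in frontier:
            for dx, dy, dz in offsets:
                nb = (vox[0] + dx, vox[1] + dy, vox[2] + dz)
                if (
                    0 <= nb[0] < region.shape[0]
                    and 0 <= nb[1] < region.shape[1]
                    and 0 <= nb[2] < region.shape[2]
                    and region[nb]
                    and not out[nb]
                ):
                    out[nb] = True
                    new_frontier.append(nb)
                    placed += 1
                    if placed == n_vox:
                        return out
        if not new_frontier:
            # blob hit a wall: restart growth from an unused region voxel
            remaining = candidates[~out[tuple(candidates.T)]]
            nxt = tuple(remaining[rng.integers(len(remaining))])
            out[nxt] = True
            placed += 1
            new_frontier = [nxt]
        frontier = new_frontier
    return out


def generate_wmh_map(
    subject: SyntheticSubject,
    atlas: tuple[ProbabilityVolume, Mapping[str, ProbabilityVolume]],
    voxel_volume: float = 0.001,
    seed: int = 0,
    wm_threshold: float = 0.30,
    tract_threshold: float = 0.10,
) -> LabelVolume:
    """Place a subject's true volumes as voxels on the toy template.

    Each tract's share is grown inside its exclusive region (its own
    thresholded tract map, minus every other tract's region, inside WM);
    the remainder of the total goes to WM voxels outside all tract
    regions. Voxel counts therefore round-trip through volumetry to the
    generative volumes within one voxel per compartment.
    """
    wm_prob, tracts = atlas
    id_key = zlib.crc32(subject.id.encode("utf-8")) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, id_key]))
    wm_region = wm_prob.grid >= wm_threshold

    tract_regions = {
        name: (tv.grid >= tract_threshold) & wm_region for name, tv in tracts.items()
    }
    any_tract = np.zeros(wm_region.shape, dtype=bool)
    for reg in tract_regions.values():
        any_tract |= reg

    total_vox = round(back_transform(subject.true_total_log10) / voxel_volume)
    tract_vox = {
        name: round(subject.tract_ml(name) / voxel_volume)
        for name in tracts
        if name in subject.true_tract_log10
    }
    # keep the sum of tract allocations within the total after rounding
    while sum(tract_vox.values()) > total_vox:
        biggest = max(tract_vox, key=tract_vox.get)
        tract_vox[biggest] -= 1

    mask = np.zeros(wm_region.shape, dtype=bool)
    used = np.zeros(wm_region.shape, dtype=bool)
    for name, n_vox in tract_vox.items():
        exclusive = tract_regions[name].copy()
        for other, reg in tract_regions.items():
            if other != name:
                exclusive &= ~reg
        exclusive &= ~used
        budget = int(exclusive.sum())
        if n_vox > budget:
            raise ValueError(
                f"tract {name!r} needs {n_vox} voxels but its exclusive WM "
                f"region budget is {budget}"
            )
        blob = _grow_blob(exclusive, n_vox, rng)
        mask |= blob
        used |= blob

    remainder = total_vox - int(mask.sum())
    outside = wm_region & ~any_tract & ~used
    budget = int(outside.sum())
    if remainder > budget:
        raise ValueError(
            f"total volume needs {remainder} more voxels but the non-tract WM "
            f"budget is {budget}"
        )
    mask |= _grow_blob(outside, remainder, rng)
    return LabelVolume(mask, voxel_volume=voxel_volume)


def with_seed(params: GenerativeParams, seed: int) -> GenerativeParams:
    return replace(params, seed=seed)
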
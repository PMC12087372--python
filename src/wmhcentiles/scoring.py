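"""Percentile scoring of individual WMH volumes against normative references.

Given age, sex and a volume in mL, the score answers "what fraction of
the reference population at this age and sex has a smaller WMH volume?".
The reference is either the packaged normative table (printed reference
values for total WMH volume, ages 40-85 in 5-year steps, percentiles
5-95) or a fitted centile model.

Interpolation between tabulated percentiles runs on the
normal-equivalent-deviate axis: each percentile p is mapped to
z = Phi^{-1}(p/100), a monotone cubic (PCHIP) is built from
log10-transformed volume to z at the subject's age, and the resulting z
is mapped back to a percentile. This keeps the percentile scale smooth
and kink-free while reproducing every tabulated cell exactly. Volumes
outside the p5-p95 envelope are reported censored ("<5" / ">95") rather
than extrapolated — the reference never tabulates beyond that range.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .normative_model import FittedCentileModel, NormativeTable
from .volumetry import VolumeReport, log_offset_transform

#: SHA-256 of the packaged normative table fixture (guards against corruption).
PACKAGED_TABLE_SHA256 = (
    "fa043c3f679415f37f75c78e5e539d2d67fa8c08912c896e88d8cd2d6669bb1b"
)

AGE_SCORING_RANGE = (18.0, 97.0)


@dataclass
class PercentileScore:
    """An individual's placement on the normative surface."""

    label: str  # e.g. "62", "<5", ">95"
    percentile: float | None  # None when censored
    censored: bool
    source: str  # "packaged_table" | "fitted_model" | "table"
    extrapolated_age: bool
    age: float
    sex: str
    volume_ml: float

    def __str__(self) -> str:
        note = " (age outside reference range)" if self.extrapolated_age else ""
        if self.censored:
            bound = "below the 5th" if self.label.startswith("<") else "above the 95th"
            return (
                f"{self.sex}, age {self.age:g}, {self.volume_ml:g} mL: "
                f"{bound} percentile for age and sex{note}"
            )
        p = round(self.percentile)
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(
            p % 10 if p % 100 not in (11, 12, 13) else 0, "th"
        )
        return (
            f"{self.sex}, age {self.age:g}, {self.volume_ml:g} mL: "
            f"~{p:.0f}{suffix} percentile for age and sex{note}"
        )


def load_packaged_table(sex: str) -> NormativeTable:
    """The packaged normative reference for total WMH volume, one sex.

    Checksummed on load; every row is validated to increase strictly
    across percentiles.
    """
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    ref = resources.files("wmhcentiles").joinpath("data/normative_table.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != PACKAGED_TABLE_SHA256:
        raise ValueError(
            f"packaged normative table checksum mismatch: {digest} "
            f"(expected {PACKAGED_TABLE_SHA256})"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    frame = df[df["sex"] == sex].drop(columns="sex").set_index("age")
    table = NormativeTable(sex=sex, frame=frame)
    table.validate(strict=True)
    return table


def _table_log10_row(table: NormativeTable, age: float) -> tuple[np.ndarray, bool]:
    """Log10-transformed centile volumes at an age, linearly interpolated
    between grid rows; ages beyond the grid clamp to the nearest row and
    are flagged."""
    grid = np.asarray(table.frame.index, dtype=float)
    vals = np.log10(table.frame.to_numpy() + 0.001)
    extrapolated = age < grid.min() or age > grid.max()
    a = float(np.clip(age, grid.min(), grid.max()))
    hi = int(np.searchsorted(grid, a))
    if grid[min(hi, len(grid) - 1)] == a or hi == 0:
        row = vals[min(hi, len(grid) - 1)]
    else:
        lo = hi - 1
        w = (a - grid[lo]) / (grid[hi] - grid[lo])
        row = (1 - w) * vals[lo] + w * vals[hi]
    return row, extrapolated


def score_individual(
    age: float,
    sex: str,
    volume_ml: float,
    reference: NormativeTable | FittedCentileModel | Mapping[str, FittedCentileModel],
) -> PercentileScore:
    """Score one individual against a normative reference.

    The volume is log10(v + 0.001)-transformed and located on the
    reference centiles at the given age via monotone interpolation on the
    normal-equivalent-deviate axis. Non-integer ages are accepted.
    """
    if volume_ml < 0:
        raise ValueError(f"volume must be nonnegative, got {volume_ml}")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    lo, hi = AGE_SCORING_RANGE
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside supported scoring range {lo:g}-{hi:g}")

    if isinstance(reference, Mapping):
        reference = reference[sex]

    if isinstance(reference, NormativeTable):
        if reference.sex != sex:
            raise ValueError(
                f"reference table is for {reference.sex!r}, subject is {sex!r}"
            )
        row, extrapolated = _table_log10_row(reference, age)
        extrapolated = bool(extrapolated)
        pcts = np.array(reference.percentiles, dtype=float)
        source = "packaged_table"
    elif isinstance(reference, FittedCentileModel):
        if reference.sex != sex:
            raise ValueError(
                f"reference model is for {reference.sex!r}, subject is {sex!r}"
            )
        row = reference.curves([age])[:, 0]
        pcts = np.array(reference.taus, dtype=float) * 100.0
        dlo, dhi = reference.age_domain
        extrapolated = not (dlo <= age <= dhi)
        source = "fitted_model"
    else:
        raise TypeError(f"unsupported reference type {type(reference).__name__}")

    x = log_offset_transform(volume_ml)
    if x < row[0]:
        label = f"<{pcts[0]:g}"
        return PercentileScore(label, None, True, source, extrapolated,
                               float(age), sex, float(volume_ml))
    if x > row[-1]:
        label = f">{pcts[-1]:g}"
        return PercentileScore(label, None, True, source, extrapolated,
                               float(age), sex, float(volume_ml))

    z_knots = norm.ppf(pcts / 100.0)
    # strictly increasing abscissa required; collapse exact ties (possible for
    # near-noiseless fitted models) before interpolating
    xs, idx = np.unique(row, return_index=True)
    if len(xs) == 1:
        pct = 50.0
    else:
        interp = PchipInterpolator(xs, z_knots[idx])
        pct = float(100.0 * norm.cdf(interp(x)))
    return PercentileScore(
        label=f"{pct:.0f}", percentile=pct, censored=False, source=source,
        extrapolated_age=extrapolated, age=float(age), sex=sex,
        volume_ml=float(volume_ml),
    )


def score_report(
    report: VolumeReport,
    age: float,
    sex: str,
    references: Mapping[str, NormativeTable | FittedCentileModel | Mapping],
) -> dict[str, PercentileScore]:
    """Score every compartment of a volumetry report that has a reference.

    ``references`` maps compartment name ("total" or a tract name) to a
    normative reference; compartments without a reference are skipped
    with a warning.
    """
    out: dict[str, PercentileScore] = {}
    compartments: dict[str, float] = {"total": report.total_ml}
    compartments.update({t: ml for t, (ml, _lg) in report.per_tract.items()})
    for name, ml in compartments.items():
        if name not in references:
            warnings.warn(f"no reference for compartment {name!r}; skipped",
                          stacklevel=2)
            continue
        out[name] = score_individual(age, sex, ml, references[name])
    return out
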
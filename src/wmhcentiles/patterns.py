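"""Rule-based classification of tract-level centile curve patterns.

Regional WMH accumulation falls into three qualitative classes:

1. total-like — the tract's median volume is above baseline already in
   middle age and rises steadily (periventricular tracts);
2. late-onset — the median stays at baseline until roughly age 60 and
   accelerates afterwards (deep/subcortical tracts);
3. persistently rare — the median never leaves baseline even at advanced
   age (para-sagittal / medial temporal tracts).

"Baseline" is the transform of a zero volume, log10(0.001) = -3. The
visual judgment behind the classes is operationalized with two explicit
parameters: a departure margin ``eps`` above baseline and an onset age
cutoff separating classes 1 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .normative_model import FittedCentileModel

BASELINE_LOG10 = -3.0
DEFAULT_EPS = 0.05
DEFAULT_ONSET_CUT = 60.0


@dataclass
class TractCurveSummary:
    """p10/p50/p90 centile values of one tract on an age grid (log10-mL)."""

    tract: str
    ages: np.ndarray
    p10: np.ndarray
    p50: np.ndarray
    p90: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.p10 = np.asarray(self.p10, dtype=float)
        self.p50 = np.asarray(self.p50, dtype=float)
        self.p90 = np.asarray(self.p90, dtype=float)
        if not (len(self.ages) == len(self.p10) == len(self.p50) == len(self.p90)):
            raise ValueError(f"tract {self.tract!r}: grid/curve length mismatch")
        if ((self.p10 > self.p50 + 1e-9) | (self.p50 > self.p90 + 1e-9)).any():
            raise ValueError(f"tract {self.tract!r}: centile ordering violated")


@dataclass
class PatternLabel:
    """A pattern class plus the evidence it rests on."""

    tract: str
    label: int  # 1, 2 or 3
    onset_age: float | None  # first grid age where p50 departs baseline


def classify_pattern(
    summary: TractCurveSummary,
    baseline: float = BASELINE_LOG10,
    eps: float = DEFAULT_EPS,
    onset_cut: float = DEFAULT_ONSET_CUT,
) -> PatternLabel:
    """Classify one tract's median curve.

    Pattern 3 if the median never exceeds ``baseline + eps`` up to age 85;
    otherwise pattern 2 if the first departure age is >= ``onset_cut``,
    else pattern 1. Grid ages above 85 are ignored, so extending the grid
    upward cannot change the label. The grid must cover at least [45, 85].
    """
    if summary.ages.min() > 45 or summary.ages.max() < 85:
        raise ValueError(
            f"tract {summary.tract!r}: age grid "
            f"[{summary.ages.min():g}, {summary.ages.max():g}] must cover [45, 85]"
        )
    keep = summary.ages <= 85
    ages = summary.ages[keep]
    p50 = summary.p50[keep]
    departed = p50 > baseline + eps
    if not departed.any():
        return PatternLabel(tract=summary.tract, label=3, onset_age=None)
    onset = float(ages[np.argmax(departed)])
    label = 2 if onset >= onset_cut else 1
    return PatternLabel(tract=summary.tract, label=label, onset_age=onset)


def summaries_from_models(
    tract_models: Mapping[str, FittedCentileModel],
    ages: Sequence[float] | None = None,
) -> list[TractCurveSummary]:
    """Evaluate fitted per-tract models into p10/p50/p90 summaries.

    Each model must include taus 0.10, 0.50 and 0.90.
    """
    out = []
    for tract, model in tract_models.items():
        grid = (
            np.asarray(ages, dtype=float)
            if ages is not None
            else np.arange(45.0, 86.0)
        )
        curves = model.curves(grid)
        idx = {t: i for i, t in enumerate(model.taus)}
        missing = {0.10, 0.50, 0.90} - set(idx)
        if missing:
            raise ValueError(f"tract {tract!r}: model lacks taus {sorted(missing)}")
        out.append(
            TractCurveSummary(
                tract=tract, ages=grid,
                p10=curves[idx[0.10]], p50=curves[idx[0.50]], p90=curves[idx[0.90]],
            )
        )
    return out


def summaries_from_volumes(
    ages: Sequence[float],
    volumes_by_tract_ml: Mapping[str, Sequence[float]],
    age_grid: Sequence[float] | None = None,
    window: int = 2,
    min_count: int = 20,
) -> list[TractCurveSummary]:
    """Empirical windowed-quantile curve summaries from raw tract volumes.

    For each grid age, p10/p50/p90 of log10(v + 0.001) are taken over all
    subjects within ``window`` years of that age (a 5-year stratum at the
    default). Unlike a low-df spline fit, these summaries are consistent
    estimators near sharp onsets, which matters for onset-age evidence.
    """
    ages = np.asarray(ages, dtype=float)
    grid = (
        np.asarray(age_grid, dtype=float)
        if age_grid is not None
        else np.arange(45.0, 86.0)
    )
    out = []
    for tract, vols in volumes_by_tract_ml.items():
        x = np.log10(np.asarray(vols, dtype=float) + 0.001)
        p10 = np.empty(len(grid))
        p50 = np.empty(len(grid))
        p90 = np.empty(len(grid))
        for i, a in enumerate(grid):
            sel = np.abs(ages - a) <= window
            if sel.sum() < min_count:
                raise ValueError(
                    f"tract {tract!r}: only {int(sel.sum())} subjects within "
                    f"{window} years of age {a:g} (< {min_count})"
                )
            p10[i], p50[i], p90[i] = np.quantile(x[sel], [0.10, 0.50, 0.90])
        out.append(TractCurveSummary(tract=tract, ages=grid, p10=p10, p50=p50, p90=p90))
    return out


def classify_all(
    summaries: Sequence[TractCurveSummary], **kwargs
) -> pd.DataFrame:
    """Classify many tracts; returns a frame with tract,label,onset_age."""
    rows = []
    for s in summaries:
        lab = classify_pattern(s, **kwargs)
        rows.append({"tract": lab.tract, "label": lab.label,
                     "onset_age": lab.onset_age})
    return pd.DataFrame(rows)


def read_curves_csv(path) -> list[TractCurveSummary]:
    """Read tract curves from CSV with columns tract,age,p10,p50,p90."""
    df = pd.read_csv(path, comment="#")
    required = {"tract", "age", "p10", "p50", "p90"}
    if not required.issubset(df.columns):
        raise ValueError(f"curves CSV needs columns {sorted(required)}")
    out = []
    for tract, grp in df.groupby("tract", sort=False):
        grp = grp.sort_values("age")
        out.append(
            TractCurveSummary(
                tract=str(tract), ages=grp["age"].to_numpy(),
                p10=grp["p10"].to_numpy(), p50=grp["p50"].to_numpy(),
                p90=grp["p90"].to_numpy(),
            )
        )
    return out


def write_curves_csv(summaries: Sequence[TractCurveSummary], path) -> None:
    rows = []
    for s in summaries:
        for i, a in enumerate(s.ages):
            rows.append({"tract": s.tract, "age": a, "p10": s.p10[i],
                         "p50": s.p50[i], "p90": s.p90[i]})
    pd.DataFrame(rows).to_csv(path, index=False)
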
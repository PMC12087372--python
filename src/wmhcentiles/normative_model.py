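"""Sex-stratified spline quantile regression for normative centile curves.

The response is log10(WMH volume + 0.001) and the single continuous
predictor is age. For each quantile level tau, coefficients minimize the
check (pinball) loss ``sum rho_tau(y - X beta)`` exactly, via the linear
programming dual of the problem (HiGHS). Age enters through a B-spline
basis whose dimension is the user-facing "degrees of freedom" delta
(delta = 1 reduces to an affine model). Curves for different taus are fit
independently and made mutually consistent by monotone rearrangement of
the fitted values across taus at each evaluation age, so exported
normative tables can never show crossing percentiles.

Confidence bands come from a participant-level bootstrap: subjects are
resampled with replacement, curves re-estimated, and pointwise 2.5th and
97.5th percentiles of the resulting curve distribution taken as the 95%
band.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.optimize import linprog

from . import __version__ as _pkg_version
from .volumetry import back_transform

DEFAULT_TAUS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)
DEFAULT_AGE_DOMAIN = (40.0, 85.0)
DEFAULT_TABLE_AGES = tuple(range(40, 86, 5))
MIN_PER_SEX = 50


# ---------------------------------------------------------------------------
# Spline basis


@dataclass(frozen=True)
class AgeSplineBasis:
    """B-spline basis for age of dimension ``df``, plus an intercept.

    The full basis of ``df + 1`` functions is a partition of unity on the
    boundary interval; the first function is dropped in favour of an
    explicit intercept column, giving a design matrix of ``df + 1``
    columns. Degree is ``min(3, df)``; interior knots sit at equally
    spaced quantiles of the training ages and boundary knots at the
    1st/99th training-age percentiles. Evaluation outside the boundary
    knots extrapolates the boundary polynomial.
    """

    df: int
    degree: int
    knots: tuple[float, ...]  # full knot vector

    @classmethod
    def from_ages(cls, ages: Sequence[float], df: int) -> "AgeSplineBasis":
        ages = np.asarray(ages, dtype=float)
        if df < 1:
            raise ValueError(f"spline df must be >= 1, got {df}")
        if np.unique(ages).size <= df:
            raise ValueError(
                f"df={df} needs more than {df} distinct ages "
                f"(got {np.unique(ages).size})"
            )
        degree = min(3, df)
        n_interior = df - degree
        lo, hi = np.percentile(ages, [1, 99])
        if hi <= lo:
            raise ValueError("degenerate age range for spline basis")
        interior = (
            np.quantile(ages, np.arange(1, n_interior + 1) / (n_interior + 1))
            if n_interior
            else np.empty(0)
        )
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
        knots = np.concatenate(
            [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
        )
        return cls(df=df, degree=degree, knots=tuple(float(k) for k in knots))

    @classmethod
    def with_interior_knot(
        cls, ages: Sequence[float], df: int, knot: float
    ) -> "AgeSplineBasis":
        """Basis of dimension ``df`` with a single, explicitly placed
        interior knot (degree ``df - 1``, capped at 3)."""
        ages = np.asarray(ages, dtype=float)
        if not 2 <= df <= 4:
            raise ValueError("explicit-knot basis supports df in {2, 3, 4}")
        degree = df - 1
        lo, hi = np.percentile(ages, [1, 99])
        if not lo < knot < hi:
            raise ValueError(f"knot {knot} outside boundary ({lo}, {hi})")
        knots = np.concatenate(
            [np.full(degree + 1, lo), [knot], np.full(degree + 1, hi)]
        )
        return cls(df=df, degree=degree, knots=tuple(float(k) for k in knots))

    @property
    def boundary(self) -> tuple[float, float]:
        return self.knots[0], self.knots[-1]

    @property
    def n_columns(self) -> int:
        return self.df + 1  # intercept + df spline columns

    def full_basis(self, ages) -> np.ndarray:
        """All ``df + 1`` B-spline functions (partition of unity inside the
        boundary knots)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        k = len(self.knots) - self.degree - 1  # == df + 1
        spl = BSpline(np.asarray(self.knots), np.eye(k), self.degree, extrapolate=True)
        return spl(ages)

    def design(self, ages) -> np.ndarray:
        """Design matrix: intercept column then spline columns 2..df+1."""
        B = self.full_basis(ages)
        return np.column_stack([np.ones(len(B)), B[:, 1:]])

    def is_nested_in(self, other: "AgeSplineBasis") -> bool:
        """Nesting in the model-comparison sense used here: same family with
        fewer or equal degrees of freedom."""
        return self.df <= other.df


# ---------------------------------------------------------------------------
# Check-loss fitting


def pinball_loss(y: np.ndarray, fitted: np.ndarray, tau: float) -> float:
    u = np.asarray(y, dtype=float) - np.asarray(fitted, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _fit_primal_lp(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A = sparse.hstack(
        [sparse.csr_matrix(X), sparse.eye(n), -sparse.eye(n)], format="csr"
    )
    res = linprog(
        c,
        A_eq=A,
        b_eq=y,
        bounds=[(None, None)] * p + [(0, None)] * (2 * n),
        method="highs",
    )
    if not res.success:  # pragma: no cover - HiGHS is robust on feasible LPs
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:p]


def fit_pinball(
    X: np.ndarray, y: np.ndarray, tau: float, check_rank: bool = True
) -> np.ndarray:
    """Exact check-loss minimizer for one quantile level.

    Solves the LP dual (n box-constrained variables, p equality
    constraints), reads the optimal basic observations off the dual
    solution, and verifies optimality through the duality gap; on any
    degeneracy it falls back to the primal LP. Minimizers may be
    non-unique — correctness is defined by the attained loss.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"design/response mismatch: {X.shape} vs {y.shape}")
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p})")
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    if check_rank and np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    res = linprog(
        -y,
        A_eq=X.T,
        b_eq=(1.0 - tau) * X.sum(axis=0),
        bounds=[(0.0, 1.0)] * n,
        method="highs",
    )
    if res.success:
        a = res.x
        # complementary slackness: observations with interior dual values have
        # zero residual; ties in the design (whole-year ages) can make this
        # set larger than p, so solve it in the least-squares sense
        interior = np.where((a > 1e-8) & (a < 1.0 - 1e-8))[0]
        if len(interior) < p:
            interior = np.argsort(np.minimum(a, 1.0 - a))[::-1][:p]
        beta, *_ = np.linalg.lstsq(X[interior], y[interior], rcond=None)
        # strong duality: optimal check loss equals the dual optimum after
        # undoing the a = nu + (1 - tau) substitution
        dual_opt = -res.fun - (1.0 - tau) * y.sum()
        gap = pinball_loss(y, X @ beta, tau) - dual_opt
        if abs(gap) <= 1e-7 * max(1.0, abs(dual_opt)):
            return beta
    return _fit_primal_lp(X, y, tau)


def search_age_basis(
    ages: Sequence[float], y: Sequence[float], df: int, tau: float = 0.5
) -> AgeSplineBasis:
    """Free-knot basis selection: place the single interior knot where the
    check loss of the tau-level fit is smallest.

    Profiles the knot over the distinct training ages between the 10th and
    90th age percentiles. Useful for curves with a localized change of
    regime (late-onset tract accumulation), where quantile-placed knots
    land far from the knee.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = np.percentile(ages, [10, 90])
    candidates = np.unique(ages[(ages >= lo) & (ages <= hi)])
    if candidates.size < 2:
        raise ValueError("too few distinct ages to search a knot")
    best: tuple[float, AgeSplineBasis] | None = None
    for k in candidates:
        basis = AgeSplineBasis.with_interior_knot(ages, df, float(k))
        X = basis.design(ages)
        beta = fit_pinball(X, y, tau, check_rank=False)
        loss = pinball_loss(y, X @ beta, tau)
        if best is None or loss < best[0] - 1e-12:
            best = (loss, basis)
    return best[1]


# ---------------------------------------------------------------------------
# Model containers


@dataclass
class QuantileModelSpec:
    """What to fit: quantile levels, spline df, age domain, covariates."""

    taus: tuple[float, ...] = DEFAULT_TAUS
    df: int = 4
    age_domain: tuple[float, float] = DEFAULT_AGE_DOMAIN
    covariates: tuple[str, ...] = ()
    knot_rule: str = "quantile"  # or "search": profile the interior knot

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.taus)
        if not taus or any(not 0 < t < 1 for t in taus):
            raise ValueError(f"taus must lie in (0,1): {taus}")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError(f"taus must be strictly increasing: {taus}")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.knot_rule not in ("quantile", "search"):
            raise ValueError(f"unknown knot_rule {self.knot_rule!r}")
        self.taus = taus
        self.covariates = tuple(self.covariates)


@dataclass(frozen=True)
class SubjectRecord:
    """One modeling record: age, sex, log10-transformed response."""

    id: str
    age: float
    sex: str
    y: float
    covariates: Mapping[str, str] = field(default_factory=dict)
    history_of_stroke: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.y):
            raise ValueError(f"record {self.id!r}: response must be finite")
        if self.age < 18:
            raise ValueError(f"record {self.id!r}: age must be >= 18, got {self.age}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"record {self.id!r}: unknown sex {self.sex!r}")


def records_from_frame(
    frame: pd.DataFrame,
    value_column: str = "total_volume_ml",
    covariates: Sequence[str] = (),
) -> list[SubjectRecord]:
    """Build modeling records from a subject table; volumes in mL are
    log10(v + 0.001)-transformed."""
    from .volumetry import log_offset_transform

    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        out.append(
            SubjectRecord(
                id=str(d["id"]),
                age=float(d["age"]),
                sex=str(d["sex"]),
                y=log_offset_transform(float(d[value_column])),
                covariates={c: str(d[c]) for c in covariates},
                history_of_stroke=bool(d.get("history_of_stroke", False)),
            )
        )
    return out


@dataclass
class FittedCentileModel:
    """Per-sex fitted centile model: basis, per-tau coefficients, diagnostics."""

    sex: str
    basis: AgeSplineBasis
    taus: tuple[float, ...]
    coef: dict[float, np.ndarray]
    age_domain: tuple[float, float]
    covariate_levels: dict[str, list[str]] = field(default_factory=dict)
    pinball: dict[float, float] = field(default_factory=dict)
    n: int = 0

    def design(self, ages) -> np.ndarray:
        """Design at reference covariate levels (covariate columns zero)."""
        X = self.basis.design(ages)
        n_extra = sum(len(v) - 1 for v in self.covariate_levels.values())
        if n_extra:
            X = np.column_stack([X, np.zeros((X.shape[0], n_extra))])
        return X

    def raw_curve(self, ages, tau: float) -> np.ndarray:
        if tau not in self.coef:
            raise KeyError(
                f"tau {tau} not in fitted taus {sorted(self.coef)}; "
                "no interpolation between taus at this layer"
            )
        return self.design(ages) @ self.coef[tau]

    def curves(self, ages) -> np.ndarray:
        """Monotone-rearranged fitted values, shape (n_taus, n_ages).

        At each age the independently fitted values are sorted across
        taus, which repairs any quantile crossing without changing the
        multiset of values at that age.
        """
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        raw = np.stack([self.raw_curve(ages, t) for t in self.taus])
        return np.sort(raw, axis=0)

    def covariate_effects(self) -> dict[str, dict[str, dict[float, float]]]:
        """Per-tau additive offsets of non-reference covariate levels."""
        out: dict[str, dict[str, dict[float, float]]] = {}
        pos = self.basis.n_columns
        for name, levels in self.covariate_levels.items():
            out[name] = {}
            for lvl in levels[1:]:
                out[name][lvl] = {t: float(self.coef[t][pos]) for t in self.taus}
                pos += 1
        return out


@dataclass
class CentileValue:
    value: float
    tau: float
    age: float
    extrapolated: bool


def evaluate_centile(model: FittedCentileModel, age: float, tau: float) -> CentileValue:
    """Evaluate one (monotone-repaired) centile at an age.

    Ages outside the model's stated domain are evaluated anyway but
    flagged as extrapolated — confidence degrades quickly past the
    well-sampled range.
    """
    if tau not in model.taus:
        raise KeyError(
            f"tau {tau} not among fitted taus {model.taus}; "
            "no interpolation between taus at this layer"
        )
    vals = model.curves([age])[:, 0]
    i = model.taus.index(tau)
    lo, hi = model.age_domain
    return CentileValue(
        value=float(vals[i]), tau=tau, age=float(age),
        extrapolated=not (lo <= age <= hi),
    )


# ---------------------------------------------------------------------------
# Fitting


def _build_design(
    records: Sequence[SubjectRecord],
    basis: AgeSplineBasis,
    covariates: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, dict[str, list[str]]]:
    ages = np.array([r.age for r in records], dtype=float)
    y = np.array([r.y for r in records], dtype=float)
    X = basis.design(ages)
    levels: dict[str, list[str]] = {}
    for name in covariates:
        vals = [r.covariates.get(name, "") for r in records]
        if any(v == "" for v in vals):
            raise ValueError(f"covariate {name!r} missing for some records")
        lv = sorted(set(vals))
        if len(lv) < 2:
            raise ValueError(f"covariate {name!r} has a single level {lv}")
        levels[name] = lv
        for other in lv[1:]:  # first level is the reference
            X = np.column_stack([X, np.array([v == other for v in vals], dtype=float)])
    return X, y, levels


def fit_centile_model(
    records: Sequence[SubjectRecord],
    spec: QuantileModelSpec | None = None,
    exclude_stroke: bool = False,
    min_per_sex: int = MIN_PER_SEX,
) -> dict[str, FittedCentileModel]:
    """Fit one centile model per sex.

    ``exclude_stroke`` drops subjects with a history of stroke before
    fitting (sensitivity-analysis style). A sex stratum smaller than
    ``min_per_sex`` is skipped with a warning rather than fit unstably.
    """
    spec = spec if spec is not None else QuantileModelSpec()
    if exclude_stroke:
        records = [r for r in records if not r.history_of_stroke]
    out: dict[str, FittedCentileModel] = {}
    for sex in ("female", "male"):
        stratum = [r for r in records if r.sex == sex]
        if len(stratum) < min_per_sex:
            warnings.warn(
                f"sex stratum {sex!r} has {len(stratum)} records "
                f"(< {min_per_sex}); skipped",
                stacklevel=2,
            )
            continue
        ages = [r.age for r in stratum]
        if spec.knot_rule == "search":
            basis = search_age_basis(ages, [r.y for r in stratum], spec.df)
        else:
            basis = AgeSplineBasis.from_ages(ages, spec.df)
        X, y, levels = _build_design(stratum, basis, spec.covariates)
        coef: dict[float, np.ndarray] = {}
        losses: dict[float, float] = {}
        for tau in spec.taus:
            beta = fit_pinball(X, y, tau)
            coef[tau] = beta
            losses[tau] = pinball_loss(y, X @ beta, tau)
        out[sex] = FittedCentileModel(
            sex=sex,
            basis=basis,
            taus=spec.taus,
            coef=coef,
            age_domain=spec.age_domain,
            covariate_levels=levels,
            pinball=losses,
            n=len(stratum),
        )
    return out


# ---------------------------------------------------------------------------
# Degrees-of-freedom comparison


@dataclass
class DfComparison:
    """Nested spline-df comparison for one sex."""

    sex: str
    df_small: int
    df_large: int
    loss_small: dict[float, float]
    loss_large: dict[float, float]
    loss_reduction: dict[float, float]  # per-observation
    p_value: dict[float, float]
    recommended_df: int
    n: int
    B: int


def compare_df(
    records: Sequence[SubjectRecord],
    spec: QuantileModelSpec,
    df_small: int,
    df_large: int,
    B: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    min_per_sex: int = MIN_PER_SEX,
) -> dict[str, DfComparison]:
    """Does raising the spline df improve the fit beyond overfitting noise?

    For each sex and tau the statistic is the per-observation check-loss
    reduction of the larger model. Its null distribution is approximated
    by a subject-level bootstrap: both models are refit on resamples and
    the resampled reductions, recentred at the observed reduction, give a
    one-sided p-value. The larger df is recommended only if significant at
    ``alpha`` for the median (tau closest to 0.5); the returned losses
    support the visual-assessment step that should follow.
    """
    if df_small >= df_large:
        raise ValueError("df_small must be < df_large (nested comparison)")
    out: dict[str, DfComparison] = {}
    rng = np.random.default_rng(seed)
    for sex in ("female", "male"):
        stratum = [r for r in records if r.sex == sex]
        if len(stratum) < min_per_sex:
            continue
        ages = [r.age for r in stratum]
        y = np.array([r.y for r in stratum])
        n = len(stratum)
        Xs = AgeSplineBasis.from_ages(ages, df_small).design(ages)
        Xl = AgeSplineBasis.from_ages(ages, df_large).design(ages)

        loss_s, loss_l, reduction = {}, {}, {}
        for tau in spec.taus:
            bs = fit_pinball(Xs, y, tau)
            bl = fit_pinball(Xl, y, tau)
            loss_s[tau] = pinball_loss(y, Xs @ bs, tau)
            loss_l[tau] = pinball_loss(y, Xl @ bl, tau)
            reduction[tau] = (loss_s[tau] - loss_l[tau]) / n

        boot = {tau: [] for tau in spec.taus}
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            Xsb, Xlb = Xs[idx], Xl[idx]
            for tau in spec.taus:
                ls = pinball_loss(yb, Xsb @ fit_pinball(Xsb, yb, tau), tau)
                ll = pinball_loss(yb, Xlb @ fit_pinball(Xlb, yb, tau), tau)
                boot[tau].append((ls - ll) / n)
        pvals = {}
        for tau in spec.taus:
            centred = np.array(boot[tau]) - reduction[tau]
            pvals[tau] = float((np.sum(centred >= reduction[tau]) + 1) / (B + 1))

        tau_mid = min(spec.taus, key=lambda t: abs(t - 0.5))
        recommended = df_large if pvals[tau_mid] < alpha else df_small
        out[sex] = DfComparison(
            sex=sex, df_small=df_small, df_large=df_large,
            loss_small=loss_s, loss_large=loss_l, loss_reduction=reduction,
            p_value=pvals, recommended_df=recommended, n=n, B=B,
        )
    return out


# ---------------------------------------------------------------------------
# Bootstrap confidence bands


@dataclass
class CentileBands:
    """Pointwise 95% bootstrap bands around the fitted centile curves."""

    sex: str
    ages: np.ndarray
    taus: tuple[float, ...]
    point: np.ndarray  # (n_taus, n_ages)
    lower: np.ndarray
    upper: np.ndarray
    B: int
    n_redrawn: int = 0


def bootstrap_bands(
    records: Sequence[SubjectRecord],
    spec: QuantileModelSpec | None = None,
    B: int = 1000,
    taus_subset: Sequence[float] = (0.10, 0.50, 0.90),
    seed: int = 0,
    ages: Sequence[float] | None = None,
    exclude_stroke: bool = False,
    min_per_sex: int = MIN_PER_SEX,
) -> dict[str, CentileBands]:
    """Participant-resampling bootstrap of the centile curves.

    Each iteration resamples subjects with replacement from the full
    record list, refits per sex, and evaluates the repaired curves on the
    age grid; the 2.5th/97.5th pointwise percentiles over iterations form
    the band. Iterations whose resample leaves a sex stratum below the
    floor are redrawn (and counted). Bands are widened, if necessary, to
    contain the full-sample point estimate.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    base_spec = spec if spec is not None else QuantileModelSpec()
    taus = tuple(sorted(float(t) for t in taus_subset))
    sub_spec = QuantileModelSpec(
        taus=taus, df=base_spec.df, age_domain=base_spec.age_domain,
        covariates=base_spec.covariates,
    )
    if exclude_stroke:
        records = [r for r in records if not r.history_of_stroke]
    records = list(records)
    n = len(records)
    if ages is None:
        lo, hi = base_spec.age_domain
        ages = np.arange(float(lo), float(hi) + 1)
    ages = np.asarray(ages, dtype=float)

    point_fit = fit_centile_model(records, sub_spec, min_per_sex=min_per_sex)
    sexes = sorted(point_fit)
    if not sexes:
        raise ValueError("no sex stratum reaches the fitting floor")

    # Precompute, per sex: the full-record design under that sex's basis
    # (knots are held at the full-sample fit, the standard choice for curve
    # bootstraps) and the design of the evaluation grid.
    sex_arr = np.array([r.sex for r in records])
    all_X: dict[str, np.ndarray] = {}
    grid_X: dict[str, np.ndarray] = {}
    y_arr = np.array([r.y for r in records], dtype=float)
    ages_arr = np.array([r.age for r in records], dtype=float)
    for sex in sexes:
        basis = point_fit[sex].basis
        if point_fit[sex].covariate_levels:
            # covariate designs need stratum-level rebuilds per resample; use
            # the record-level path below for covariate models
            all_X[sex] = None
        else:
            all_X[sex] = basis.design(ages_arr)
        grid_X[sex] = point_fit[sex].design(ages)

    rng = np.random.default_rng(seed)
    curves = {sex: np.empty((B, len(taus), len(ages))) for sex in sexes}
    n_redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        sel = {sex: idx[sex_arr[idx] == sex] for sex in sexes}
        if any(len(s) < min_per_sex for s in sel.values()):
            n_redrawn += 1
            continue
        try:
            if all(all_X[sex] is not None for sex in sexes):
                for sex in sexes:
                    Xb, yb = all_X[sex][sel[sex]], y_arr[sel[sex]]
                    raw = np.stack(
                        [grid_X[sex] @ fit_pinball(Xb, yb, t, check_rank=False)
                         for t in taus]
                    )
                    curves[sex][b] = np.sort(raw, axis=0)
            else:
                resample = [records[i] for i in idx]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    refit = fit_centile_model(
                        resample, sub_spec, min_per_sex=min_per_sex
                    )
                if set(refit) != set(sexes):
                    n_redrawn += 1
                    continue
                for sex in sexes:
                    curves[sex][b] = refit[sex].curves(ages)
        except (np.linalg.LinAlgError, ValueError, RuntimeError):
            n_redrawn += 1
            continue
        b += 1

    out = {}
    for sex in sexes:
        point = point_fit[sex].curves(ages)
        lower = np.percentile(curves[sex], 2.5, axis=0)
        upper = np.percentile(curves[sex], 97.5, axis=0)
        out[sex] = CentileBands(
            sex=sex, ages=ages, taus=taus, point=point,
            lower=np.minimum(lower, point), upper=np.maximum(upper, point),
            B=B, n_redrawn=n_redrawn,
        )
    return out


# ---------------------------------------------------------------------------
# Normative table


@dataclass
class NormativeTable:
    """Sex-specific table of centile volumes (mL) on an age grid."""

    sex: str
    frame: pd.DataFrame  # index: age; columns: p5..p95 (or the fitted taus)

    def __post_init__(self) -> None:
        if self.frame.index.name != "age":
            self.frame = self.frame.copy()
            self.frame.index.name = "age"

    @property
    def percentiles(self) -> list[int]:
        return [int(c[1:]) for c in self.frame.columns]

    def value(self, age: float, percentile: int) -> float:
        return float(self.frame.loc[age, f"p{percentile}"])

    def validate(self, strict: bool = True) -> None:
        vals = self.frame.to_numpy()
        if (vals < 0).any():
            raise ValueError("normative volumes must be nonnegative")
        diffs = np.diff(vals, axis=1)
        if strict and not (diffs > 0).all():
            raise ValueError("percentile columns must strictly increase per age row")
        if not strict and (diffs < 0).any():
            raise ValueError("percentile columns must be nondecreasing per age row")


def export_normative_table(
    model: FittedCentileModel, ages: Sequence[float] = DEFAULT_TABLE_AGES
) -> NormativeTable:
    """Evaluate the repaired centile curves on an age grid and
    back-transform to mL. Full precision is retained; round only for
    display."""
    ages = list(ages)
    vals = model.curves(ages)  # (n_taus, n_ages), log10 scale
    cols = {
        f"p{round(t * 100):d}": [back_transform(v) for v in vals[i]]
        for i, t in enumerate(model.taus)
    }
    frame = pd.DataFrame(cols, index=pd.Index(ages, name="age"))
    table = NormativeTable(sex=model.sex, frame=frame)
    table.validate(strict=False)
    return table


def write_table_csv(tables: Mapping[str, NormativeTable] | NormativeTable, path) -> None:
    """CSV with columns sex,age,p5,...,p95 (one file may hold both sexes)."""
    if isinstance(tables, NormativeTable):
        tables = {tables.sex: tables}
    frames = []
    for sex in sorted(tables):
        f = tables[sex].frame.reset_index()
        f.insert(0, "sex", sex)
        frames.append(f)
    # repr round-trips doubles exactly; pandas' default formatting does not
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )


def read_table_csv(path) -> dict[str, NormativeTable]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = {}
    for sex, grp in df.groupby("sex"):
        frame = grp.drop(columns="sex").set_index("age")
        out[str(sex)] = NormativeTable(sex=str(sex), frame=frame)
    return out


# ---------------------------------------------------------------------------
# Model (de)serialization


def model_to_json(models: Mapping[str, FittedCentileModel]) -> str:
    payload = {"format": "wmhcentiles-model", "version": _pkg_version, "models": {}}
    for sex, m in models.items():
        payload["models"][sex] = {
            "sex": m.sex,
            "basis": {"df": m.basis.df, "degree": m.basis.degree,
                      "knots": list(m.basis.knots)},
            "taus": list(m.taus),
            "coef": {str(t): list(map(float, m.coef[t])) for t in m.taus},
            "age_domain": list(m.age_domain),
            "covariate_levels": m.covariate_levels,
            "pinball": {str(t): m.pinball.get(t) for t in m.taus},
            "n": m.n,
        }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> dict[str, FittedCentileModel]:
    payload = json.loads(text)
    if payload.get("format") != "wmhcentiles-model":
        raise ValueError("not a wmhcentiles model file")
    out = {}
    for sex, d in payload["models"].items():
        basis = AgeSplineBasis(
            df=d["basis"]["df"], degree=d["basis"]["degree"],
            knots=tuple(d["basis"]["knots"]),
        )
        taus = tuple(d["taus"])
        out[sex] = FittedCentileModel(
            sex=d["sex"], basis=basis, taus=taus,
            coef={t: np.array(d["coef"][str(t)]) for t in taus},
            age_domain=tuple(d["age_domain"]),
            covariate_levels={k: list(v) for k, v in d["covariate_levels"].items()},
            pinball={t: d["pinball"].get(str(t)) for t in taus},
            n=d["n"],
        )
    return out
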
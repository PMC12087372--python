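import json

import numpy as np
import pytest

from wmhcentiles import normative_model as nm
from wmhcentiles import synthetic_data as sd

from conftest import make_linear_records


def brute_force_intercept_loss(y, tau, n_grid=20001):
    """Independent oracle: grid-search the best constant under check loss."""
    y = np.asarray(y, dtype=float)
    grid = np.linspace(y.min(), y.max(), n_grid)
    grid = np.unique(np.concatenate([grid, y]))  # order statistics included
    losses = [np.sum((y - g) * (tau - (y < g))) for g in grid]
    return float(np.min(losses))


class TestAgeSplineBasis:
    def test_df1_is_affine(self):
        ages = np.arange(40, 91)
        basis = nm.AgeSplineBasis.from_ages(ages, 1)
        X = basis.design(ages)
        assert X.shape == (51, 2)
        # second column affine in age: second differences vanish
        assert np.allclose(np.diff(X[:, 1], 2), 0, atol=1e-10)

    @pytest.mark.parametrize("df", [1, 2, 3, 4, 6])
    def test_partition_of_unity(self, df):
        ages = np.arange(30, 95)
        basis = nm.AgeSplineBasis.from_ages(ages, df)
        lo, hi = basis.boundary
        inside = np.linspace(lo, hi, 200)
        assert np.allclose(basis.full_basis(inside).sum(axis=1), 1.0, atol=1e-9)

    def test_evaluation_deterministic(self):
        ages = np.arange(40, 91)
        basis = nm.AgeSplineBasis.from_ages(ages, 4)
        assert np.array_equal(basis.design(ages), basis.design(ages))

    def test_df_exceeding_distinct_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            nm.AgeSplineBasis.from_ages([50, 51, 52], 3)

    def test_affine_functions_representable(self):
        # linear precision: an affine target is fit exactly at any df
        ages = np.arange(40, 91).astype(float)
        y = -1.0 + 0.03 * ages
        for df in (1, 2, 4):
            X = nm.AgeSplineBasis.from_ages(ages, df).design(ages)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert np.allclose(X @ beta, y, atol=1e-9)


class TestFitPinball:
    def test_intercept_only_median(self):
        X = np.ones((5, 1))
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        beta = nm.fit_pinball(X, y, 0.5)
        assert beta[0] == pytest.approx(3.0)

    def test_intercept_only_tau09_matches_grid_search(self):
        X = np.ones((10, 1))
        y = np.arange(1.0, 11.0)
        beta = nm.fit_pinball(X, y, 0.9)
        assert 9.0 <= beta[0] <= 10.0
        loss = nm.pinball_loss(y, X @ beta, 0.9)
        assert loss == pytest.approx(brute_force_intercept_loss(y, 0.9), abs=1e-8)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(5, 51))
            tau = float(rng.uniform(0.05, 0.95))
            y = rng.normal(size=n) * rng.uniform(0.5, 3)
            beta = nm.fit_pinball(np.ones((n, 1)), y, tau)
            loss = nm.pinball_loss(y, np.full(n, beta[0]), tau)
            assert loss <= brute_force_intercept_loss(y, tau) + 1e-8

    def test_slope_recovery_median_regression(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(40, 90, size=2000)
        y = 2.0 + 0.1 * ages + rng.normal(0, 0.5, size=2000)
        X = np.column_stack([np.ones(2000), ages])
        beta = nm.fit_pinball(X, y, 0.5)
        assert beta[1] == pytest.approx(0.1, abs=0.02)

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            nm.fit_pinball(X, np.arange(20.0), 0.5)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            nm.fit_pinball(np.ones((5, 1)), np.arange(5.0), 1.5)

    def test_matches_statsmodels_loss(self):
        # independent cross-check: the IRLS solver of statsmodels should not
        # beat the exact LP minimizer
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 3))])
        y = X @ np.array([1.0, 0.5, -0.3, 0.2]) + rng.normal(size=300)
        for tau in (0.1, 0.5, 0.9):
            ours = nm.fit_pinball(X, y, tau)
            theirs = sm.QuantReg(y, X).fit(q=tau).params
            l_ours = nm.pinball_loss(y, X @ ours, tau)
            l_theirs = nm.pinball_loss(y, X @ np.asarray(theirs), tau)
            assert l_ours <= l_theirs + 1e-6


class TestFitCentileModel:
    def test_noiseless_p50_reproduces_generative_median(self, gen_params):
        import dataclasses

        params = dataclasses.replace(gen_params, noise_scale=1e-9)
        subs = sd.generate_cohort(
            [sd.CohortSpec("c", 400, 40, 90, female_fraction=1.0,
                           stroke_fraction=0.0)],
            params, seed=3,
        )
        recs = [nm.SubjectRecord(s.id, s.age, s.sex, s.true_total_log10)
                for s in subs]
        spec = nm.QuantileModelSpec(taus=(0.5,), df=4)
        model = nm.fit_centile_model(recs, spec)["female"]
        for age in sorted({r.age for r in recs}):
            fitted = model.raw_curve([age], 0.5)[0]
            assert fitted == pytest.approx(
                params.median_log10(age, "female"), abs=1e-6
            )

    def test_small_stratum_skipped_with_warning(self, small_records):
        few = [r for r in small_records if r.sex == "female"][:30]
        with pytest.warns(UserWarning, match="skipped"):
            out = nm.fit_centile_model(few)
        assert out == {}

    def test_covariate_offset_recovery(self):
        rng = np.random.default_rng(17)
        recs = []
        for i in range(2000):
            age = int(rng.integers(40, 91))
            grp = "b" if rng.random() < 0.5 else "a"
            y = -1.5 + 0.03 * age + (0.1 if grp == "b" else 0.0) + rng.normal(0, 0.3)
            recs.append(nm.SubjectRecord(f"s{i}", age, "female", float(y),
                                         covariates={"site": grp}))
        spec = nm.QuantileModelSpec(taus=(0.5,), df=2, covariates=("site",))
        model = nm.fit_centile_model(recs, spec)["female"]
        offset = model.covariate_effects()["site"]["b"][0.5]
        assert offset == pytest.approx(0.1, abs=0.03)

    def test_exclude_stroke_lowers_median(self):
        params = sd.GenerativeParams(stroke_offset=0.5)
        subs = sd.generate_cohort(
            [sd.CohortSpec("c", 1500, 40, 90, female_fraction=1.0,
                           stroke_fraction=0.3)],
            params, seed=13,
        )
        recs = [nm.SubjectRecord(s.id, s.age, s.sex, s.true_total_log10,
                                 history_of_stroke=s.history_of_stroke)
                for s in subs]
        spec = nm.QuantileModelSpec(taus=(0.5,), df=2)
        with_stroke = nm.fit_centile_model(recs, spec)["female"]
        without = nm.fit_centile_model(recs, spec, exclude_stroke=True)["female"]
        ages = np.arange(45, 86)
        assert (without.curves(ages) < with_stroke.curves(ages)).mean() > 0.9


class TestCompareDf:
    def test_equal_df_rejected(self, small_records):
        spec = nm.QuantileModelSpec(taus=(0.5,), df=2)
        with pytest.raises(ValueError, match="df_small"):
            nm.compare_df(small_records, spec, 3, 3)

    def test_linear_truth_retains_small_df(self):
        spec = nm.QuantileModelSpec(taus=(0.5,), df=1)
        keep = 0
        reps = 10
        for rep in range(reps):
            recs = make_linear_records(400, seed=100 + rep)
            cmp = nm.compare_df(recs, spec, 1, 4, B=60, seed=rep)["female"]
            keep += cmp.recommended_df == 1
        assert keep >= 0.9 * reps

    def test_curved_truth_prefers_large_df(self):
        rng = np.random.default_rng(5)
        recs = []
        for i in range(600):
            age = int(rng.integers(40, 91))
            y = -1.0 + 0.5 * np.sin((age - 40) / 8.0) + rng.normal(0, 0.2)
            recs.append(nm.SubjectRecord(f"s{i}", age, "female", float(y)))
        spec = nm.QuantileModelSpec(taus=(0.5,), df=1)
        cmp = nm.compare_df(recs, spec, 1, 6, B=60, seed=0)["female"]
        assert cmp.recommended_df == 6
        assert cmp.loss_reduction[0.5] > 0

    def test_losses_nested_ordering(self, small_records):
        spec = nm.QuantileModelSpec(taus=(0.25, 0.5, 0.75), df=2)
        cmp = nm.compare_df(small_records, spec, 1, 4, B=10, seed=1)
        for sex, c in cmp.items():
            for tau in spec.taus:
                assert c.loss_large[tau] <= c.loss_small[tau] + 1e-9


class TestBootstrapBands:
    def test_bands_contain_point_estimate(self, small_records):
        spec = nm.QuantileModelSpec(taus=(0.1, 0.5, 0.9), df=2)
        bands = nm.bootstrap_bands(small_records, spec, B=30, seed=4)
        for b in bands.values():
            assert (b.lower <= b.point + 1e-12).all()
            assert (b.upper >= b.point - 1e-12).all()

    def test_near_noiseless_band_width_vanishes(self, gen_params):
        import dataclasses

        params = dataclasses.replace(gen_params, noise_scale=1e-9)
        subs = sd.generate_cohort(
            [sd.CohortSpec("c", 300, 40, 90, female_fraction=1.0,
                           stroke_fraction=0.0)],
            params, seed=6,
        )
        recs = [nm.SubjectRecord(s.id, s.age, s.sex, s.true_total_log10)
                for s in subs]
        spec = nm.QuantileModelSpec(taus=(0.5,), df=2)
        bands = nm.bootstrap_bands(recs, spec, B=40, seed=1,
                                   ages=np.arange(45.0, 86.0))
        b = bands["female"]
        assert (b.upper - b.lower).max() < 1e-6

    def test_deterministic_given_seed(self, small_records):
        spec = nm.QuantileModelSpec(taus=(0.5,), df=2)
        b1 = nm.bootstrap_bands(small_records, spec, B=20, seed=9)
        b2 = nm.bootstrap_bands(small_records, spec, B=20, seed=9)
        for sex in b1:
            assert np.array_equal(b1[sex].lower, b2[sex].lower)
            assert np.array_equal(b1[sex].upper, b2[sex].upper)

    def test_b_floor(self, small_records):
        with pytest.raises(ValueError, match="B"):
            nm.bootstrap_bands(small_records, B=1)


@pytest.fixture(scope="module")
def fitted(small_records):
    spec = nm.QuantileModelSpec(df=4)
    return nm.fit_centile_model(small_records, spec)["female"]


class TestEvaluateAndExport:
    def test_extrapolation_flag_boundary_contract(self, fitted):
        assert not nm.evaluate_centile(fitted, 40, 0.5).extrapolated
        assert not nm.evaluate_centile(fitted, 85, 0.5).extrapolated
        assert nm.evaluate_centile(fitted, 86, 0.5).extrapolated
        assert nm.evaluate_centile(fitted, 39, 0.5).extrapolated

    def test_unknown_tau_rejected(self, fitted):
        with pytest.raises(KeyError, match="interpolation"):
            nm.evaluate_centile(fitted, 60, 0.42)

    def test_monotone_across_taus_everywhere(self, fitted):
        for age in np.linspace(40, 85, 40):
            vals = [nm.evaluate_centile(fitted, age, t).value
                    for t in fitted.taus]
            assert vals == sorted(vals)

    def test_repair_only_reorders_values(self, fitted):
        ages = np.linspace(40, 85, 20)
        raw = np.stack([fitted.raw_curve(ages, t) for t in fitted.taus])
        repaired = fitted.curves(ages)
        for j in range(len(ages)):
            assert np.allclose(sorted(raw[:, j]), repaired[:, j])

    def test_exported_table_rows_nondecreasing(self, fitted):
        table = nm.export_normative_table(fitted)
        vals = table.frame.to_numpy()
        assert (np.diff(vals, axis=1) >= 0).all()
        assert (vals >= 0).all()
        assert list(table.frame.index) == list(range(40, 86, 5))

    def test_table_csv_round_trip(self, fitted, tmp_path):
        table = nm.export_normative_table(fitted)
        path = tmp_path / "table.csv"
        nm.write_table_csv(table, path)
        back = nm.read_table_csv(path)["female"]
        assert np.array_equal(back.frame.to_numpy(), table.frame.to_numpy())

    def test_model_json_round_trip(self, fitted, tmp_path):
        text = nm.model_to_json({"female": fitted})
        back = nm.model_from_json(text)["female"]
        ages = np.linspace(40, 85, 30)
        assert np.allclose(back.curves(ages), fitted.curves(ages), atol=0)

    def test_fit_beats_intercept_only_loss(self, small_records):
        spec = nm.QuantileModelSpec(taus=(0.1, 0.5, 0.9), df=4)
        model = nm.fit_centile_model(small_records, spec)["female"]
        stratum = [r for r in small_records if r.sex == "female"]
        y = np.array([r.y for r in stratum])
        for tau in spec.taus:
            flat = nm.fit_pinball(np.ones((len(y), 1)), y, tau)
            assert model.pinball[tau] <= nm.pinball_loss(
                y, np.full(len(y), flat[0]), tau
            ) + 1e-9


class TestKnotSearch:
    def test_search_never_worse_than_quantile_rule_on_kink(self):
        rng = np.random.default_rng(31)
        ages = rng.integers(40, 91, size=1500).astype(float)
        y = np.where(ages < 62, -3.0, -3.0 + 0.12 * (ages - 62))
        y = y + rng.normal(0, 0.05, size=len(ages))
        q_basis = nm.AgeSplineBasis.from_ages(ages, 2)
        s_basis = nm.search_age_basis(ages, y, 2)
        for basis in (q_basis, s_basis):
            X = basis.design(ages)
            b = nm.fit_pinball(X, y, 0.5)
            if basis is q_basis:
                loss_q = nm.pinball_loss(y, X @ b, 0.5)
            else:
                loss_s = nm.pinball_loss(y, X @ b, 0.5)
        assert loss_s <= loss_q + 1e-9
        # the searched knee lands near the true change point
        interior = [k for k in s_basis.knots
                    if s_basis.boundary[0] < k < s_basis.boundary[1]]
        assert len(interior) == 1
        assert abs(interior[0] - 62) <= 3


class TestParameterRecovery:
    def test_error_shrinks_with_n(self, gen_params):
        errs = {}
        for n, seed in ((500, 51), (5000, 52)):
            subs = sd.generate_cohort(
                [sd.CohortSpec("c", n, 40, 90, female_fraction=1.0,
                               stroke_fraction=0.0)],
                gen_params, seed=seed,
            )
            recs = [nm.SubjectRecord(s.id, s.age, s.sex, s.true_total_log10)
                    for s in subs]
            spec = nm.QuantileModelSpec(taus=(0.1, 0.5, 0.9), df=4)
            model = nm.fit_centile_model(recs, spec)["female"]
            ages = np.arange(40, 86)
            worst = 0.0
            for i, tau in enumerate(spec.taus):
                true = np.array(
                    [gen_params.quantile_log10(a, "female", tau) for a in ages]
                )
                worst = max(worst, np.abs(model.curves(ages)[i] - true).max())
            errs[n] = worst
        assert errs[5000] < errs[500]
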
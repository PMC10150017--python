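import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from pedqus.lms import (
    LMS,
    bccg_loglik,
    bccg_pdf,
    boxcox_z,
    centile,
    cross_validate_lms,
    df_grid_search,
    fit_lms,
    load_model,
)


def _simulate_bccg(rng, x, L, M, S):
    """Draw y from the BCCG distribution with pointwise parameters."""
    z = rng.standard_normal(np.shape(x))
    return centile(norm.cdf(z), L, M, S)


class TestBoxcoxZ:
    def test_median_maps_to_zero(self):
        for L in (-1.0, 0.0, 1.0, 2.3):
            assert boxcox_z(4.0, L, 4.0, 0.25) == pytest.approx(0.0, abs=1e-12)

    def test_closed_forms(self):
        assert boxcox_z(5.0, 1.0, 4.0, 0.25) == pytest.approx(1.0)
        assert boxcox_z(4.0 * np.e**0.5, 0.0, 4.0, 0.25) == pytest.approx(2.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="y"):
            boxcox_z(-1.0, 1.0, 4.0, 0.25)
        with pytest.raises(ValueError, match="M"):
            boxcox_z(1.0, 1.0, 0.0, 0.25)
        with pytest.raises(ValueError, match="S"):
            boxcox_z(1.0, 1.0, 4.0, -0.1)


class TestCentile:
    def test_median_level_returns_M(self):
        assert centile(0.5, 0.7, 4.0, 0.25) == pytest.approx(4.0)

    def test_hand_computed(self):
        assert centile(0.975, 1.0, 4.0, 0.25) == pytest.approx(5.95996, abs=1e-4)

    def test_roundtrip_inverse_to_1e10(self):
        alphas = np.linspace(0.005, 0.995, 67)
        for L, M, S in [(1.0, 4.0, 0.25), (0.0, 10.0, 0.1),
                        (-0.8, 2.0, 0.12), (2.5, 0.6, 0.08)]:
            y = centile(alphas, L, M, S)
            z = np.asarray(boxcox_z(y, L, M, S))
            assert np.max(np.abs(z - norm.ppf(alphas))) < 1e-10

    def test_invalid_alpha_and_strong_skew(self):
        with pytest.raises(ValueError):
            centile(0.0, 1.0, 4.0, 0.25)
        with pytest.raises(ValueError, match="alpha"):
            centile(1e-9, 3.0, 4.0, 1.5)


class TestBccgLoglik:
    def test_reduces_to_normal_when_L_is_one(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(5, 15, 200)
        M, S = 10.0, 0.2
        expected = float(np.sum(norm.logpdf(y, loc=M, scale=M * S)))
        assert bccg_loglik(y, np.ones_like(y), np.full_like(y, M),
                           np.full_like(y, S)) == pytest.approx(expected)

    @pytest.mark.parametrize("params", [(1.0, 10.0, 0.1), (0.5, 4.0, 0.15),
                                        (-0.5, 4.0, 0.1)])
    def test_density_integrates_to_one(self, params):
        L, M, S = params
        val, err = quad(lambda t: bccg_pdf(t, L, M, S), 1e-9, 12 * M, limit=300)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_error_names_offending_index(self):
        y = np.array([1.0, 2.0, -3.0])
        with pytest.raises(ValueError, match="index 2"):
            bccg_loglik(y, 1.0, 1.0, 0.1)


class TestFitLms:
    def test_constant_truth_recovery(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 1000)
        y = _simulate_bccg(rng, x, 1.0, 10.0, 0.1)
        res = fit_lms(x, y, (0, 0, 0))
        assert res.converged
        assert float(res.M(5.0)) == pytest.approx(10.0, rel=0.01)
        assert float(res.S(5.0)) == pytest.approx(0.1, rel=0.10)

    def test_linear_median_slope_recovery(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 1000)
        y = (10.0 + 2.0 * x) * (1.0 + 0.1 * rng.standard_normal(1000))
        res = fit_lms(x, y, (0, 1, 0))
        slope = (float(res.M(10.0)) - float(res.M(0.0))) / 10.0
        assert slope == pytest.approx(2.0, rel=0.05)

    def test_zero_dfs_give_constant_curves(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 200)
        y = (5 + x) * np.exp(0.2 * rng.standard_normal(200))
        res = fit_lms(x, y, (0, 0, 0))
        for name in ("L", "M", "S"):
            curve = res.curves[name]
            assert curve.kind == "constant"
            vals = curve.value(np.linspace(0, 5, 9))
            assert np.ptp(vals) == 0.0

    def test_input_validation(self):
        x = np.linspace(0, 1, 30)
        with pytest.raises(ValueError, match="positive"):
            fit_lms(x, np.linspace(-1, 1, 30), (0, 0, 0))
        with pytest.raises(ValueError, match="n >= 20"):
            fit_lms(x[:10], np.ones(10) + x[:10], (0, 0, 0))
        with pytest.raises(ValueError, match="dfs"):
            fit_lms(x, 1.0 + x, (0, 6, 0))

    def test_gaussian_limit_matches_quantile_fit(self):
        """With L=1 and small S the centiles equal mean + z*sd within 2%."""
        rng = np.random.default_rng(4)
        x = np.linspace(0, 1, 800)
        y = 20.0 + 0.6 * rng.standard_normal(800)  # CV = 3%
        res = fit_lms(x, y, (0, 0, 0))
        for alpha in (0.1, 0.5, 0.9):
            gauss = y.mean() + norm.ppf(alpha) * y.std()
            assert float(res.centile_at(0.5, alpha)) == pytest.approx(
                gauss, rel=0.02
            )

    def test_stratified_fits_have_no_leakage(self, retained_cohort):
        """Fitting one sex stratum equals fitting that stratum's data alone."""
        girls = retained_cohort[retained_cohort.sex == "female"]
        direct = LMS.from_dataframe(girls, "swe_ms", "wall_mm", (0, 1, 0)).fit()
        via_groupby = {
            level: LMS.from_dataframe(g, "swe_ms", "wall_mm", (0, 1, 0)).fit()
            for level, g in retained_cohort.groupby("sex")
        }["female"]
        for name in ("L", "M", "S"):
            assert np.array_equal(direct.curves[name].coef,
                                  via_groupby.curves[name].coef)

    def test_bic_prefers_true_linear_structure(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 800)
        y = (5.0 + 1.5 * x) * (1.0 + 0.08 * rng.standard_normal(800))
        flat = fit_lms(x, y, (0, 0, 0))
        lin = fit_lms(x, y, (0, 1, 0))
        assert lin.bic < flat.bic


class TestDfGridSearch:
    def test_single_cell_grid(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 1, 100)
        y = 5.0 * np.exp(0.1 * rng.standard_normal(100))
        best, table = df_grid_search(x, y, grid=[(0, 1, 0)])
        assert best.model.dfs == (0, 1, 0)
        assert len(table) == 1

    def test_table_has_one_row_per_cell(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 1, 150)
        y = 5.0 * np.exp(0.1 * rng.standard_normal(150))
        grid = [(0, 0, 0), (0, 1, 0), (1, 1, 1), (0, 2, 0)]
        best, table = df_grid_search(x, y, grid=grid)
        assert len(table) == len(grid)
        assert set(zip(table.df_L, table.df_M, table.df_S)) == set(grid)

    def test_constant_truth_selects_constant_model(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 10, 600)
        y = _simulate_bccg(rng, x, 1.0, 8.0, 0.12)
        grid = [(a, b, c) for a in (0, 1) for b in (0, 1, 2) for c in (0, 1)]
        best, _ = df_grid_search(x, y, grid=grid)
        assert best.model.dfs == (0, 0, 0)


class TestCrossValidate:
    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 5, 200)
        y = 5.0 * np.exp(0.15 * rng.standard_normal(200))
        a = cross_validate_lms(x, y, (0, 0, 0), k_folds=5, seed=11)
        b = cross_validate_lms(x, y, (0, 0, 0), k_folds=5, seed=11)
        assert a == b

    def test_overfit_scores_below_truth_matched(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 10, 400)
        y = _simulate_bccg(rng, x, 1.0, 8.0, 0.12)
        plain = cross_validate_lms(x, y, (0, 0, 0), k_folds=5, seed=0)
        overfit = cross_validate_lms(x, y, (5, 5, 5), k_folds=5, seed=0)
        assert plain > overfit

    def test_leave_one_out_accepted_for_small_samples(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0, 2, 60)
        y = 4.0 * np.exp(0.1 * rng.standard_normal(60))
        score = cross_validate_lms(x, y, (0, 0, 0), k_folds=60, seed=0)
        assert np.isfinite(score)

    def test_invalid_folds(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="k_folds"):
            cross_validate_lms(x, 1.0 + x, (0, 0, 0), k_folds=1)


class TestReferenceTableAndScoring:
    @pytest.fixture(scope="class")
    def ati_model(self, retained_cohort):
        return LMS.from_dataframe(retained_cohort, "ati", "age", (0, 2, 0)).fit()

    def test_median_column_equals_M(self, ati_model):
        table = ati_model.reference_table([0.5], num=20)
        expected = np.asarray(ati_model.M(table.grid))
        assert np.allclose(table.values["P50"].to_numpy(), expected)

    def test_columns_strictly_increasing(self, ati_model):
        table = ati_model.reference_table((0.03, 0.25, 0.5, 0.75, 0.97))
        arr = table.values.to_numpy()
        assert np.all(np.diff(arr, axis=1) > 0)

    def test_ati_median_declines_with_age(self, ati_model):
        table = ati_model.reference_table([0.5], num=30)
        med = table.values["P50"].to_numpy()
        assert med[-1] < med[0]

    def test_extrapolation_refused_by_default(self, ati_model):
        hi = ati_model.x_range[1]
        with pytest.raises(ValueError, match="outside fitted range"):
            ati_model.reference_table([0.5], grid=[hi + 1.0])
        assert np.isfinite(
            ati_model.centile_at(hi + 1.0, 0.5, allow_extrapolate=True)
        )

    def test_zscore_inverse_properties(self, ati_model):
        x0 = float(np.mean(ati_model.x_range))
        on_median = float(ati_model.M(x0))
        assert float(ati_model.zscore(x0, on_median)) == pytest.approx(0.0,
                                                                       abs=1e-9)
        y977 = float(ati_model.centile_at(x0, norm.cdf(2.0)))
        assert float(ati_model.zscore(x0, y977)) == pytest.approx(2.0, abs=1e-6)

    def test_zscore_calibration_on_simulated_cohort(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 10, 1000)
        y = _simulate_bccg(rng, x, 1.0, 10.0 - 0.3 * x, 0.1)
        res = fit_lms(x, y, (0, 1, 0))
        z = np.asarray(res.zscore(x, y))
        assert -0.1 < z.mean() < 0.1
        assert 0.9 < z.std() < 1.1

    def test_serialization_roundtrip(self, ati_model, tmp_path):
        path = tmp_path / "model.json"
        ati_model.to_json(path)
        frozen = load_model(path)
        x0 = float(np.mean(ati_model.x_range))
        assert float(frozen.M(x0)) == pytest.approx(float(ati_model.M(x0)))
        assert float(frozen.zscore(x0, 0.5)) == pytest.approx(
            float(ati_model.zscore(x0, 0.5))
        )

    def test_summary_mentions_key_facts(self, ati_model):
        text = ati_model.summary()
        assert "ati" in text and "age" in text and "BIC" in text
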
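import numpy as np
import pytest
from oracles import (
    kendall_tau_b_bruteforce,
    pearson_bruteforce,
    point_biserial_bruteforce,
)

from pedqus.association import (
    correlation_matrix,
    kendall_tau_b,
    min_detectable_r,
    pearson,
    point_biserial,
)
from pedqus.pipeline import CORRELATION_VARIABLES
from pedqus.qc import semi_winsorize


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_hand_computed(self):
        assert pearson([1, 2, 3], [6, 4, 5]).r == pytest.approx(-0.5)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal((2, 10_000))
        assert abs(pearson(x, y).r) < 0.05

    def test_pairwise_deletion_and_df(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 1.0, 9.0, 4.5, 5.5]
        res = pearson(x, y)
        assert res.n == 4
        assert res.df == 2

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 13)
            x, y = rng.standard_normal((2, n))
            assert pearson(x, y).r == pytest.approx(
                pearson_bruteforce(list(x), list(y)), abs=1e-12
            )


class TestPointBiserial:
    def test_hand_computed(self):
        res = point_biserial([0, 0, 1, 1], [1, 2, 3, 4])
        assert res.r == pytest.approx(0.8944271909999159)

    def test_equals_pearson_on_coded(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 30).astype(float)
        y = rng.standard_normal(30) + x
        assert point_biserial(x, y).r == pytest.approx(pearson(x, y).r)

    def test_recoding_flips_sign(self):
        x = np.array([0, 0, 1, 1, 0, 1], float)
        y = np.array([1.0, 2, 3, 4, 1.5, 3.5])
        assert point_biserial(1 - x, y).r == pytest.approx(
            -point_biserial(x, y).r
        )

    def test_identical_group_means_near_zero(self):
        x = [0, 0, 1, 1]
        y = [1.0, 3.0, 1.0, 3.0]
        assert point_biserial(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_single_level_raises(self):
        with pytest.raises(ValueError, match="both levels"):
            point_biserial([1, 1, 1], [1.0, 2.0, 3.0])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(5, 13))
            x = np.r_[0, 1, rng.integers(0, 2, n - 2)].astype(float)
            y = rng.standard_normal(n)
            assert point_biserial(x, y).r == pytest.approx(
                point_biserial_bruteforce(list(x), list(y)), abs=1e-12
            )


class TestKendallTauB:
    def test_monotone_sequences(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]).r == 1.0

    def test_hand_computed(self):
        # pairs: 5 concordant, 1 discordant -> (5-1)/6
        assert kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4]).r == pytest.approx(2 / 3)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        base = kendall_tau_b(x, y).r
        assert kendall_tau_b(np.exp(x), y).r == pytest.approx(base)
        assert kendall_tau_b(x, y**3).r == pytest.approx(base)

    def test_all_tied_raises(self):
        with pytest.raises(ValueError, match="all-tied"):
            kendall_tau_b([1, 1, 1], [1.0, 2.0, 3.0])

    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            assert kendall_tau_b(x, y).r == pytest.approx(
                kendall_tau_b_bruteforce(list(x), list(y)), abs=1e-12
            )


class TestMinDetectableR:
    def test_published_sensitivity_setting(self):
        # (1.95996 + 0.84162)/sqrt(82) = 0.3094 -> tanh -> 0.300
        assert min_detectable_r(85, 0.80, 0.05) == pytest.approx(0.300, abs=5e-4)

    def test_coin_flip_power_reduces_to_critical_r(self):
        # at power 0.5 the power term z_power vanishes and the formula
        # collapses to the critical correlation tanh(z_{a/2}/sqrt(n-3))
        n = 50
        limit = np.tanh(1.959964 / np.sqrt(n - 3))
        assert min_detectable_r(n, power=0.5, alpha=0.05) == pytest.approx(
            limit, abs=1e-6
        )

    def test_monotone_in_n(self):
        rs = [min_detectable_r(n) for n in (10, 30, 100, 500)]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_detectable_r(3)
        with pytest.raises(ValueError):
            min_detectable_r(50, power=1.0)


class TestCorrelationMatrix:
    def test_two_variable_matrix(self, synth2000):
        m = correlation_matrix(synth2000, ["ati", "age"])
        frame = m.r_frame()
        assert frame.shape == (2, 2)
        assert frame.iloc[0, 0] == frame.iloc[1, 1] == 1.0
        assert frame.equals(frame.T)

    def test_method_selection(self, synth2000):
        m = correlation_matrix(synth2000, ["ati", "wall_mm", "sex"])
        assert m.get("ati", "wall_mm").method == "kendall_tau_b"
        assert m.get("ati", "sex").method == "point_biserial"

    def test_unknown_field_raises(self, synth2000):
        with pytest.raises(ValueError, match="unknown field"):
            correlation_matrix(synth2000, ["ati", "nonexistent"])

    def test_sign_pattern_on_synthetic_cohort(self, synth2000):
        m = correlation_matrix(
            synth2000, ["ati", "swe_ms", "swd", "age", "bmi_sds", "sex"]
        )
        assert m.get("ati", "age").r < -0.4
        assert m.get("swd", "bmi_sds").r < 0
        assert m.get("swe_ms", "swd").r > 0
        assert m.get("swe_ms", "sex").r < 0  # girls lower, female coded 1
        for a, b in [("ati", "swe_ms"), ("ati", "swd")]:
            assert abs(m.get(a, b).r) < 0.15

    def test_pairwise_n_reflects_missingness(self, retained_cohort):
        m = correlation_matrix(retained_cohort, ["ati", "swd", "age"])
        assert m.get("ati", "age").n == len(retained_cohort)
        assert m.get("ati", "swd").n == int(retained_cohort.swd.notna().sum())

    def test_winsorization_leaves_significance_pattern(self, retained_cohort):
        """Winsorized and raw data flag the same pairs at p < .05."""
        wins = retained_cohort.copy()
        for outcome in ("ati", "swe_ms", "swe_kpa", "swd"):
            wins[outcome] = semi_winsorize(
                retained_cohort[outcome].to_numpy(float)
            ).values
        variables = [v for v in CORRELATION_VARIABLES
                     if v in retained_cohort.columns]
        sig_raw = {
            k for k, v in correlation_matrix(retained_cohort, variables)
            .results.items() if v.p < 0.05
        }
        sig_win = {
            k for k, v in correlation_matrix(wins, variables)
            .results.items() if v.p < 0.05
        }
        assert sig_raw == sig_win
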
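"""Force-deformation fits, ICC reliability, repeated-measures ANOVA."""

import numpy as np
import pytest
from scipy import stats as sps

from specklestrain import (
    MissingDataError,
    SpecError,
    fit_force_relationship,
    gg_epsilon,
    icc_category,
    icc_trials,
    mauchly_test,
    r2_category,
    rm_anova,
)

LEVELS = np.array([10, 20, 40, 60, 80, 100], dtype=float)


class TestForceRelationship:
    def test_exact_linear_data_is_very_strong_linear(self):
        fit = fit_force_relationship(LEVELS, 2.0 + 0.5 * LEVELS)
        assert fit.adj_r2_linear == pytest.approx(1.0, abs=1e-12)
        assert fit.selected == "linear"
        assert fit.category == "very strong"

    def test_exact_quadratic_data_selects_quadratic(self):
        fit = fit_force_relationship(LEVELS, 1.0 + 0.02 * LEVELS**2)
        assert fit.selected == "quadratic"
        assert fit.adj_r2_quadratic == pytest.approx(1.0, abs=1e-12)

    def test_tie_goes_to_linear(self):
        # exactly linear data: the quadratic fit also reaches adj R2 = 1
        fit = fit_force_relationship(LEVELS, 3.0 * LEVELS)
        assert fit.adj_r2_quadratic <= fit.adj_r2_linear + 1e-12
        assert fit.selected == "linear"

    def test_affine_rescaling_leaves_adjusted_r2_unchanged(self):
        rng = np.random.default_rng(0)
        y = 5 + 0.4 * LEVELS + rng.normal(0, 3, LEVELS.size)
        a = fit_force_relationship(LEVELS, y)
        b = fit_force_relationship(2.0 * LEVELS - 7.0, 0.1 * y + 11.0)
        assert a.adj_r2_linear == pytest.approx(b.adj_r2_linear, abs=1e-9)
        assert a.adj_r2_quadratic == pytest.approx(b.adj_r2_quadratic, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(SpecError):
            fit_force_relationship(LEVELS[:3], LEVELS[:3])


class TestCategories:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.96, "very strong"),  # printed subject with the strongest linear fit
            (0.46, "moderate"),  # printed subject 17
            (0.90, "strong"),
            (0.61, "strong"),
            (0.31, "moderate"),
            (0.10, "weak"),
            (0.05, "below-weak"),
            (-0.2, "below-weak"),
        ],
    )
    def test_r2_boundaries(self, value, expected):
        assert r2_category(value) == expected

    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.79, "strong"),  # five-muscle-sum reliability
            (0.75, "strong"),
            (0.74, "good"),
            (0.60, "good"),
            (0.43, "fair"),
            (0.39, "poor"),
            (-0.1, "poor"),
        ],
    )
    def test_icc_boundaries(self, value, expected):
        assert icc_category(value) == expected


class TestICC:
    def _matrix(self, seed=1, n=8, k=3, subject_sd=5.0, noise_sd=1.0):
        rng = np.random.default_rng(seed)
        subj = rng.normal(0, subject_sd, (n, 1))
        return 20 + subj + rng.normal(0, noise_sd, (n, k))

    def test_identical_trials_give_unit_icc(self):
        col = np.linspace(5, 40, 8)[:, None]
        data = np.tile(col, (1, 3))
        res = icc_trials(data)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.category == "strong"

    def test_matches_hand_sums_of_squares_on_6x3(self):
        data = np.array(
            [
                [9.0, 10.0, 11.0],
                [5.0, 6.0, 4.0],
                [12.0, 14.0, 13.0],
                [8.0, 8.0, 9.0],
                [3.0, 2.0, 4.0],
                [15.0, 16.0, 14.0],
            ]
        )
        n, k = data.shape
        grand = data.mean()
        msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
        mse = (
            np.sum((data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand) ** 2)
            / ((n - 1) * (k - 1))
        )
        expected_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        expected_c = (msr - mse) / (msr + (k - 1) * mse)
        res = icc_trials(data)
        assert res.icc == pytest.approx(expected_a, abs=1e-10)
        assert res.icc_consistency == pytest.approx(expected_c, abs=1e-10)

    def test_agreement_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        data = self._matrix(seed=2)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(data.shape[0]), data.shape[1]),
                "trial": np.tile(np.arange(data.shape[1]), data.shape[0]),
                "value": data.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="trial", ratings="value")
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        ref = table[table["Type"] == "ICC(A,1)"].iloc[0]
        res = icc_trials(data)
        assert res.icc == pytest.approx(ref["ICC"], abs=1e-8)
        # pingouin rounds its interval to two decimals
        assert res.ci95[0] == pytest.approx(ref[ci_col][0], abs=0.011)
        assert res.ci95[1] == pytest.approx(ref[ci_col][1], abs=0.011)
        ref_c = table[table["Type"] == "ICC(C,1)"].iloc[0]
        assert res.icc_consistency == pytest.approx(ref_c["ICC"], abs=1e-8)

    def test_more_subject_spread_raises_icc(self):
        base = icc_trials(self._matrix(seed=3, subject_sd=2.0)).icc
        wide = icc_trials(self._matrix(seed=3, subject_sd=8.0)).icc
        assert wide > base

    def test_zero_between_subject_variance_warns_and_returns_zero(self):
        data = np.tile(np.array([[4.0, 4.0, 4.0]]), (6, 1))
        with pytest.warns(UserWarning):
            res = icc_trials(data)
        assert res.icc == 0.0
        assert res.category == "poor"

    def test_missing_cells_rejected(self):
        data = self._matrix()
        data[2, 1] = np.nan
        with pytest.raises(MissingDataError):
            icc_trials(data)


class TestRMAnova:
    def _data(self, seed=4, n=10, k=4, effect=None):
        rng = np.random.default_rng(seed)
        subj = rng.normal(0, 2, (n, 1))
        data = 10 + subj + rng.normal(0, 1, (n, k))
        if effect is not None:
            data = data + np.asarray(effect)
        return data

    def test_identical_conditions_give_zero_f_unit_p(self):
        col = np.linspace(1, 10, 8)[:, None]
        res = rm_anova(np.tile(col, (1, 4)))
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_two_condition_f_equals_squared_paired_t(self):
        data = self._data(k=2, effect=[0.0, 1.5])
        res = rm_anova(data)
        t = sps.ttest_rel(data[:, 0], data[:, 1]).statistic
        assert res.f_stat == pytest.approx(t**2, abs=1e-10)

    def test_gg_epsilon_matches_covariance_formula(self):
        data = self._data(seed=5, n=10, k=4)
        k = 4
        s = np.cov(data, rowvar=False, ddof=1)
        p = np.eye(k) - np.ones((k, k)) / k
        ss = p @ s @ p
        expected = np.trace(ss) ** 2 / ((k - 1) * np.trace(ss @ ss))
        assert gg_epsilon(data) == pytest.approx(expected, abs=1e-10)
        assert 1 / (k - 1) < gg_epsilon(data) <= 1.0

    def test_epsilon_and_mauchly_match_pingouin(self):
        import pandas as pd
        import pingouin as pg

        data = self._data(seed=6, n=12, k=4)
        df = pd.DataFrame(data, columns=list("abcd"))
        assert gg_epsilon(data) == pytest.approx(pg.epsilon(df, correction="gg"), abs=1e-8)
        spher = pg.sphericity(df)
        w, p = mauchly_test(data)
        assert w == pytest.approx(spher.W, abs=1e-8)
        assert p == pytest.approx(spher.pval, abs=1e-8)

    def test_strong_effect_detected_with_bonferroni_pairs(self):
        res = rm_anova(self._data(seed=7, k=4, effect=[0.0, 2.0, 4.0, 6.0]))
        assert res.p_value < 0.001
        assert res.pairwise_p[(0, 3)] < 0.01
        assert all(0 <= p <= 1 for p in res.pairwise_p.values())

    def test_corrected_dfs_scale_by_epsilon_when_violated(self):
        rng = np.random.default_rng(8)
        # strongly non-spherical: one condition with much larger variance
        n, k = 12, 4
        data = 10 + rng.normal(0, 1, (n, k))
        data[:, 0] += rng.normal(0, 6, n)
        res = rm_anova(data)
        if res.sphericity_violated:
            assert res.df[0] == pytest.approx(res.gg_epsilon * (k - 1))
            assert res.df[1] == pytest.approx(res.gg_epsilon * (n - 1) * (k - 1))
        else:  # extremely unlikely; identity still holds trivially
            assert res.df == (k - 1, (n - 1) * (k - 1))

    def test_incomplete_data_rejected(self):
        data = self._data()
        data[0, 0] = np.nan
        with pytest.raises(MissingDataError):
            rm_anova(data)
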
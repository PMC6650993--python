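"""GLM, TFCE, permutation FWE, correlations and repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest

from alongtract.stats import (DesignMatrix, TractAssociationModel,
                              bayes_factor_pearson, glm_segment, pearson_report,
                              permutation_fwe, rm_anova_gg, tfce_1d, _run_lengths)
from alongtract.synthetic import CohortSpec, make_profile_cohort


def make_design(n=46, seed=0):
    rng = np.random.default_rng(seed)
    return DesignMatrix(rng.normal(250, 48, n), rng.uniform(19, 24, n)), rng


class TestGLM:
    def test_matches_normal_equations(self):
        design, rng = make_design()
        y = 0.5 * design.regressor + 0.2 * design.nuisance + rng.normal(0, 1, 46)
        beta_std, t = glm_segment(y, design)
        X = np.column_stack([np.ones(46), design.regressor, design.nuisance])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ coef
        sigma2 = resid @ resid / (46 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert t == pytest.approx(coef[1] / se, abs=1e-10)
        assert beta_std == pytest.approx(coef[1] * design.regressor.std(ddof=1)
                                         / y.std(ddof=1), abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        design, rng = make_design(seed=2)
        y = rng.normal(0, 1, 46)
        X = sm.add_constant(np.column_stack([design.regressor, design.nuisance]))
        fit = sm.OLS(y, X).fit()
        _, t = glm_segment(y, design)
        assert t == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_perfect_fit_capped(self):
        design, _ = make_design(seed=3)
        beta_std, t = glm_segment(design.regressor * 2.0, design)
        assert abs(t) >= 1e5
        assert beta_std == pytest.approx(1.0, abs=1e-6)

    def test_null_t_distribution(self):
        design, rng = make_design(seed=4)
        hits = 0
        crit = 2.0167  # t(43) two-sided 5%
        for _ in range(400):
            _, t = glm_segment(rng.normal(0, 1, 46), design)
            hits += abs(t) > crit
        assert 0.02 < hits / 400 < 0.09

    def test_affine_invariance_of_beta_std(self):
        design, rng = make_design(seed=5)
        y = rng.normal(0, 1, 46)
        b1, _ = glm_segment(y, design)
        b2, _ = glm_segment(3.5 * y + 10, design)
        d2 = DesignMatrix(0.2 * design.regressor - 7, design.nuisance)
        b3, _ = glm_segment(y, d2)
        assert b1 == pytest.approx(b2, abs=1e-10)
        assert b1 == pytest.approx(b3, abs=1e-10)


class TestTFCE:
    def test_zero_input_zero_output(self):
        assert np.allclose(tfce_1d(np.zeros(30)), 0.0)

    def test_isolated_peak_closed_form(self):
        stat = np.zeros(31)
        h0 = 3.0
        stat[15] = h0
        out = tfce_1d(stat, E=0.5, H=2.0, dh=h0 / 1000)
        # e=1 throughout: integral of h^2 dh = h0^3/3
        assert out[15] == pytest.approx(h0**3 / 3, rel=0.01)
        assert np.all(out[np.arange(31) != 15] == 0)

    def test_scaling_monotonicity(self):
        rng = np.random.default_rng(6)
        stat = np.abs(rng.normal(0, 1, 30))
        a = tfce_1d(stat, dh=0.01)
        b = tfce_1d(2.0 * stat, dh=0.01)
        assert np.all(b[stat > 0.02] > a[stat > 0.02])

    def test_single_threshold_recovers_cluster_extent(self):
        stat = np.array([0, 2, 2, 2, 0, 0, 2.9, 2.9, 0, 1])
        thr = 1.5  # single step: all suprathreshold values below 2*thr
        out = tfce_1d(stat, E=1.0, H=0.0, dh=thr)
        expected = np.array([0, 3, 3, 3, 0, 0, 2, 2, 0, 0]) * thr
        assert np.allclose(out, expected)

    def test_run_lengths_helper(self):
        mask = np.array([[1, 1, 0, 1, 1, 1, 0, 0, 1]], dtype=bool)
        assert _run_lengths(mask).tolist() == [[2, 2, 0, 3, 3, 3, 0, 0, 1]]


class TestPermutationFWE:
    def test_deterministic_given_seed(self):
        prof, behav = make_profile_cohort(CohortSpec(), seed=1)
        design = DesignMatrix(behav["t_er_ms"].to_numpy(), behav["age"].to_numpy())
        r1 = permutation_fwe(prof, design, n_perm=100, seed=9)
        r2 = permutation_fwe(prof, design, n_perm=100, seed=9)
        assert np.array_equal(r1.p_fwe, r2.p_fwe, equal_nan=True)
        assert np.nanmin(r1.p_fwe) >= 1 / 101

    def test_null_fwe_quick(self):
        # reduced version of the full calibration (acceptance suite runs 500)
        hits = 0
        for rep in range(60):
            prof, behav = make_profile_cohort(CohortSpec(), seed=3000 + rep,
                                              planted=False)
            design = DesignMatrix(behav["t_er_ms"].to_numpy(),
                                  behav["age"].to_numpy())
            res = permutation_fwe(prof, design, n_perm=500, seed=rep)
            hits += np.nanmin(res.p_fwe) <= 0.05
        assert hits / 60 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 60) + 1e-9

    def test_planted_effect_detected(self):
        prof, behav = make_profile_cohort(CohortSpec(), seed=2, planted=True)
        model = TractAssociationModel(prof, behav["t_er_ms"], behav["age"])
        fit = model.fit(n_perm=1000, seed=3)
        sig = set(fit.significant_segments("NDI"))
        assert len(sig & set(range(18, 31))) >= 10
        # specificity: planted effect lives in NDI only
        for metric in ("ODI", "FA", "MD"):
            assert len(fit.significant_segments(metric)) <= 1
        # direction: negative association
        assert np.nanmean(fit.beta_std[17:30, 0]) < -0.3

    def test_constant_cell_flagged(self):
        prof, behav = make_profile_cohort(CohortSpec(), seed=4)
        prof.values[:, 5, 1] = 0.3  # constant ODI in segment 6
        design = DesignMatrix(behav["t_er_ms"].to_numpy(), behav["age"].to_numpy())
        res = permutation_fwe(prof, design, n_perm=100, seed=5)
        assert np.isnan(res.p_fwe[5, 1])
        assert np.isfinite(res.p_fwe[5, 0])

    def test_missing_values_pairwise_deleted(self):
        prof, behav = make_profile_cohort(CohortSpec(), seed=6)
        prof.values[::5, 7, 0] = np.nan
        design = DesignMatrix(behav["t_er_ms"].to_numpy(), behav["age"].to_numpy())
        res = permutation_fwe(prof, design, n_perm=100, seed=7)
        assert np.isfinite(res.p_fwe[7, 0])


class TestPearson:
    def test_identical_vectors(self):
        x = np.random.default_rng(0).normal(0, 1, 30)
        rep = pearson_report(x, x)
        assert rep.r == pytest.approx(1.0)
        assert rep.p == 0.0

    def test_closed_form_grid(self):
        from scipy import stats as sps
        rng = np.random.default_rng(1)
        for n in (10, 46, 120):
            x = rng.normal(0, 1, n)
            y = 0.3 * x + rng.normal(0, 1, n)
            rep = pearson_report(x, y)
            r_ref, p_ref = sps.pearsonr(x, y)
            assert rep.r == pytest.approx(r_ref, abs=1e-12)
            assert rep.p == pytest.approx(p_ref, abs=1e-9)
            z = np.arctanh(rep.r)
            lo = np.tanh(z - 1.959964 / np.sqrt(n - 3))
            assert rep.ci95[0] == pytest.approx(lo, abs=1e-9)
            assert rep.ci95[0] < rep.r < rep.ci95[1]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_report(np.ones(10), np.arange(10))


class TestBayesFactor:
    def test_against_pingouin(self):
        import pingouin as pg
        for r, n in [(0.114, 46), (0.062, 46), (0.3, 20), (-0.5, 30), (0.05, 100)]:
            mine = bayes_factor_pearson(r, n)
            ref = float(pg.bayesfactor_pearson(r, n))
            assert mine == pytest.approx(ref, rel=1e-3)

    def test_larger_effect_larger_evidence(self):
        assert bayes_factor_pearson(0.6, 46) > bayes_factor_pearson(0.2, 46) > \
            bayes_factor_pearson(0.05, 46)


class TestRmAnova:
    def _data(self, n=12, a=2, b=5, seed=4):
        rng = np.random.default_rng(seed)
        return (rng.normal(0, 1, (n, 1, 1))
                + rng.normal(0, 1, (n, a, b))
                + np.linspace(0, 1, b)[None, None, :]
                + np.linspace(0, 0.5, a)[None, :, None])

    def test_two_level_factor_epsilon_is_one(self):
        res = rm_anova_gg(self._data())
        assert res.effects.loc["hemisphere", "eps_gg"] == 1.0

    def test_matches_pingouin(self):
        import pingouin as pg
        data = self._data()
        n, a, b = data.shape
        rows = [{"subj": i, "A": j, "B": k, "y": data[i, j, k]}
                for i in range(n) for j in range(a) for k in range(b)]
        aov = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within=["A", "B"],
                          subject="subj", detailed=True).set_index("Source")
        res = rm_anova_gg(data).effects
        assert res.loc["hemisphere", "F"] == pytest.approx(aov.loc["A", "F"], rel=1e-8)
        assert res.loc["segment", "F"] == pytest.approx(aov.loc["B", "F"], rel=1e-8)
        assert res.loc["hemispherexsegment", "F"] == pytest.approx(
            aov.loc["A * B", "F"], rel=1e-8)
        assert res.loc["segment", "eps_gg"] == pytest.approx(
            aov.loc["B", "eps"], rel=1e-6)
        assert res.loc["segment", "p_gg"] == pytest.approx(
            aov.loc["B", "p_GG_corr"], rel=1e-6)

    def test_degenerate_constant_data_flagged(self):
        res = rm_anova_gg(np.full((8, 2, 4), 3.0))
        assert np.isnan(res.effects.loc["segment", "F"])

    def test_missing_cells_rejected(self):
        data = self._data()
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_gg(data)


class TestResultsSurface:
    def test_dataframe_and_summary(self):
        prof, behav = make_profile_cohort(CohortSpec(), seed=8, planted=True)
        fit = TractAssociationModel(prof, behav["t_er_ms"], behav["age"]).fit(
            n_perm=200, seed=9)
        df = fit.to_dataframe()
        assert set(df.columns) == {"segment", "metric", "beta_std", "t", "tfce",
                                   "p_fwe", "significant"}
        assert len(df) == 30 * 4
        assert "NDI" in fit.summary()
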
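"""Group statistics: age regression, CCA, structure correlations,
permutation inference, moderation, FDR, and the shared EC/FC pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from specdcm.cohort import COGNITIVE_TESTS, CohortConfig, generate_cohort
from specdcm.groupstats import (
    age_regression,
    brain_behaviour_analysis,
    cca,
    cca_significance,
    fc_reanalysis,
    fdr_correct,
    moderation,
    structure_correlations,
)


class TestAgeRegression:
    def test_perfect_signal(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(80, 3))
        # infinitesimal noise keeps the standard errors well defined
        age = 2.0 * P[:, 1] + 1e-6 * rng.normal(size=80)
        res = age_regression(P, age)
        assert res.r == pytest.approx(1.0, abs=1e-8)
        tab = res.table.set_index("name")
        assert tab.loc["param_1", "significant"]
        assert not tab.loc["param_0", "significant"]
        assert not tab.loc["param_2", "significant"]

    def test_null_p_values_uniform_under_permutation(self):
        """Permuting age should give a null R distribution: empirical
        p-values of the observed model p-value are uniform."""
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(100):
            P = rng.normal(size=(100, 3))
            age = rng.normal(size=100)
            fit = age_regression(P, age)
            # model F-test p-value via statsmodels is inside the table; use
            # the max-|beta| coefficient p as a null draw
            pvals.append(float(fit.table["pvalue"].min()))
        # min of 3 uniform p-values ~ Beta(1,3)
        ks = stats.kstest(pvals, stats.beta(1, 3).cdf)
        assert ks.pvalue > 0.01

    def test_recovers_generator_slopes(self):
        cfg = CohortConfig(n_subjects=300, seed=21)
        cohort = generate_cohort(cfg)
        cols = [f"true_{n}" for n in ("self_0", "exp_0", "amp_1")]
        P = cohort.table[cols].to_numpy()
        res = age_regression(P, cohort.table["age"].to_numpy(),
                             param_names=cols)
        tab = res.table.set_index("name")
        # configured positive slope on self_0 and exp_0, negative on amp_1
        assert tab.loc["true_self_0", "beta"] > 0
        assert tab.loc["true_exp_0", "beta"] > 0
        assert tab.loc["true_amp_1", "beta"] < 0
        assert res.r > 0.5

    def test_too_small_design_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            age_regression(np.zeros((5, 4)), np.zeros(5))


class TestCCA:
    def test_identical_single_columns(self):
        x = np.random.default_rng(0).normal(size=(50, 1))
        res = cca(x, x.copy())
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        Y = rng.normal(size=(200, 3))
        base = cca(X, Y).correlations
        T = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        out = cca(X @ T + 7.0, Y).correlations
        np.testing.assert_allclose(base, out, atol=1e-10)

    def test_matches_sklearn_oracle(self):
        from sklearn.cross_decomposition import CCA as SkCCA

        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 4))
        Y = 0.3 * X[:, :3] + rng.normal(size=(300, 3))
        ours = cca(X, Y)
        sk = SkCCA(n_components=3).fit(X, Y)
        xs, ys = sk.transform(X, Y)
        sk_r = sorted((abs(np.corrcoef(xs[:, i], ys[:, i])[0, 1])
                       for i in range(3)), reverse=True)
        np.testing.assert_allclose(ours.correlations, sk_r, atol=1e-6)

    def test_correlations_bounded_and_sorted(self):
        rng = np.random.default_rng(3)
        res = cca(rng.normal(size=(100, 5)), rng.normal(size=(100, 4)))
        r = res.correlations
        assert np.all((0 <= r) & (r <= 1))
        assert np.all(np.diff(r) <= 1e-12)

    def test_first_correlation_dominates_pairwise(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 4))
        Y = 0.4 * X[:, [0, 2]] + rng.normal(size=(150, 2))
        r1 = cca(X, Y).correlations[0]
        pair = max(abs(np.corrcoef(X[:, i], Y[:, j])[0, 1])
                   for i in range(4) for j in range(2))
        assert r1 >= pair - 1e-12

    def test_sign_convention(self):
        rng = np.random.default_rng(5)
        res = cca(rng.normal(size=(80, 3)), rng.normal(size=(80, 3)))
        for W in (res.x_weights, res.y_weights):
            for j in range(W.shape[1]):
                assert W[np.argmax(np.abs(W[:, j])), j] > 0

    def test_rank_deficiency_ridge_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 3))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        with pytest.warns(UserWarning, match="ridge"):
            cca(X, rng.normal(size=(100, 2)))

    def test_null_permutation_p_rarely_significant(self):
        """Independent Gaussians: first-pair permutation p > 0.05 in at
        least 90% of seeded runs."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            X = rng.normal(size=(500, 5))
            Y = rng.normal(size=(500, 5))
            p = cca_significance(X, Y, n_perm=199, rng=rng)["p_perm"]
            hits += p > 0.05
        assert hits >= 18


class TestStructureCorrelations:
    def test_single_column_loading_is_unit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 1))
        Y = 0.5 * X + rng.normal(size=(60, 1))
        res = cca(X, Y)
        fx, _ = structure_correlations(res, X, Y)
        assert abs(fx["loading"].iloc[0]) == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_columns_equal_loadings(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(120, 2))
        X = np.hstack([base, base[:, :1]])
        Y = 0.4 * base[:, :1] + rng.normal(size=(120, 1))
        with pytest.warns(UserWarning, match="ridge"):
            res = cca(X, Y)
        fx, _ = structure_correlations(res, X, Y)
        assert fx["loading"].iloc[0] == pytest.approx(fx["loading"].iloc[2],
                                                      abs=1e-10)

    def test_signal_columns_identified(self):
        """Only 2 of 9 connectivity columns carry signal: those two have
        the largest |loading| in at least 18 of 20 seeded replicates."""
        rng = np.random.default_rng(2)
        good = 0
        for _ in range(20):
            X = rng.normal(size=(400, 9))
            latent = X[:, 3] - X[:, 7]
            Y = np.outer(latent, [0.5, 0.4, 0.3]) + rng.normal(size=(400, 3))
            res = cca(X, Y)
            fx, _ = structure_correlations(res, X, Y)
            top2 = set(np.argsort(-np.abs(fx["loading"].to_numpy()))[:2])
            good += top2 == {3, 7}
        assert good >= 18

    def test_low_contribution_flag(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        Y = 0.8 * X[:, :1] + 0.1 * rng.normal(size=(200, 1))
        res = cca(X, Y)
        fx, _ = structure_correlations(res, X, Y)
        assert not fx["low_contribution"].iloc[0]
        assert fx["low_contribution"].iloc[1] and fx["low_contribution"].iloc[2]


class TestCcaSignificance:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 1))
        out = cca_significance(X, X.copy(), n_perm=199, rng=1)
        assert out["p_perm"] == pytest.approx(1 / 200)

    def test_agrees_with_bartlett_on_strong_signal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 3))
        Y = 0.5 * X[:, :2] + rng.normal(size=(500, 2))
        out = cca_significance(X, Y, n_perm=199, rng=2)
        assert out["p_perm"] < 0.01 and out["p_bartlett"] < 0.001
        assert abs(out["p_perm"] - out["p_bartlett"]) < 0.05

    def test_null_calibration(self):
        """p approximately uniform under independence (KS p > 0.01
        over 100 seeded repeats at n_perm = 199)."""
        rng = np.random.default_rng(42)
        ps = [cca_significance(rng.normal(size=(120, 4)),
                               rng.normal(size=(120, 3)),
                               n_perm=199, rng=rng)["p_perm"]
              for _ in range(100)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_n_perm_guard(self):
        with pytest.raises(ValueError, match="n_perm"):
            cca_significance(np.zeros((30, 1)), np.zeros((30, 1)), n_perm=10)


class TestModeration:
    @staticmethod
    def cohort_profiles(lam, seed, n=400):
        cfg = CohortConfig(n_subjects=n, moderation_strength=lam,
                           age_effects={}, seed=seed)
        cohort = generate_cohort(cfg)
        cog = cohort.table[COGNITIVE_TESTS].to_numpy()
        prof = cohort.table["profile"].to_numpy()
        res = cca(prof[:, None], cog)
        return (res.y_scores[:, 0], res.x_scores[:, 0],
                cohort.table["age"].to_numpy())

    def test_null_interaction_within_3se(self):
        W1, V1, age = self.cohort_profiles(0.0, seed=5)
        res = moderation(W1, V1, age)
        row = res.table.set_index("name").loc["age_x_profile"]
        assert abs(row.beta) < 3 * row.se

    def test_positive_interaction_detected(self):
        """lambda = 0.3 cohorts of n = 400: positive significant
        interaction in at least 80% of 20 seeded replicates."""
        hits = 0
        for s in range(20):
            W1, V1, age = self.cohort_profiles(0.3, seed=100 + s)
            row = moderation(W1, V1, age).table.set_index("name").loc["age_x_profile"]
            hits += (row.beta > 0) and (row.pvalue < 0.05)
        assert hits >= 16

    def test_tertile_slopes_increase_with_age(self):
        cfg = CohortConfig(n_subjects=600, moderation_strength=0.4,
                           age_effects={}, cognition_noise_sd=(0.01,) * 6,
                           seed=9)
        cohort = generate_cohort(cfg)
        cog = cohort.table[COGNITIVE_TESTS].to_numpy()
        prof = cohort.table["profile"].to_numpy()
        res = cca(prof[:, None], cog)
        out = moderation(res.y_scores[:, 0], res.x_scores[:, 0],
                         cohort.table["age"].to_numpy())
        s = out.simple_slopes
        assert s[0] < s[1] < s[2]

    def test_rank_deficient_design_rejected(self):
        age = np.random.default_rng(0).normal(size=50)
        V1 = np.random.default_rng(1).normal(size=50)
        W1 = np.random.default_rng(2).normal(size=50)
        with pytest.raises(ValueError, match="rank"):
            moderation(W1, V1, age, covariates=np.column_stack([age, age]))

    def test_covariates_standardized_coefficients(self):
        W1, V1, age = self.cohort_profiles(0.3, seed=3)
        cov = np.random.default_rng(4).normal(size=(age.size, 2))
        res = moderation(W1, V1, age, covariates=cov,
                         covariate_names=["motion", "education"])
        assert list(res.table["name"]) == ["age", "profile", "age_x_profile",
                                           "motion", "education"]


class TestFdr:
    def test_hand_evaluated_bh_example(self):
        qvals, reject = fdr_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_no_rejections(self):
        _, reject = fdr_correct(np.ones(6))
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        _, reject = fdr_correct([0.04], q=0.05)
        assert reject[0]
        _, reject = fdr_correct([0.06], q=0.05)
        assert not reject[0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_q_values_monotone_and_dominate_p(self, pvals):
        p = np.asarray(pvals)
        q, _ = fdr_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


class TestSharedPipeline:
    def test_fc_reanalysis_is_same_code_path(self):
        """EC and FC labels aside, identical inputs give identical
        statistics through the shared implementation."""
        rng = np.random.default_rng(0)
        P = rng.normal(size=(200, 5))
        cog = 0.3 * P[:, :2].sum(axis=1, keepdims=True) \
            + rng.normal(size=(200, 6)) * 0.8
        age = rng.uniform(18, 88, 200)
        a = brain_behaviour_analysis(P, cog, age, n_perm=100, rng=1)
        b = fc_reanalysis(P, cog, age, n_perm=100, rng=1)
        assert a["label"] == "EC" and b["label"] == "FC"
        assert a["age_regression"].r == b["age_regression"].r
        np.testing.assert_array_equal(a["cca"].correlations,
                                      b["cca"].correlations)
        assert a["cca_significance"]["p_perm"] == b["cca_significance"]["p_perm"]

    def test_incomplete_rows_dropped(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(120, 3))
        cog = rng.normal(size=(120, 6))
        age = rng.uniform(18, 88, 120)
        P[3, 0] = np.nan
        cog[7, 2] = np.nan
        out = brain_behaviour_analysis(P, cog, age, n_perm=100, rng=2)
        assert out["n"] == 118 and out["dropped"] == 2
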
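import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from thetamark import synthetic
from thetamark.outcomes import (bh_adjust, improvement, improvement_table,
                                ridge_permutation_importance, spearman_matrix,
                                stepwise_select, univariate_r2,
                                wilcoxon_paired)
from thetamark.spectral import build_feature_table


class TestImprovement:
    @pytest.mark.parametrize("pre,post,expected", [
        (20, 10, 0.5), (20, 20, 0.0), (20, 7, 0.65),
    ])
    def test_fraction(self, pre, post, expected):
        assert improvement(pre, post) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            improvement(0, 5)

    def test_responder_and_remission_labels(self):
        cohort = pd.DataFrame({
            "patient_id": ["A", "B", "C"],
            "hamd_baseline": [20.0, 20.0, 20.0],
            "hamd_3m": [10.0, 7.0, 15.0],
            "madrs_baseline": [30.0] * 3, "madrs_3m": [15.0] * 3,
            "hama_baseline": [20.0] * 3, "hama_3m": [10.0] * 3,
            "dars_baseline": [40.0] * 3, "dars_3m": [50.0] * 3,
        })
        tbl = improvement_table(cohort, horizons=("3m",))
        assert tbl["responder_3m"].tolist() == [True, True, False]
        assert tbl["remission_3m"].tolist() == [False, True, False]
        # DARS rises with improvement -> negative (pre-post)/pre
        assert (tbl["dars_improvement_3m"] < 0).all()

    def test_missing_visit_carried_forward(self):
        cohort = pd.DataFrame({
            "patient_id": ["A"],
            "hamd_baseline": [20.0], "hamd_3m": [10.0],
            "hamd_6m": [np.nan],
        })
        tbl = improvement_table(cohort, scales=("hamd",),
                               horizons=("3m", "6m"))
        assert tbl["hamd_improvement_6m"].iloc[0] == pytest.approx(0.5)


class TestSpearmanMatrix:
    def test_monotone_transform_gives_r1(self):
        idx = [f"P{i}" for i in range(10)]
        y = pd.DataFrame({"imp": np.arange(10.0)}, index=idx)
        x = pd.DataFrame({"f": np.exp(np.arange(10.0))}, index=idx)
        r, p, flags = spearman_matrix(x, y)
        assert r.loc["f", "imp"] == pytest.approx(1.0)
        assert flags.loc["f", "imp"]

    def test_agrees_with_rank_by_hand(self):
        rng = np.random.default_rng(0)
        idx = [f"P{i}" for i in range(20)]
        x = pd.DataFrame({"f": rng.standard_normal(20)}, index=idx)
        y = pd.DataFrame({"o": rng.standard_normal(20)}, index=idx)
        r, _, _ = spearman_matrix(x, y)
        rx = sstats.rankdata(x["f"])
        ry = sstats.rankdata(y["o"])
        manual = np.corrcoef(rx, ry)[0, 1]
        assert r.loc["f", "o"] == pytest.approx(manual, abs=1e-10)

    def test_constant_column_undefined(self):
        idx = [f"P{i}" for i in range(8)]
        x = pd.DataFrame({"f": np.ones(8)}, index=idx)
        y = pd.DataFrame({"o": np.arange(8.0)}, index=idx)
        r, p, flags = spearman_matrix(x, y)
        assert np.isnan(r.loc["f", "o"])
        assert not flags.loc["f", "o"]


def test_bh_stepup_hand_example():
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04)


class TestRidgeImportance:
    def test_planted_feature_ranks_first(self):
        # strong planted slope (population R² = 0.75)
        cohort, _ = synthetic.gen_cohort(
            synthetic.SimConfig(seed=11, effect_noise_sd=0.0866))
        feats = build_feature_table(cohort)
        imp = improvement_table(cohort)
        res = ridge_permutation_importance(feats, imp["hamd_improvement_3m"],
                                           n_iter=1000, seed=0)
        assert res.importances_mean.idxmax() == "pow_bnst_theta"
        assert res.n_iter == 1000

    def test_pure_noise_importances_null_in_expectation(self):
        # expectation over null datasets: any single dataset carries its own
        # spurious correlations, so the null property holds across datasets
        means = []
        for s in range(30):
            rng = np.random.default_rng(s)
            feats = pd.DataFrame(rng.standard_normal((17, 15)),
                                 columns=[f"f{i}" for i in range(15)])
            res = ridge_permutation_importance(feats, rng.standard_normal(17),
                                               n_iter=100, seed=s)
            means.append(res.importances_mean.to_numpy())
        means = np.array(means)
        grand = means.mean(axis=0)
        sem = means.std(axis=0, ddof=1) / np.sqrt(len(means))
        assert np.all(np.abs(grand) <= np.maximum(3 * sem, 0.04))

    def test_duplicated_feature_splits_importance(self, default_cohort):
        # at a fixed penalty the coefficient mass splits across duplicates,
        # so each copy's importance drops below the unique feature's
        cohort, _ = default_cohort
        feats = build_feature_table(cohort)
        imp = improvement_table(cohort)["hamd_improvement_3m"]
        res1 = ridge_permutation_importance(feats, imp, n_iter=500, seed=0,
                                            alphas=[10.0])
        dup = feats.copy()
        dup["pow_bnst_theta_copy"] = dup["pow_bnst_theta"]
        res2 = ridge_permutation_importance(dup, imp, n_iter=500, seed=0,
                                            alphas=[10.0])
        solo = res1.importances_mean["pow_bnst_theta"]
        assert res2.importances_mean["pow_bnst_theta"] < solo
        assert res2.importances_mean["pow_bnst_theta_copy"] < solo

    def test_matches_sklearn_ridge_solution(self):
        # the SVD shortcut must reproduce sklearn's ridge coefficients
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(2)
        X = rng.standard_normal((17, 15))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.standard_normal(17)
        yc = y - y.mean()
        alpha = 3.7
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        beta = Vt.T @ ((s / (s**2 + alpha)) * (U.T @ yc))
        sk = Ridge(alpha=alpha, fit_intercept=False).fit(X, yc)
        assert np.allclose(beta, sk.coef_, atol=1e-10)

    def test_constant_outcome_rejected(self, default_cohort):
        cohort, _ = default_cohort
        feats = build_feature_table(cohort)
        with pytest.raises(ValueError, match="constant"):
            ridge_permutation_importance(feats, np.ones(17), n_iter=10)


class TestUnivariate:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        r2, p, sgn = univariate_r2(x, 2 * x)
        assert r2 == pytest.approx(1.0)
        assert sgn == 1

    def test_null_expectation_of_r2(self):
        rng = np.random.default_rng(3)
        r2s = [univariate_r2(rng.standard_normal(17),
                             rng.standard_normal(17))[0]
               for _ in range(800)]
        assert np.mean(r2s) == pytest.approx(1 / 16, abs=0.015)

    def test_population_r2_calibration_recovered(self):
        # generator defaults place the theta->improvement population R² at 0.55
        r2s = []
        for s in range(60):
            cohort, _ = synthetic.gen_cohort(synthetic.SimConfig(seed=s))
            imp = improvement_table(cohort)
            r2s.append(univariate_r2(cohort["pow_bnst_theta"],
                                     imp["hamd_improvement_3m"])[0])
        assert np.median(r2s) == pytest.approx(0.55, abs=0.12)
        signs = [univariate_r2(synthetic.gen_cohort(
            synthetic.SimConfig(seed=s))[0]["pow_bnst_theta"],
            improvement_table(synthetic.gen_cohort(
                synthetic.SimConfig(seed=s))[0])["hamd_improvement_3m"])[2]
            for s in range(20)]
        assert np.mean(np.array(signs) == -1) >= 0.95


class TestStepwise:
    def test_single_perfect_candidate(self):
        x = pd.DataFrame({"a": np.arange(10.0)})
        res = stepwise_select(x, 3 * np.arange(10.0))
        assert res["selected"] == ["a"]
        assert res["r2"] == pytest.approx(1.0)

    def test_predictive_candidate_found_among_noise(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 17
            sig = rng.standard_normal(n)
            X = pd.DataFrame({
                "signal": sig,
                "n1": rng.standard_normal(n),
                "n2": rng.standard_normal(n),
            })
            y = 2.0 * sig + rng.normal(0, 0.5, n)
            res = stepwise_select(X, y)
            hits += res["selected"] == ["signal"]
        assert hits >= 17

    def test_all_noise_rarely_selects(self):
        nonempty = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            X = pd.DataFrame(rng.standard_normal((17, 3)),
                             columns=list("abc"))
            res = stepwise_select(X, rng.standard_normal(17))
            nonempty += bool(res["selected"])
        assert nonempty <= 20      # stepwise inflation, but bounded


class TestWilcoxon:
    def test_identical_pairs(self):
        a = np.arange(9.0)
        z, p = wilcoxon_paired(a, a)
        assert (z, p) == (0.0, 1.0)

    def test_constant_shift_minimal_exact_p(self):
        a = np.arange(9.0)
        z, p = wilcoxon_paired(a, a - 1.0)
        assert p == pytest.approx(2 / 512)
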
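import numpy as np
import pandas as pd
import pytest
from oracles import (
    dependent_corr_diff_bootstrap,
    exact_corr_pair,
    ols_normal_equations,
    vif_brute,
)

from gpadelta import models
from gpadelta.errors import (
    CollinearityError,
    InsufficientDataError,
    ValidationError,
)


class TestPearsonCi:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(50)
        res = models.pearson_ci(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.ci_upper == pytest.approx(1.0)

    def test_fisher_ci_at_half(self, rng):
        x, y = exact_corr_pair(100, 0.5, rng)
        res = models.pearson_ci(x, y)
        assert res.r == pytest.approx(0.5, abs=1e-10)
        # atanh(0.5) +/- 1.96/sqrt(97), back-transformed
        assert res.ci_lower == pytest.approx(0.337, abs=0.001)
        assert res.ci_upper == pytest.approx(0.634, abs=0.001)

    def test_null_covers_zero(self, rng):
        x = rng.standard_normal(5000)
        y = rng.permutation(x)
        res = models.pearson_ci(x, y)
        assert res.ci_lower < 0 < res.ci_upper

    def test_missing_dropped_pairwise(self, rng):
        x = np.append(rng.standard_normal(50), np.nan)
        y = np.append(rng.standard_normal(50), 1.0)
        assert models.pearson_ci(x, y).n == 50

    def test_too_few(self):
        with pytest.raises(InsufficientDataError):
            models.pearson_ci([1, 2, 3], [3, 2, 1])


class TestHierarchicalRegression:
    @staticmethod
    def _orthogonal_design(rng, n=200, p=3):
        M = rng.standard_normal((n, p))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        return Q * np.sqrt(n - 1)  # orthonormal columns scaled to unit variance

    def test_orthogonal_covariates_leave_sr2_unchanged(self, rng):
        Q = self._orthogonal_design(rng, 400, 3)
        focal, c1, c2 = Q.T
        y = 0.5 * focal + rng.standard_normal(400)
        data = pd.DataFrame({"y": y, "focal": focal, "c1": c1, "c2": c2})
        reps = models.hierarchical_regression(data, "y", "focal", [["c1"], ["c2"]])
        sr2 = [r.semipartial_r2_focal for r in reps]
        assert sr2[1] == pytest.approx(sr2[0], abs=5e-3)
        assert sr2[2] == pytest.approx(sr2[0], abs=5e-3)

    def test_outcome_equals_focal(self, rng):
        focal = rng.standard_normal(150)
        data = pd.DataFrame(
            {
                "y": focal,
                "focal": focal,
                "c1": rng.standard_normal(150),
            }
        )
        reps = models.hierarchical_regression(data, "y", "focal", [["c1"]])
        assert reps[0].r_squared == pytest.approx(1.0)
        assert reps[1].r_squared == pytest.approx(1.0)

    def test_correlated_covariate_cannot_increase_sr2(self, rng):
        focal = rng.standard_normal(500)
        cov = 0.8 * focal + 0.6 * rng.standard_normal(500)
        y = 0.5 * focal + 0.3 * cov + rng.standard_normal(500)
        data = pd.DataFrame({"y": y, "focal": focal, "cov": cov})
        reps = models.hierarchical_regression(data, "y", "focal", [["cov"]])
        assert reps[1].semipartial_r2_focal <= reps[0].semipartial_r2_focal + 1e-12

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 60))
            X = rng.standard_normal((n, 3))
            y = X @ rng.standard_normal(3) + rng.standard_normal(n)
            data = pd.DataFrame(
                {"y": y, "focal": X[:, 0], "c1": X[:, 1], "c2": X[:, 2]}
            )
            reps = models.hierarchical_regression(data, "y", "focal", [["c1", "c2"]])
            full = ols_normal_equations(X, y)
            reduced = ols_normal_equations(X[:, 1:], y)
            m1 = ols_normal_equations(X[:, :1], y)
            assert reps[1].r_squared == pytest.approx(full["r2"], abs=1e-10)
            assert reps[1].semipartial_r2_focal == pytest.approx(
                full["r2"] - reduced["r2"], abs=1e-10
            )
            got = reps[1].coef["estimate"].to_numpy()
            assert np.allclose(got, full["beta"], atol=1e-10)
            # nested F from residual sums of squares
            f_oracle = ((m1["rss"] - full["rss"]) / 2) / (full["rss"] / (n - 4))
            assert reps[1].nested_f == pytest.approx(f_oracle, abs=1e-8)

    def test_rank_deficient_raises(self, rng):
        x = rng.standard_normal(50)
        data = pd.DataFrame({"y": rng.standard_normal(50), "focal": x, "dup": x})
        with pytest.raises(CollinearityError):
            models.hierarchical_regression(data, "y", "focal", [["dup"]])


class TestModeration:
    def test_null_interaction_coverage(self, rng):
        # outcome built with zero interaction: CI should cover 0 most of the time
        cover = 0
        n_rep = 60
        for _ in range(n_rep):
            n = 2000
            f = rng.standard_normal(n)
            m = rng.standard_normal(n)
            y = 0.4 * f + 0.2 * m + rng.standard_normal(n)
            res = models.moderation_test(
                pd.DataFrame({"y": y, "f": f, "m": m}), "y", "f", "m"
            )
            cover += res.ci_lower <= 0 <= res.ci_upper
        assert cover / n_rep >= 0.90

    def test_pure_interaction_detected(self, rng):
        n = 500
        f = rng.standard_normal(n)
        m = rng.standard_normal(n)
        y = f * m
        res = models.moderation_test(
            pd.DataFrame({"y": y, "f": f, "m": m}), "y", "f", "m"
        )
        assert res.p_value < 1e-10
        assert abs(res.interaction_beta) > 0.5

    def test_constant_moderator_rejected(self, rng):
        n = 100
        data = pd.DataFrame(
            {"y": rng.standard_normal(n), "f": rng.standard_normal(n), "m": np.ones(n)}
        )
        with pytest.raises(ValidationError):
            models.moderation_test(data, "y", "f", "m")


class TestVif:
    def test_orthogonal_is_one(self, rng):
        M = rng.standard_normal((100, 4))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))  # centered + orthogonal columns
        out = models.vif(Q)
        assert np.allclose(out, 1.0, atol=1e-8)

    def test_pairwise_point_eight(self, rng):
        x, y = exact_corr_pair(300, 0.8, rng)
        out = models.vif(np.column_stack([x, y]))
        assert np.allclose(out, 1 / (1 - 0.64), atol=1e-6)

    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            X = rng.standard_normal((80, 4))
            X[:, 3] += 0.5 * X[:, 0]
            assert np.allclose(models.vif(X), vif_brute(X), atol=1e-8)

    def test_perfect_collinearity_inf(self, rng):
        x = rng.standard_normal(50)
        with pytest.warns(UserWarning):
            out = models.vif(np.column_stack([x, 2 * x, rng.standard_normal(50)]))
        assert np.isinf(out[0]) and np.isinf(out[1])

    def test_simulator_scores_finite(self, cohort):
        X = cohort[["gps", "gps2", "gps3", "gps4", "gps5"]].to_numpy()
        out = models.vif(X)
        assert np.all(np.isfinite(out)) and np.all(out > 1.0)


class TestMultiGpsWeights:
    def test_single_informative_score(self, rng):
        n = 2000
        X = rng.standard_normal((n, 5))
        y = 0.6 * X[:, 2] + 0.8 * rng.standard_normal(n)
        cv = models.multi_gps_weights(X, y, seed=3)
        assert np.argmax(np.abs(cv.weights)) == 2
        assert cv.cv_r2_mean == pytest.approx(0.36, abs=0.06)

    def test_exact_linear_combination(self, rng):
        n = 1000
        X = rng.standard_normal((n, 3))
        w = np.array([0.5, -0.25, 1.0])
        y = X @ w
        cv = models.multi_gps_weights(X, y, seed=1)
        assert cv.cv_r2_mean == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(cv.weights, w, atol=1e-9)

    def test_cv_r2_not_above_full_r2_on_average(self, rng):
        diffs = []
        for rep in range(50):
            n = 300
            X = rng.standard_normal((n, 3))
            y = 0.3 * X[:, 0] + rng.standard_normal(n)
            cv = models.multi_gps_weights(X, y, k=5, repeats=1, seed=rep)
            diffs.append(cv.full_r2 - cv.cv_r2_mean)
        assert np.mean(diffs) > 0

    def test_too_small_sample(self, rng):
        with pytest.raises(InsufficientDataError):
            models.multi_gps_weights(rng.standard_normal((50, 2)),
                                     rng.standard_normal(50), k=10)

    def test_composite_no_better_than_single_when_one_score_carries_signal(
        self, rng
    ):
        # target driven by score 1 only; noise scores should not beat it
        n = 4000
        X = rng.standard_normal((n, 5))
        y = 0.3 * X[:, 0] + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        cv = models.multi_gps_weights(X, y, seed=5)
        composite = X @ cv.weights
        r_single = models.pearson_ci(X[:, 0], y)
        r_multi = models.pearson_ci(composite, y)
        # overlapping confidence intervals
        assert r_multi.ci_lower <= r_single.ci_upper
        assert r_single.ci_lower <= r_multi.ci_upper


class TestJointDeltaRegression:
    def test_collinear_predictors_fall_back(self, rng):
        d = rng.standard_normal(200)
        y = 0.5 * d + rng.standard_normal(200)
        data = pd.DataFrame({"slope_z": y, "gpa_delta": d, "cog_delta": d})
        with pytest.warns(UserWarning):
            rep = models.joint_delta_regression(data)
        single = ols_normal_equations(d, y)
        assert rep.r_squared == pytest.approx(single["r2"], abs=1e-10)

    def test_orthogonal_known_correlations(self, rng):
        M = rng.standard_normal((500, 2))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))  # centered orthogonal columns
        x1 = Q[:, 0] / Q[:, 0].std(ddof=1)
        x2 = Q[:, 1] / Q[:, 1].std(ddof=1)
        e = rng.standard_normal(500)
        e -= e.mean()
        for v in (x1, x2):
            e -= (e @ v) / (v @ v) * v
        y = 0.4 * x1 - 0.3 * x2 + e
        data = pd.DataFrame({"slope_z": y, "gpa_delta": x1, "cog_delta": x2})
        rep = models.joint_delta_regression(data)
        r1 = np.corrcoef(x1, y)[0, 1]
        r2 = np.corrcoef(x2, y)[0, 1]
        assert rep.r_squared == pytest.approx(r1**2 + r2**2, abs=1e-10)

    def test_betas_match_oracle(self, rng):
        for _ in range(20):
            X = rng.standard_normal((80, 2))
            y = X @ [0.4, -0.2] + rng.standard_normal(80)
            data = pd.DataFrame(
                {"slope_z": y, "gpa_delta": X[:, 0], "cog_delta": X[:, 1]}
            )
            rep = models.joint_delta_regression(data)
            oracle = ols_normal_equations(X, y)
            got = rep.coef["estimate"].to_numpy()
            assert np.allclose(got, oracle["beta"], atol=1e-10)
            betas = rep.coef["beta"].drop("const").to_numpy()
            sd = np.std(X, axis=0, ddof=1) / np.std(y, ddof=1)
            assert np.allclose(betas, oracle["beta"][1:] * sd, atol=1e-10)


class TestCompareCorrelations:
    def test_equal_correlations_centered_at_zero(self):
        res = models.compare_correlations(0.4, 0.4, 500, overlap=0.3)
        assert res.difference == 0.0
        assert res.ci_lower < 0 < res.ci_upper
        assert not res.significant

    def test_extreme_difference_significant(self):
        res = models.compare_correlations(0.9, 0.1, 1000, overlap=0.05)
        assert res.significant
        assert res.ci_lower > 0

    def test_invalid_r(self):
        with pytest.raises(ValidationError):
            models.compare_correlations(1.0, 0.5, 100, overlap=0.2)

    def test_bootstrap_oracle_agreement(self, rng):
        # seeded trivariate normal sample; bootstrap CI within 0.01
        n = 2000
        cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        sample = rng.multivariate_normal(np.zeros(3), cov, size=n)
        x, y1, y2 = sample.T
        r1 = np.corrcoef(x, y1)[0, 1]
        r2 = np.corrcoef(x, y2)[0, 1]
        r12 = np.corrcoef(y1, y2)[0, 1]
        res = models.compare_correlations(r1, r2, n, overlap=r12)
        blo, bhi = dependent_corr_diff_bootstrap(x, y1, y2, n_boot=2000, seed=4)
        assert res.ci_lower == pytest.approx(blo, abs=0.01)
        assert res.ci_upper == pytest.approx(bhi, abs=0.01)
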
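"""Normalization, factor-model and outlier-detection behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lrnkit.preprocess import (
    beta_to_m,
    composite_covariate,
    detect_outliers,
    estimate_hidden_factors,
    m_to_beta,
    quantile_normalize,
    residualize,
)


class TestBetaM:
    @pytest.mark.parametrize(
        "beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)]
    )
    def test_fixed_points(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            beta_to_m(1.2)
        with pytest.raises(ValueError):
            beta_to_m(-0.1)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    def test_roundtrip_identity(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)

    def test_antisymmetry_and_monotonicity(self):
        b = np.linspace(0.01, 0.99, 99)
        m = beta_to_m(b)
        assert np.allclose(m, -beta_to_m(1 - b), atol=1e-12)
        assert np.all(np.diff(m) > 0)

    def test_bounds_clipped_not_rejected(self):
        assert np.isfinite(beta_to_m(0.0))
        assert np.isfinite(beta_to_m(1.0))


class TestQuantileNormalize:
    def test_three_point_closed_form(self):
        out = quantile_normalize(np.array([[1.0, 2.0, 3.0]]))[0]
        expect = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        assert np.allclose(out, expect, atol=1e-12)
        assert np.allclose(out, [-0.9674, 0.0, 0.9674], atol=1e-4)

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.standard_normal((3, 50))
        assert np.allclose(
            quantile_normalize(x), quantile_normalize(np.exp(x)), atol=1e-12
        )

    def test_rows_with_same_rank_order_match(self, rng):
        x = rng.standard_normal(40)
        both = np.vstack([x, 5 * x + 2])
        out = quantile_normalize(both)
        assert np.allclose(out[0], out[1], atol=1e-12)

    def test_constant_row_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = quantile_normalize(np.ones((1, 10)))
        assert np.all(out == 0)

    def test_output_approximately_gaussian(self, rng):
        x = rng.exponential(size=(5, 200))
        out = quantile_normalize(x)
        for row in out:
            ks = stats.kstest(row, "norm")
            assert ks.statistic < 0.05

    def test_dataframe_round_trips_labels(self, rng):
        df = pd.DataFrame(rng.standard_normal((2, 8)),
                          index=["a", "b"], columns=list("abcdefgh"))
        out = quantile_normalize(df)
        assert list(out.index) == ["a", "b"]
        assert list(out.columns) == list("abcdefgh")


class TestResidualize:
    def test_orthogonal_to_covariates(self, rng):
        cov = rng.standard_normal((2, 100))
        y = 2.0 * cov[0] - cov[1] + 0.1 * rng.standard_normal(100)
        res = residualize(y[None, :], cov)[0]
        assert abs(np.corrcoef(res, cov[0])[0, 1]) < 1e-10
        assert abs(np.corrcoef(res, cov[1])[0, 1]) < 1e-10

    def test_intercept_only_mean_centers(self, rng):
        y = rng.standard_normal((3, 30)) + 5
        res = residualize(y, None)
        assert np.allclose(res, y - y.mean(axis=1, keepdims=True), atol=1e-10)

    def test_idempotent(self, rng):
        cov = rng.standard_normal((3, 80))
        y = rng.standard_normal((4, 80))
        once = residualize(y, cov)
        twice = residualize(once, cov)
        assert np.allclose(once, twice, atol=1e-10)

    def test_never_increases_variance(self, rng):
        cov = rng.standard_normal((3, 60))
        y = rng.standard_normal((10, 60))
        res = residualize(y, cov)
        assert np.all(res.var(axis=1) <= y.var(axis=1) + 1e-12)

    def test_collinear_covariates_named(self, rng):
        c = rng.standard_normal(50)
        cov = pd.DataFrame([c, 2 * c], index=["batch", "batch_dup"])
        with pytest.raises(ValueError, match="batch_dup"):
            residualize(rng.standard_normal((2, 50)), cov)


class TestHiddenFactors:
    def test_rank_one_recovery(self, rng):
        f = rng.standard_normal(120)
        w = rng.standard_normal(30)
        X = np.outer(w, f)
        model = estimate_hidden_factors(X, 1)
        r = np.corrcoef(model.factors[0], f)[0, 1]
        assert abs(r) > 0.99

    def test_simulated_confounder_recovery(self, rng):
        f = rng.standard_normal(200)
        X = np.outer(rng.standard_normal(40) * 2.0, f) + rng.standard_normal((40, 200))
        model = estimate_hidden_factors(X, 1)
        assert abs(np.corrcoef(model.factors[0], f)[0, 1]) > 0.9

    def test_k_zero_gives_empty_model_and_zero_composites(self, rng):
        X = rng.standard_normal((5, 20))
        model = estimate_hidden_factors(pd.DataFrame(X, index=list("abcde")), 0)
        assert model.n_factors == 0
        assert np.all(composite_covariate(model, "a") == 0)

    def test_composite_is_weighted_factor_sum(self):
        from lrnkit.preprocess import HiddenFactorModel

        F = np.array([[1.0, 2.0, 3.0], [0.0, 1.0, -1.0]])
        W = np.array([[2.0, 3.0]])
        model = HiddenFactorModel(factors=F, weights=W, feature_ids=["x"])
        assert np.allclose(composite_covariate(model, "x"),
                           2 * F[0] + 3 * F[1], atol=1e-12)

    def test_unknown_feature_raises_key_error(self, rng):
        model = estimate_hidden_factors(rng.standard_normal((5, 30)), 2)
        with pytest.raises(KeyError):
            composite_covariate(model, "nope")


class TestOutliers:
    def test_identical_samples_no_flags(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 8))
        report = detect_outliers(X)
        assert report.flagged_samples == []

    def test_corrupted_sample_flagged(self, rng):
        X = np.tile(rng.standard_normal(50)[:, None], (1, 20))
        X += 0.05 * rng.standard_normal(X.shape)
        X[:, 7] = rng.standard_normal(50) * 10
        report = detect_outliers(pd.DataFrame(X, columns=[f"s{i}" for i in range(20)]))
        assert "s7" in report.flagged_samples

    def test_threshold_consistent_with_d_vector(self, rng):
        X = rng.standard_normal((30, 15))
        report = detect_outliers(X)
        q1, q3 = np.percentile(report.d, [25, 75])
        iqr = q3 - q1
        assert report.lower == pytest.approx(q1 - 1.5 * iqr)
        assert report.upper == pytest.approx(q3 + 1.5 * iqr)
        flagged = [s for s, d in report.d.items()
                   if d < report.lower or d > report.upper]
        assert flagged == report.flagged_samples

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_outliers(rng.standard_normal((10, 3)))
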
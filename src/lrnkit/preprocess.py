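"""Normalization and covariate-removal transforms for omics matrices.

These are the transforms applied to each molecular layer (mRNA, DNA
methylation, histone acetylation) before association mapping and network
inference: the Beta→M logit transform for methylation, rank-based
inverse-normal (quantile) normalization, linear-regression residualization
against known covariates, hidden-factor estimation (a truncated-SVD factor
model standing in for PEER), and connectivity-based sample-outlier detection
with the 1.5×IQR flag rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "quantile_normalize",
    "residualize",
    "HiddenFactorModel",
    "estimate_hidden_factors",
    "composite_covariate",
    "OutlierReport",
    "detect_outliers",
]

_LOG2 = np.log(2.0)


def beta_to_m(beta, eps: float = 1e-6):
    """Convert methylation Beta values (fraction methylated) to M-values.

    M = log2(beta / (1 - beta)). Values at or beyond the open interval
    (0, 1) are clipped to [eps, 1 - eps] before the logit; values outside
    [0, 1] raise.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1.0 - eps)
    out = np.log2(clipped / (1.0 - clipped))
    if np.isscalar(beta) or arr.ndim == 0:
        return float(out)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M) (logistic in base 2)."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp(-arr * _LOG2))
    if np.isscalar(m) or arr.ndim == 0:
        return float(out)
    return out


def quantile_normalize(matrix, ties: str = "average"):
    """Rank-based inverse-normal transform, applied per feature (row).

    Each row's values are replaced by standard-normal quantiles of their
    (average, for ties) ranks with the offset (r - 0.5) / n, so output rows
    have mean ≈ 0 and Gaussian margins. Constant rows map to all zeros with
    a warning. Accepts an ndarray or a DataFrame (features × samples) and
    returns the same type.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    values = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
        squeeze = True
    else:
        squeeze = False
    if np.isnan(values).any():
        raise ValueError("missing values are not supported; impute or drop first")
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1, method=ties)
    out = stats.norm.ppf((ranks - 0.5) / n)
    constant = values.ptp(axis=1) == 0 if hasattr(values, "ptp") else np.ptp(values, axis=1) == 0
    if np.any(constant):
        warnings.warn(f"{int(constant.sum())} constant feature(s) set to zero", stacklevel=2)
        out[constant] = 0.0
    if squeeze:
        out = out[0]
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def residualize(matrix, covariates):
    """Replace each feature by its least-squares residuals on the covariates.

    An intercept is always included, so the output is mean-centered.
    `matrix` is features × samples; `covariates` is covariates × samples
    (or samples × covariates as a DataFrame indexed by sample). Raises if
    the design is rank deficient, naming the offending covariates.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    Y = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[None, :]
    n = Y.shape[1]

    if covariates is None:
        C = np.empty((0, n))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        C = covariates.to_numpy(dtype=float)
        names = list(covariates.index)
        if C.shape[1] != n and C.shape[0] == n:  # samples × covariates orientation
            C = C.T
            names = list(covariates.columns)
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        names = [f"cov{i}" for i in range(C.shape[0])]
    if C.shape[1] != n:
        raise ValueError("covariate sample dimension does not match matrix")

    X = np.vstack([np.ones((1, n)), C]).T  # n × (k+1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by greedy rank growth
        bad = []
        kept = X[:, :1]
        for i in range(1, X.shape[1]):
            cand = np.hstack([kept, X[:, i : i + 1]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(names[i - 1])
        raise ValueError(f"rank-deficient covariate design; collinear covariates: {bad}")

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = (Y.T - X @ beta).T
    if squeeze:
        resid = resid[0]
    if is_df:
        return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)
    return resid


@dataclass
class HiddenFactorModel:
    """A k-factor linear model of a feature × sample matrix.

    `factors` is k × samples, `weights` is features × k, and the composite
    covariate of feature j is weights[j] @ factors — the per-feature
    combination of shared hidden factors used as a single confounder node.
    """

    factors: np.ndarray
    weights: np.ndarray
    feature_ids: list = field(default_factory=list)
    n_factors: int = 0

    def __post_init__(self):
        self.factors = np.atleast_2d(np.asarray(self.factors, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.n_factors == 0:
            self.n_factors = self.factors.shape[0]


def estimate_hidden_factors(matrix, k: int) -> HiddenFactorModel:
    """Estimate k hidden factors by truncated SVD of the standardized matrix.

    Rows (features) are centered and scaled to unit variance first; factors
    are ordered by explained variance. This is a variance-capturing factor
    model in the role PEER plays for real cohorts: it produces factors F and
    per-feature weights w consumed downstream as composite covariates.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    feature_ids = list(matrix.index) if is_df else list(range(X.shape[0]))
    n_feat, n_samp = X.shape
    if k <= 0:
        return HiddenFactorModel(
            factors=np.zeros((0, n_samp)),
            weights=np.zeros((n_feat, 0)),
            feature_ids=feature_ids,
            n_factors=0,
        )
    if k >= min(n_feat, n_samp):
        raise ValueError("k must be smaller than both matrix dimensions")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    factors = Vt[:k]  # k × samples, unit norm rows
    weights = U[:, :k] * s[:k]  # features × k; Z ≈ weights @ factors
    return HiddenFactorModel(factors=factors, weights=weights, feature_ids=feature_ids, n_factors=k)


def composite_covariate(model: HiddenFactorModel, feature) -> np.ndarray:
    """Return the composite covariate Σ_i w_ij F_i for one feature.

    One value per sample; the zero vector when the model has no factors.
    """
    try:
        j = model.feature_ids.index(feature)
    except ValueError:
        raise KeyError(f"feature {feature!r} not in hidden-factor model") from None
    if model.n_factors == 0:
        return np.zeros(model.factors.shape[1] if model.factors.size else 0)
    return model.weights[j] @ model.factors


@dataclass
class OutlierReport:
    """Per-sample outlier statistic d_i with the 1.5×IQR flag rule applied."""

    d: pd.Series
    lower: float
    upper: float
    flagged_samples: list

    @property
    def threshold(self) -> tuple:
        return (self.lower, self.upper)


def detect_outliers(matrix) -> OutlierReport:
    """Flag outlier samples by low connectivity to the rest of the cohort.

    d_i = 1 − mean Spearman correlation of sample i with every other sample;
    samples with d_i outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the d
    distribution are flagged. Requires at least 4 samples.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    samples = list(matrix.columns) if is_df else list(range(X.shape[1]))
    n = X.shape[1]
    if n < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    # rank-transform columns, then Pearson on ranks = Spearman
    R = stats.rankdata(X, axis=0, method="average")
    R = R - R.mean(axis=0, keepdims=True)
    norms = np.sqrt((R**2).sum(axis=0))
    norms[norms == 0] = 1.0
    Rn = R / norms
    C = Rn.T @ Rn
    np.fill_diagonal(C, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = 1.0 - np.nanmean(C, axis=1)
    d = np.nan_to_num(d, nan=0.0)
    q1, q3 = np.percentile(d, [25, 75])
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = [s for s, di in zip(samples, d) if di < lower or di > upper]
    return OutlierReport(
        d=pd.Series(d, index=samples, name="d"),
        lower=float(lower),
        upper=float(upper),
        flagged_samples=flagged,
    )
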
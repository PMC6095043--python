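"""Cis-association mapping with permutation-based feature-level significance.

Implements xQTL mapping (SNP → molecular feature) in symmetric cis-windows
around each feature's anchor (TSS for genes, peak center for DNAm/H3K9ac),
eQTM/eQTH mapping (epigenetic peak → mRNA within 1 Mb of the TSS) with the
dual gene-level/peak-level FDR rule, Benjamini–Hochberg q-values, Storey's
π1 replication statistic, and deterministic best-SNP selection per feature.

Feature-level significance uses the min-p permutation scheme: the
phenotype/feature vector is permuted, the best nominal p over all window
candidates is recomputed each time, and the empirical p is
(1 + #{permutation best p ≤ observed best p}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CisWindow",
    "define_cis_window",
    "marginal_association",
    "permutation_min_p",
    "map_cis_qtl",
    "map_eqtx",
    "bh_fdr",
    "storey_pi1",
    "best_snp_per_feature",
]


@dataclass(frozen=True)
class CisWindow:
    """A symmetric 1-based inclusive interval around a feature anchor."""

    chrom: str
    start: int
    end: int
    feature: str = ""

    def contains(self, chrom, position) -> bool:
        return str(chrom) == self.chrom and self.start <= position <= self.end


def define_cis_window(feature, w: int, position=None, chrom=None) -> CisWindow:
    """Window [anchor − w, anchor + w] truncated at position 1.

    `feature` may be a feature id (with chrom/position given) or a pandas
    Series/mapping with 'chrom' and 'position' entries. The anchor is the
    TSS for genes and the peak center for epigenetic marks; the window is
    symmetric regardless of strand.
    """
    if w <= 0:
        raise ValueError("window half-width w must be positive")
    if position is None:
        chrom = feature["chrom"]
        position = feature["position"]
        name = str(feature.name) if hasattr(feature, "name") else ""
    else:
        name = str(feature)
    position = int(position)
    return CisWindow(chrom=str(chrom), start=max(1, position - w), end=position + w, feature=name)


def marginal_association(y, x) -> dict:
    """Simple least-squares slope of y on x with a two-sided t-test.

    Returns {'beta', 'se', 't', 'p', 'r', 'n'}. Requires ≥ 3 complete pairs
    and non-constant x.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; association undefined")
    res = stats.linregress(x, y)
    return {
        "beta": float(res.slope),
        "se": float(res.stderr),
        "t": float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        "p": float(res.pvalue),
        "r": float(res.rvalue),
        "n": n,
    }


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant rows get zero correlation
    return X / sd


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def permutation_min_p(y, X, n_perm: int = 1000, seed=0, rng=None) -> dict:
    """Min-p permutation test of y against a set of candidate regressors.

    X is candidates × samples. Only y is permuted, preserving the
    correlation structure among candidates. Returns the best candidate
    index, its nominal p, and the empirical permutation p with the
    (1 + count) / (n_perm + 1) floor.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[1] != n:
        raise ValueError("X and y sample dimensions differ")
    if rng is None:
        rng = np.random.default_rng(seed)
    Xs = _standardize_rows(X)
    ys = y - y.mean()
    sd = ys.std()
    if sd == 0:
        raise ValueError("y is constant")
    ys = ys / sd
    r_obs = Xs @ ys / n
    best_idx = int(np.argmax(np.abs(r_obs)))
    best_abs_r = float(np.abs(r_obs[best_idx]))
    nominal_p = float(_p_from_r(np.array([r_obs[best_idx]]), n)[0])

    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = ys[perm_idx]  # n_perm × n
    R = np.abs(Xs @ Yp.T) / n  # candidates × n_perm
    best_perm = R.max(axis=0)
    # smaller p ⇔ larger |r| at fixed n, so count on |r| directly
    count = int(np.sum(best_perm >= best_abs_r - 1e-12))
    emp_p = (1.0 + count) / (n_perm + 1.0)
    return {
        "best_index": best_idx,
        "best_r": float(r_obs[best_idx]),
        "nominal_p": nominal_p,
        "empirical_p": emp_p,
        "n_candidates": X.shape[0],
    }


def _mean_impute(X: np.ndarray) -> np.ndarray:
    X = np.array(X, dtype=float)
    for i in range(X.shape[0]):
        bad = ~np.isfinite(X[i])
        if bad.any():
            X[i, bad] = np.nanmean(np.where(bad, np.nan, X[i]))
    return X


def map_cis_qtl(omics, genotypes, w: int = 50_000, n_perm: int = 1000,
                fdr: float = 0.05, seed: int = 0, min_samples: int = 30) -> pd.DataFrame:
    """Map cis-QTLs for every feature of one omics layer.

    For each feature, candidate SNPs are those whose position falls in the
    symmetric window of half-width `w` around the feature anchor on the
    same chromosome; the feature-level p is the min-p permutation p over
    those candidates; q-values are BH across features; `significant` flags
    q ≤ fdr. Features with zero candidate SNPs are reported with NaN
    statistics, never silently dropped. Missing dosages are mean-imputed
    per SNP.
    """
    values = omics.values
    annot = omics.annotations
    geno = genotypes.dosages
    gannot = genotypes.annotations
    shared = [s for s in values.columns if s in set(geno.columns)]
    if len(shared) < min_samples:
        raise ValueError(f"only {len(shared)} shared samples; need ≥ {min_samples}")
    Y = values[shared].to_numpy(dtype=float)
    G = _mean_impute(geno[shared].to_numpy(dtype=float))
    snp_ids = np.array(geno.index)
    snp_chrom = gannot["chrom"].astype(str).to_numpy()
    snp_pos = gannot["position"].to_numpy()

    rng = np.random.default_rng(seed)
    rows = []
    for fi, feat in enumerate(values.index):
        fa = annot.loc[feat]
        win = define_cis_window(fa, w)
        in_win = (snp_chrom == win.chrom) & (snp_pos >= win.start) & (snp_pos <= win.end)
        idx = np.where(in_win)[0]
        # drop constant candidates (monomorphic in the shared samples)
        idx = idx[[np.ptp(G[i]) > 0 for i in idx]] if len(idx) else idx
        if len(idx) == 0:
            rows.append((feat, None, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        res = permutation_min_p(Y[fi], G[idx], n_perm=n_perm, rng=rng)
        order = np.lexsort((snp_ids[idx], snp_pos[idx]))  # deterministic ties
        cand_r = np.abs(_standardize_rows(G[idx]) @ ((Y[fi] - Y[fi].mean()) / max(Y[fi].std(), 1e-300)) / len(shared))
        best_abs = cand_r.max()
        tied = idx[np.abs(cand_r - best_abs) < 1e-12]
        best = tied[np.lexsort((snp_ids[tied], snp_pos[tied]))][0]
        beta = marginal_association(Y[fi], G[best])["beta"]
        rows.append((feat, snp_ids[best], beta, res["nominal_p"], res["empirical_p"],
                     np.nan, len(idx)))
    out = pd.DataFrame(rows, columns=["feature", "variant", "beta", "nominal_p",
                                      "perm_p", "qvalue", "n_tested"])
    tested = out["perm_p"].notna()
    if tested.any():
        out.loc[tested, "qvalue"] = bh_fdr(out.loc[tested, "perm_p"].to_numpy())
    out["significant"] = out["qvalue"] <= fdr
    return out


def map_eqtx(expression, epigenome, w: int = 1_000_000, n_perm: int = 1000,
             fdr: float = 0.05, seed: int = 0, min_samples: int = 30) -> pd.DataFrame:
    """Map epigenetic peaks associated with gene expression (eQTM/eQTH).

    Tests every (gene, peak) pair with the peak center within `w` of the
    gene's TSS. Two significance layers are combined: BH across all pairs
    on nominal p (peak level) and BH across genes on the min-p permutation
    p of the best peak (gene level); a pair is `significant` only when both
    q-values are ≤ fdr. The signed correlation is retained for
    activator/suppressor annotation downstream.
    """
    evals, eannot = expression.values, expression.annotations
    pvals_mat, pannot = epigenome.values, epigenome.annotations
    shared = [s for s in evals.columns if s in set(pvals_mat.columns)]
    if len(shared) < min_samples:
        raise ValueError(f"only {len(shared)} shared samples; need ≥ {min_samples}")
    E = evals[shared].to_numpy(dtype=float)
    P = pvals_mat[shared].to_numpy(dtype=float)
    n = len(shared)
    peak_ids = np.array(pvals_mat.index)
    peak_chrom = pannot["chrom"].astype(str).to_numpy()
    peak_pos = pannot["position"].to_numpy()

    rng = np.random.default_rng(seed)
    Ps = _standardize_rows(P)
    pair_rows = []
    gene_rows = []
    for gi, gene in enumerate(evals.index):
        ga = eannot.loc[gene]
        win = define_cis_window(ga, w)
        in_win = (peak_chrom == win.chrom) & (peak_pos >= win.start) & (peak_pos <= win.end)
        idx = np.where(in_win)[0]
        idx = idx[[np.ptp(P[i]) > 0 for i in idx]] if len(idx) else idx
        if len(idx) == 0:
            gene_rows.append((gene, np.nan, 0))
            continue
        y = E[gi]
        ys = (y - y.mean()) / max(y.std(), 1e-300)
        r = Ps[idx] @ ys / n
        p_nom = _p_from_r(r, n)
        for k, pi in enumerate(idx):
            pair_rows.append((gene, peak_ids[pi], float(r[k]), float(p_nom[k])))
        res = permutation_min_p(y, P[idx], n_perm=n_perm, rng=rng)
        gene_rows.append((gene, res["empirical_p"], len(idx)))

    pairs = pd.DataFrame(pair_rows, columns=["gene", "peak", "r", "nominal_p"])
    genes = pd.DataFrame(gene_rows, columns=["gene", "gene_perm_p", "n_tested"])
    tested = genes["gene_perm_p"].notna()
    genes["gene_q"] = np.nan
    if tested.any():
        genes.loc[tested, "gene_q"] = bh_fdr(genes.loc[tested, "gene_perm_p"].to_numpy())
    if len(pairs):
        pairs["pair_q"] = bh_fdr(pairs["nominal_p"].to_numpy())
    else:
        pairs["pair_q"] = []
    pairs = pairs.merge(genes, on="gene", how="left")
    pairs["significant"] = (pairs["pair_q"] <= fdr) & (pairs["gene_q"] <= fdr)
    return pairs


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi1(pvals, lambdas=None) -> dict:
    """Storey's estimate of the fraction of true alternatives, π1 = 1 − π0.

    π0(λ) = #{p > λ} / (m·(1 − λ)) is computed over the λ-grid and
    extrapolated to λ → 1 with a cubic smoothing spline (the smoother
    method); the result is clipped to [0, 1]. Used as a replication rate:
    p-values of signals that replicate pile up near 0, driving π1 toward 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    m = p.size
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if len(lambdas) >= 4:
        spline = interpolate.UnivariateSpline(lambdas, pi0_lam, k=3)
        pi0 = float(spline(lambdas.max()))
    else:
        pi0 = float(pi0_lam[-1])
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return {"pi1": 1.0 - pi0, "pi0": pi0, "lambdas": lambdas, "n": int(m)}


def best_snp_per_feature(results: pd.DataFrame, significant_only: bool = True) -> dict:
    """Map each feature to its best cis-SNP from a QTL result table.

    The best SNP is the one recorded per feature (smallest nominal p, ties
    broken by genomic position then id during mapping). By default only
    features passing the FDR threshold are returned.
    """
    if results.empty:
        raise ValueError("empty result table")
    sel = results
    if significant_only and "significant" in results.columns:
        sel = results[results["significant"].fillna(False)]
    sel = sel[sel["variant"].notna()]
    return dict(zip(sel["feature"], sel["variant"]))
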
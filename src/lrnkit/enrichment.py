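"""Enrichment statistics: genomic annotation, gene sets, permutation nulls.

Genomic annotation follows the gene-model convention: promoter = TSS ± 3 kb
(in genomic coordinates, symmetric about the TSS), downstream = the 3 kb
past the transcription end site in the direction of transcription, gene
body = the non-promoter part of [TSS, TED], and intergenic elsewhere.
Peaks and DNAm sites are assigned by their center position; TF-binding
assignment uses any-interval overlap instead. Category enrichment uses
Fisher's exact test (two-sided by default); gene-set enrichment uses the
upper-tail hypergeometric test with BH correction and the dual
significance rule q < 0.05 AND overlap > 2; label-vs-statistic association
uses a 10,000-permutation null of the median statistic per label class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qtl import bh_fdr

__all__ = [
    "GeneModel",
    "annotate_position",
    "EnrichmentResult",
    "fisher_enrichment",
    "hypergeometric_enrichment",
    "permutation_label_null",
]

_PROMOTER_PAD = 3_000
_DOWNSTREAM_PAD = 3_000

#: precedence when gene models overlap: the promoter is the focal category
_PRECEDENCE = {"promoter": 0, "gene_body": 1, "downstream": 2}


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: TSS/TED in genomic coordinates plus strand.

    For '+' strand genes TSS < TED; for '−' strand genes the TSS is the
    higher genomic coordinate and TED the lower.
    """

    gene: str
    chrom: str
    tss: int
    ted: int
    strand: str = "+"

    def category(self, position: int) -> str | None:
        """Annotation category of a point position, or None if outside."""
        if self.strand == "+":
            promoter = (self.tss - _PROMOTER_PAD, self.tss + _PROMOTER_PAD)
            downstream = (self.ted, self.ted + _DOWNSTREAM_PAD)
            body = (self.tss, self.ted)
        else:
            promoter = (self.tss - _PROMOTER_PAD, self.tss + _PROMOTER_PAD)
            downstream = (self.ted - _DOWNSTREAM_PAD, self.ted)
            body = (self.ted, self.tss)
        if promoter[0] <= position <= promoter[1]:
            return "promoter"
        if body[0] <= position <= body[1]:
            return "gene_body"
        if downstream[0] <= position <= downstream[1]:
            return "downstream"
        return None


def annotate_position(chrom, position: int, gene_models) -> str:
    """Assign one genomic category to a point (peak/DNAm-site center).

    Categories from overlapping gene models are resolved by precedence
    promoter > gene_body > downstream; positions hitting no model are
    intergenic. Every position receives exactly one label.
    """
    chrom = str(chrom)
    hits = []
    for gm in gene_models:
        if str(gm.chrom) != chrom:
            continue
        cat = gm.category(int(position))
        if cat is not None:
            hits.append(cat)
    if not hits:
        return "intergenic"
    return min(hits, key=_PRECEDENCE.__getitem__)


@dataclass
class EnrichmentResult:
    """A 2×2 enrichment outcome: counts, odds ratio, p, and overlap size."""

    term: str
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float
    p: float
    q: float = float("nan")
    n_overlap: int = 0
    significant: bool = False


def fisher_enrichment(hits_in_category: int, hits_total: int,
                      category_total: int, universe: int,
                      alternative: str = "two-sided",
                      term: str = "") -> EnrichmentResult:
    """Fisher's exact test on the 2×2 table implied by the four margins.

    Rows: in/out of the hit set; columns: in/out of the category. All of
    `hits_total` and `category_total` are counted within `universe`.
    """
    a = hits_in_category
    b = hits_total - a
    c = category_total - a
    d = universe - hits_total - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent 2×2 margins")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(
        term=term, table=((a, b), (c, d)), odds_ratio=float(odds), p=float(p),
        n_overlap=a,
    )


def hypergeometric_enrichment(query, terms: dict, background,
                              fdr: float = 0.05,
                              min_overlap: int = 2) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set against term sets.

    Every term set is intersected with the background before testing, and
    the query must be a subset of the background. The `significant` flag
    applies the dual rule: BH q < fdr AND overlap > min_overlap.
    """
    background = set(background)
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background set")
    N = len(background)
    n = len(query)
    rows = []
    for term, members in terms.items():
        K = len(set(members) & background)
        k = len(set(members) & query)
        # P(X ≥ k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                      "query_size", "universe", "p"])
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = (out["q"] < fdr) & (out["overlap"] > min_overlap)
    return out


def permutation_label_null(labels, statistic, focal_label: str = "upstream",
                           n_perm: int = 10_000, seed: int = 0,
                           tail: str = "greater") -> dict:
    """Permutation null for a per-feature statistic aggregated within a label.

    The observed aggregate is the median statistic over features carrying
    the focal label; the null shuffles labels across features n_perm times.
    Empirical p respects the (1 + count) / (n_perm + 1) floor; `tail` is
    'greater', 'less', or 'two-sided'. Degenerate cases (all features share
    one label) return p = 1.
    """
    labels = np.asarray(labels)
    statistic = np.asarray(statistic, dtype=float)
    if labels.shape != statistic.shape:
        raise ValueError("labels and statistic must align per feature")
    focal = labels == focal_label
    if focal.sum() == 0:
        raise ValueError(f"no feature carries label {focal_label!r}")
    observed = float(np.median(statistic[focal]))
    if focal.all():
        return {"observed": observed, "null": np.full(n_perm, observed),
                "p": 1.0, "n_perm": n_perm}
    rng = np.random.default_rng(seed)
    k = int(focal.sum())
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(statistic.size, size=k, replace=False)
        null[b] = np.median(statistic[idx])
    if tail == "greater":
        count = int(np.sum(null >= observed))
    elif tail == "less":
        count = int(np.sum(null <= observed))
    elif tail == "two-sided":
        count = 2 * min(int(np.sum(null >= observed)), int(np.sum(null <= observed)))
        count = min(count, n_perm)
    else:
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    p = (1.0 + count) / (n_perm + 1.0)
    return {"observed": observed, "null": null, "p": float(p), "n_perm": n_perm}
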
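"""Simulation studies validating the pipeline against known ground truth.

Each study generates data at the package's reference conditions, runs the
relevant stages, and scores the result against the generator's truth:

* oracle agreement — structure-MCMC edge frequencies vs exhaustive
  enumeration on small random node sets;
* structure recovery — consensus-network edge precision/recall on
  anchored cascades;
* relation recovery — upstream/downstream/independent label agreement and
  the cross-phenotype consensus precision gain;
* QTL calibration — permutation-p uniformity under the null and empirical
  FDR on a signal mixture;
* π1 recovery — Storey's estimator on known p-value mixtures.

Both the test suite and the reproduction script call these functions, so
the numbers they report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exact import exhaustive_posterior
from .mcmc import structure_mcmc
from .nodes import LrnNode, LrnNodeSet, allowed_parent_mask
from .pipeline import infer_gene_networks, run_mapping
from .preprocess import quantile_normalize
from .qtl import bh_fdr, map_cis_qtl, storey_pi1
from .relations import consensus_across_phenotypes
from .synthetic import CascadeConfig, GenotypeMatrix, OmicsMatrix, simulate_lrn_cascade

__all__ = [
    "oracle_agreement_study",
    "structure_recovery_study",
    "relation_recovery_study",
    "qtl_calibration_study",
    "pi1_study",
    "true_edge_set",
    "truth_id",
]


def truth_id(node_name: str, gene: str, feature_map: dict) -> str:
    """Translate a node-set node name into the generator's truth namespace."""
    if node_name in ("e", "p"):
        return f"{gene}:{node_name}"
    return feature_map.get(node_name, f"{gene}:{node_name}")


def true_edge_set(dataset, gene: str, node_set) -> set:
    """The generator's true edges expressed in node-set node names."""
    rev = {truth_id(nd.name, gene, node_set.feature_map): nd.name
           for nd in node_set.nodes if nd.klass != "C"}
    edges = set()
    for u, v in dataset.true_dag.edges:
        if u in rev and v in rev:
            edges.add((rev[u], rev[v]))
    return edges


def _edge_metrics(dataset, results) -> pd.DataFrame:
    rows = []
    for (gene, ctx), g in results["networks"].items():
        ns = results["node_sets"][(gene, ctx)]
        truth = true_edge_set(dataset, gene, ns)
        called = {(u, v) for u, v in g.edges
                  if not (u.startswith("C") or v.startswith("C"))}
        tp = len(called & truth)
        rows.append((gene, ctx,
                     tp / len(called) if called else 1.0,
                     tp / len(truth) if truth else 1.0,
                     len(called), len(truth)))
    return pd.DataFrame(rows, columns=["gene", "context", "precision", "recall",
                                       "n_called", "n_true"])


def oracle_agreement_study(n_cases: int = 20, n_samples: int = 300,
                           n_steps: int = 75_000, seed: int = 0) -> dict:
    """MCMC edge frequencies vs exact enumeration on random ≤5-node sets.

    Each case draws a random anchored structure (SNP → mark → mRNA chains
    with random extra edges and effect sizes) and random data, then
    compares the sampled frequencies with the exhaustive posterior. Returns
    the per-case maximum absolute error and its distribution.
    """
    rng = np.random.default_rng(seed)
    qn = lambda v: quantile_normalize(v[None, :])[0]
    errors = []
    for case in range(n_cases):
        layout = rng.integers(0, 3)
        n = n_samples
        g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
        gs = (g - g.mean()) / max(g.std(), 1e-9)
        b = rng.uniform(0.3, 0.9, size=4)
        noise = lambda: 0.6 * rng.standard_normal(n)
        if layout == 0:  # g → m → e → p
            m = b[0] * gs + noise()
            e = b[1] * (m - m.mean()) / m.std() + noise()
            p = b[2] * (e - e.mean()) / e.std() + noise()
            nodes = [LrnNode("g_m1", "g", gs, anchors=("m1",)),
                     LrnNode("m1", "m", qn(m)), LrnNode("e", "e", qn(e)),
                     LrnNode("p", "p", qn(p))]
        elif layout == 1:  # g → e ← m, e → p, h independent
            m = noise() + rng.standard_normal(n)
            e = b[0] * gs + b[1] * (m - m.mean()) / m.std() + noise()
            p = b[2] * (e - e.mean()) / e.std() + noise()
            h = rng.standard_normal(n)
            nodes = [LrnNode("g_e", "g", gs, anchors=("e",)),
                     LrnNode("m1", "m", qn(m)), LrnNode("e", "e", qn(e)),
                     LrnNode("p", "p", qn(p)), LrnNode("h1", "h", qn(h))]
        else:  # g → h → e, p ← e, with covariate on e
            h = b[0] * gs + noise()
            e = b[1] * (h - h.mean()) / h.std() + noise()
            p = b[2] * (e - e.mean()) / e.std() + noise()
            c = rng.standard_normal(n)
            nodes = [LrnNode("g_h1", "g", gs, anchors=("h1",)),
                     LrnNode("h1", "h", qn(h)), LrnNode("e", "e", qn(e)),
                     LrnNode("p", "p", qn(p)),
                     LrnNode("C_e", "C", qn(c), anchors=("e",))]
        ns = LrnNodeSet(gene=f"case{case}", nodes=nodes)
        mask = allowed_parent_mask(ns)
        exact = exhaustive_posterior(ns, mask)
        mc = structure_mcmc(ns, mask, n_steps=n_steps,
                            seed=int(rng.integers(2**31)))
        errors.append(float(np.abs(mc.freq - exact.freq).max()))
    errors = np.asarray(errors)
    return {"max_abs_error": float(errors.max()),
            "mean_abs_error": float(errors.mean()),
            "per_case": errors, "n_cases": n_cases}


def structure_recovery_study(n_genes: int = 50, n_samples: int = 400,
                             effect: float = 0.7, n_steps: int = 75_000,
                             contexts=(0,), seed: int = 0,
                             dataset=None, results=None) -> dict:
    """Consensus-network edge recovery on anchored g_m → m → e → p cascades.

    Runs the full pipeline (mapping, node sets, MCMC, consensus) and scores
    consensus edges against the generator's DAG over non-covariate nodes.
    Also verifies that SNP nodes never receive incoming edge frequency.
    """
    if dataset is None:
        cfg = CascadeConfig(n_samples=n_samples, n_genes=n_genes,
                            effect_sizes={"default": effect}, seed=seed)
        dataset = simulate_lrn_cascade(cfg)
    if results is None:
        results = infer_gene_networks(dataset, contexts=list(contexts),
                                      n_steps=n_steps, seed=seed + 1)
    metrics = _edge_metrics(dataset, results)
    snp_incoming = 0.0
    n_snp_rows = 0
    for key, freq in results["frequencies"].items():
        ns = results["node_sets"][key]
        for i, nd in enumerate(ns.nodes):
            if nd.klass == "g":
                snp_incoming = max(snp_incoming, float(freq.freq[:, i].max()))
                n_snp_rows += 1
    return {"mean_precision": float(metrics["precision"].mean()),
            "mean_recall": float(metrics["recall"].mean()),
            "per_gene": metrics,
            "max_snp_incoming_frequency": snp_incoming,
            "n_snp_nodes_checked": n_snp_rows,
            "n_ineligible": len(results["ineligible"]),
            "dataset": dataset, "results": results}


def relation_recovery_study(n_genes: int = 50, n_samples: int = 400,
                            effect: float = 0.7, n_steps: int = 75_000,
                            n_contexts: int = 4, min_support: int = 3,
                            seed: int = 0, dataset=None, results=None) -> dict:
    """Relation-label agreement with truth, single-context vs consensus.

    Scores every (mark vs mRNA) and (mRNA vs phenotype) call against the
    generator's path-derived labels, then applies the ≥ min_support
    cross-phenotype consensus and compares precision before and after.
    """
    if dataset is None:
        cfg = CascadeConfig(n_samples=n_samples, n_genes=n_genes,
                            n_phenotypes=n_contexts,
                            effect_sizes={"default": effect}, seed=seed)
        dataset = simulate_lrn_cascade(cfg)
    if results is None:
        results = infer_gene_networks(dataset, contexts=list(range(n_contexts)),
                                      n_steps=n_steps, seed=seed + 1)
    rel = results["relations"].copy()
    truth = dataset.true_relations
    truth_label = {(r.source, r.reference): r.label for r in truth.itertuples()}

    def true_of(row):
        ns = results["node_sets"][(row["gene"], int(row["phenotype"]))]
        src = truth_id(row["source"], row["gene"], ns.feature_map)
        ref = truth_id(row["reference"], row["gene"], ns.feature_map)
        return truth_label.get((src, ref))

    rel["true_label"] = rel.apply(true_of, axis=1)
    rel = rel[rel["true_label"].notna()]
    rel["correct"] = rel["label"] == rel["true_label"]
    agreement = float(rel["correct"].mean())

    single_precision = agreement  # every call carries exactly one label
    per_ctx = [rel[rel["phenotype"] == str(c)][
        ["gene", "source", "reference", "label"]]
        for c in range(n_contexts)]
    cons = consensus_across_phenotypes(per_ctx, min_support=min_support)
    merged = cons.copy()
    merged["true_label"] = [
        truth_label.get(
            (truth_id(r.source, r.gene,
                      results["node_sets"][(r.gene, 0)].feature_map),
             truth_id(r.reference, r.gene,
                      results["node_sets"][(r.gene, 0)].feature_map)))
        for r in merged.itertuples()]
    merged = merged[merged["true_label"].notna()]
    consensus_precision = float((merged["label"] == merged["true_label"]).mean())
    return {"agreement": agreement,
            "single_context_precision": single_precision,
            "consensus_precision": consensus_precision,
            "n_consensus_calls": int(len(merged)),
            "n_single_calls": int(len(rel)),
            "relations": rel, "consensus": merged,
            "dataset": dataset, "results": results}


def qtl_calibration_study(n_features: int = 500, n_samples: int = 200,
                          n_perm: int = 1000, signal_fraction: float = 0.0,
                          effect: float = 0.7, fdr: float = 0.05,
                          seed: int = 0) -> dict:
    """Permutation-p calibration and empirical FDR of cis-QTL mapping.

    Builds a cohort of features each with a private window of SNPs; under
    `signal_fraction` = 0 every feature is pure noise and the permutation
    p-values should be uniform (KS test). With a signal fraction, the
    BH-thresholded discovery set's empirical FDR is measured against truth.
    """
    rng = np.random.default_rng(seed)
    n_signal = int(round(signal_fraction * n_features))
    samples = [f"s{i+1}" for i in range(n_samples)]
    snps_per = 5
    spacing = 200_000  # windows of ±50 kb never overlap
    geno_rows, annot_rows, feat_rows, feat_annot = [], [], [], []
    is_signal = np.zeros(n_features, dtype=bool)
    is_signal[:n_signal] = True
    for f in range(n_features):
        center = 100_000 + f * spacing
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, snps_per)[:, None],
                           size=(snps_per, n_samples)).astype(float)
        y = rng.standard_normal(n_samples)
        if is_signal[f]:
            gsel = dos[0]
            y = effect * (gsel - gsel.mean()) / max(gsel.std(), 1e-9) \
                + np.sqrt(max(1 - effect**2, 0.1)) * rng.standard_normal(n_samples)
        for s in range(snps_per):
            geno_rows.append(pd.Series(dos[s], index=samples,
                                       name=f"f{f}_snp{s}"))
            annot_rows.append(("1", center - 20_000 + 10_000 * s))
        feat_rows.append(pd.Series(y, index=samples, name=f"feat{f}"))
        feat_annot.append(("1", center))
    geno = GenotypeMatrix(
        dosages=pd.DataFrame(geno_rows),
        annotations=pd.DataFrame(annot_rows, columns=["chrom", "position"],
                                 index=[s.name for s in geno_rows]),
        maf=pd.Series(dtype=float),
    )
    om = OmicsMatrix(
        values=pd.DataFrame(feat_rows),
        annotations=pd.DataFrame(feat_annot, columns=["chrom", "position"],
                                 index=[s.name for s in feat_rows]).assign(strand="+"),
        layer="test",
    )
    res = map_cis_qtl(om, geno, w=50_000, n_perm=n_perm, fdr=fdr,
                      seed=int(rng.integers(2**31)))
    pvals = res["perm_p"].to_numpy()
    ks = stats.kstest(pvals, "uniform")
    disc = res["significant"].to_numpy()
    feat_is_signal = is_signal[[int(f[4:]) for f in res["feature"]]]
    n_disc = int(disc.sum())
    false_disc = int((disc & ~feat_is_signal).sum())
    out = {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
           "n_discoveries": n_disc,
           "empirical_fdr": false_disc / n_disc if n_disc else 0.0,
           "power": float((disc & feat_is_signal).sum() / max(n_signal, 1)),
           "pvals": pvals, "n_features": n_features}
    return out


def pi1_study(n_pvals: int = 10_000, signal_fraction: float = 0.30,
              seed: int = 0) -> dict:
    """Storey π1 on a known mixture of near-zero and uniform p-values."""
    rng = np.random.default_rng(seed)
    n_sig = int(round(signal_fraction * n_pvals))
    p = np.concatenate([rng.uniform(0, 1e-3, n_sig),
                        rng.uniform(0, 1, n_pvals - n_sig)])
    mix = storey_pi1(p)
    null = storey_pi1(rng.uniform(0, 1, n_pvals))
    return {"pi1_mixture": mix["pi1"], "pi1_null": null["pi1"],
            "signal_fraction": signal_fraction, "n": n_pvals}
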
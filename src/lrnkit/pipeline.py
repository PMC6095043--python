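"""End-to-end orchestration: mapping → node sets → MCMC → relation calls.

These helpers wire the stage modules together for a whole dataset: hidden
factors are estimated per layer and residualized out before association
mapping (mapping runs on residualized, quantile-normalized matrices);
cis-QTLs use the standard windows (50 kb for mRNA and H3K9ac, 5 kb for
DNAm) and expression-associated marks the 1 Mb window; per gene and
phenotype context a typed node set is assembled, a DAG posterior sampled,
a three-state consensus network formed and relations classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import consensus_network, structure_mcmc
from .nodes import IneligibleGeneError, build_node_set
from .preprocess import estimate_hidden_factors, quantile_normalize, residualize
from .qtl import map_cis_qtl, map_eqtx
from .relations import relation_table
from .synthetic import OmicsMatrix, SyntheticDataset

__all__ = ["MappingResults", "run_mapping", "infer_gene_networks", "CIS_WINDOWS"]

#: cis-window half-widths per layer (bp): 50 kb for eQTL and haQTL, 5 kb for mQTL
CIS_WINDOWS = {"mrna": 50_000, "dnam": 5_000, "h3k9ac": 50_000}
EQTX_WINDOW = 1_000_000


@dataclass
class MappingResults:
    """All association-mapping outputs needed to assemble node sets."""

    qtl: dict  # layer -> QTL result table
    eqtm: pd.DataFrame | None
    eqth: pd.DataFrame | None
    factor_models: dict = field(default_factory=dict)


def _residualized(omics: OmicsMatrix, model) -> OmicsMatrix:
    vals = omics.values
    if model is not None and model.n_factors > 0:
        vals = residualize(vals, model.factors)
    vals = quantile_normalize(vals)
    return OmicsMatrix(values=vals, annotations=omics.annotations, layer=omics.layer)


def run_mapping(dataset: SyntheticDataset, n_perm: int = 1000, fdr: float = 0.05,
                seed: int = 0, n_factors: int | None = None) -> MappingResults:
    """Map QTLs and expression-associated marks for every layer of a dataset.

    Hidden factors (default: the generator's count, capped by matrix size)
    are estimated per layer, removed by residualization prior to mapping,
    and returned for composite-covariate construction.
    """
    if n_factors is None:
        n_factors = dataset.config.n_hidden_factors
    models = {}
    resid = {}
    for layer, om in dataset.omics.items():
        k = min(n_factors, om.values.shape[0] - 1, om.values.shape[1] - 1)
        models[layer] = estimate_hidden_factors(om.values, k) if k > 0 else None
        resid[layer] = _residualized(om, models[layer])

    qtl = {}
    for i, (layer, om) in enumerate(sorted(resid.items())):
        qtl[layer] = map_cis_qtl(om, dataset.genotypes, w=CIS_WINDOWS[layer],
                                 n_perm=n_perm, fdr=fdr, seed=seed + 11 * (i + 1))
    eqtm = eqth = None
    if "dnam" in resid:
        eqtm = map_eqtx(resid["mrna"], resid["dnam"], w=EQTX_WINDOW,
                        n_perm=n_perm, fdr=fdr, seed=seed + 101)
    if "h3k9ac" in resid:
        eqth = map_eqtx(resid["mrna"], resid["h3k9ac"], w=EQTX_WINDOW,
                        n_perm=n_perm, fdr=fdr, seed=seed + 102)
    return MappingResults(qtl=qtl, eqtm=eqtm, eqth=eqth,
                          factor_models={k: v for k, v in models.items() if v is not None})


def infer_gene_networks(
    dataset: SyntheticDataset,
    mapping: MappingResults | None = None,
    genes=None,
    contexts=None,
    n_steps: int = 75_000,
    burn_in_fraction: float = 0.10,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
    score: str = "bge",
    require_eqtl: bool = True,
) -> dict:
    """Infer one consensus network per (gene, phenotype context).

    Returns {'networks': {(gene, ctx): DiGraph}, 'frequencies': {...},
    'node_sets': {...}, 'relations': DataFrame, 'mapping': MappingResults,
    'ineligible': [genes]}. Relations cover every mark node vs the mRNA
    node, plus the mRNA node vs the phenotype node, with node names
    translated back to feature identifiers. The master seed expands to
    independent per-(gene, context) streams.
    """
    if mapping is None:
        mapping = run_mapping(dataset, n_perm=n_perm, fdr=fdr, seed=seed)
    if genes is None:
        genes = dataset.genes
    if contexts is None:
        contexts = sorted({c for _, c in dataset.phenotypes.index})

    geno_vals = dataset.genotypes.dosages
    dnam_vals = dataset.omics.get("dnam")
    h3k9ac_vals = dataset.omics.get("h3k9ac")
    mrna_vals = dataset.omics["mrna"].values

    networks, freqs, node_sets, rel_rows, ineligible = {}, {}, {}, [], []
    ss = np.random.SeedSequence(seed)
    for gi, gene in enumerate(genes):
        try:
            base_set = build_node_set(
                gene=gene,
                expression_values=mrna_vals.loc[gene].to_numpy(),
                phenotype=dataset.phenotype_vector(gene, contexts[0]),
                eqtm=mapping.eqtm,
                eqth=mapping.eqth,
                mrna_qtl=mapping.qtl.get("mrna"),
                dnam_qtl=mapping.qtl.get("dnam"),
                h3k9ac_qtl=mapping.qtl.get("h3k9ac"),
                dnam_values=dnam_vals.values if dnam_vals is not None else None,
                h3k9ac_values=h3k9ac_vals.values if h3k9ac_vals is not None else None,
                genotype_values=geno_vals,
                factor_models=mapping.factor_models,
                require_eqtl=require_eqtl,
            )
        except IneligibleGeneError:
            ineligible.append(gene)
            continue
        for ctx in contexts:
            node_set = base_set
            if ctx != contexts[0]:
                node_set = _swap_phenotype(base_set, dataset.phenotype_vector(gene, ctx))
            sub_seed = int(np.random.SeedSequence((seed, gi, ctx)).generate_state(1)[0] % (2**31))
            freq = structure_mcmc(node_set, n_steps=n_steps,
                                  burn_in_fraction=burn_in_fraction,
                                  seed=sub_seed, score=score)
            cons = consensus_network(freq)
            networks[(gene, ctx)] = cons
            freqs[(gene, ctx)] = freq
            node_sets[(gene, ctx)] = node_set
            marks = [nd.name for nd in node_set.nodes if nd.klass in ("m", "h")]
            tab = relation_table(cons, marks, "e", gene=gene, phenotype=str(ctx))
            tab = pd.concat(
                [tab, relation_table(cons, ["e"], "p", gene=gene, phenotype=str(ctx))],
                ignore_index=True,
            )
            fm = node_set.feature_map
            tab["source_feature"] = [fm.get(s, s) for s in tab["source"]]
            rel_rows.append(tab)

    relations = (pd.concat(rel_rows, ignore_index=True)
                 if rel_rows else pd.DataFrame(
                     columns=["gene", "source", "reference", "phenotype", "label",
                              "source_feature"]))
    return {
        "networks": networks,
        "frequencies": freqs,
        "node_sets": node_sets,
        "relations": relations,
        "mapping": mapping,
        "ineligible": ineligible,
    }


def _swap_phenotype(node_set, phenotype_values):
    """Clone a node set with a different phenotype context vector."""
    from .nodes import LrnNode, LrnNodeSet

    new_nodes = []
    for nd in node_set.nodes:
        if nd.klass == "p":
            new_nodes.append(LrnNode("p", "p", quantile_normalize(
                np.asarray(phenotype_values, dtype=float)[None, :])[0]))
        else:
            new_nodes.append(nd)
    return LrnNodeSet(gene=node_set.gene, nodes=new_nodes,
                      phenotype_id=node_set.phenotype_id,
                      feature_map=dict(node_set.feature_map))
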
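"""Upstream / downstream / independent relation calling on consensus DAGs.

A node is upstream of a reference node when a directed path leads from it
to the reference (through any intermediate node types), downstream when
the reverse path exists, and independent when neither does; acyclicity
guarantees the three states are exclusive. Gene-vs-phenotype calls use the
stricter direct-edge rule for "upstream": a gene is an upstream gene only
when its mRNA node points directly at the phenotype node, while downstream
and independent remain path-based — the only reading under which the three
labels partition the genes.

Cross-phenotype consistency keeps a relation only when the identical label
recurs in at least `min_support` of the phenotype-specific networks
(default 3 of 4). Upstream marks are annotated as suppressors or
activators from the sign of their expression correlation.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "classify_relation",
    "call_upstream_genes",
    "relation_table",
    "consensus_across_phenotypes",
    "sign_of_regulation",
]


def classify_relation(dag: nx.DiGraph, a, b) -> str:
    """Label node `a` relative to node `b` by directed-path reachability."""
    if a not in dag or b not in dag:
        raise KeyError(f"node missing from DAG: {a if a not in dag else b}")
    if nx.has_path(dag, a, b):
        return "upstream"
    if nx.has_path(dag, b, a):
        return "downstream"
    return "independent"


def call_upstream_genes(consensus_dags: dict, mrna_node: str = "e",
                        phenotype_node: str = "p") -> pd.DataFrame:
    """Classify each gene against the phenotype across its consensus DAGs.

    `consensus_dags` maps (gene, phenotype context) — or gene, for a single
    context — to a consensus DAG containing one mRNA node and one phenotype
    node. A gene is `upstream` iff the direct edge e→p exists; `downstream`
    iff a directed path p→…→e exists; `independent` otherwise.
    """
    rows = []
    for key, dag in consensus_dags.items():
        gene, ctx = key if isinstance(key, tuple) else (key, 0)
        if mrna_node not in dag or phenotype_node not in dag:
            raise KeyError(f"{key}: DAG lacks {mrna_node!r} or {phenotype_node!r}")
        if dag.has_edge(mrna_node, phenotype_node):
            label = "upstream"
        elif nx.has_path(dag, phenotype_node, mrna_node):
            label = "downstream"
        else:
            label = "independent"
        rows.append((gene, ctx, label))
    return pd.DataFrame(rows, columns=["gene", "phenotype", "label"])


def relation_table(dag: nx.DiGraph, sources, reference, gene: str = "",
                   phenotype: str = "") -> pd.DataFrame:
    """Classify each source node against one reference node in a DAG."""
    rows = [
        (gene, src, reference, phenotype, classify_relation(dag, src, reference))
        for src in sources
    ]
    return pd.DataFrame(rows, columns=["gene", "source", "reference", "phenotype", "label"])


def consensus_across_phenotypes(tables, min_support: int = 3) -> pd.DataFrame:
    """Keep (source, reference) labels identical in ≥ min_support contexts.

    `tables` is an iterable of per-phenotype relation tables (columns
    source, reference, label, and optionally gene). A pair whose most
    frequent label reaches min_support is retained with that label and its
    support count; pairs split below min_support are dropped. At most one
    label per ordered pair is ever emitted.
    """
    tables = list(tables)
    if len(tables) < min_support:
        raise ValueError("fewer phenotype contexts than min_support")
    allt = pd.concat(tables, ignore_index=True)
    keys = [c for c in ("gene", "source", "reference") if c in allt.columns]
    counts = allt.groupby(keys + ["label"], sort=True).size().reset_index(name="support")
    # per pair, the single best-supported label (deterministic tie-break by label
    # name is irrelevant: a tie at min_support ≥ half the contexts cannot occur
    # for two labels unless both < min_support)
    counts = counts.sort_values(keys + ["support"], ascending=True)
    best = counts.groupby(keys, sort=True).tail(1)
    kept = best[best["support"] >= min_support].reset_index(drop=True)
    return kept


def sign_of_regulation(label: str, correlation: float) -> str:
    """Annotate an upstream mark as suppressor (r < 0) or activator (r > 0)."""
    if label != "upstream":
        return "n/a"
    if correlation < 0:
        return "suppressor"
    if correlation > 0:
        return "activator"
    return "n/a"
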
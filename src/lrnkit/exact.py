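"""Exact posterior edge probabilities by exhaustive DAG enumeration.

For small node sets this enumerates every mask-respecting DAG, computes
its normalized posterior weight under the same decomposable score the
sampler uses, and marginalizes edges exactly. It serves as the independent
oracle for the structure-MCMC frequencies: the two must agree as the chain
length grows.
"""

from __future__ import annotations

import math

import numpy as np

from .mcmc import EdgeFrequencyMatrix
from .nodes import LrnNodeSet, ParentMask, allowed_parent_mask
from .scoring import make_scorer

__all__ = ["exhaustive_posterior"]

_MAX_MASKABLE = 6
_MAX_COMBOS = 5_000_000


def exhaustive_posterior(
    node_set: LrnNodeSet | np.ndarray,
    mask: ParentMask | None = None,
    score: str = "bge",
    max_parents: int | None = None,
) -> EdgeFrequencyMatrix:
    """Enumerate all mask-respecting DAGs and return exact edge marginals.

    Refuses node sets with more than 6 maskable (non-root) nodes, or whose
    parent-set product space is too large to enumerate.
    """
    if isinstance(node_set, LrnNodeSet):
        data = node_set.data()
        names = node_set.names
        if mask is None:
            mask = allowed_parent_mask(node_set)
    else:
        data = np.asarray(node_set, dtype=float)
        names = [f"v{i}" for i in range(data.shape[0])]
        if mask is None:
            raise ValueError("a ParentMask is required with raw data")
    allowed = mask.allowed
    n = data.shape[0]
    scorer = make_scorer(data, score)

    children_nodes = [c for c in range(n) if allowed[c].any()]
    if len(children_nodes) > _MAX_MASKABLE:
        raise ValueError(
            f"{len(children_nodes)} maskable nodes exceed the enumeration bound "
            f"of {_MAX_MASKABLE}; use structure_mcmc instead"
        )

    # per-child candidate parent sets with their family scores
    cand_sets = []
    total_combos = 1
    for c in children_nodes:
        cands = tuple(np.where(allowed[c])[0])
        sets = []
        m = len(cands)
        for bits in range(1 << m):
            pa = tuple(cands[k] for k in range(m) if bits >> k & 1)
            if max_parents is not None and len(pa) > max_parents:
                continue
            sets.append((pa, scorer.family(c, pa)))
        cand_sets.append(sets)
        total_combos *= len(sets)
    if total_combos > _MAX_COMBOS:
        raise ValueError(
            f"{total_combos} parent-set combinations exceed the enumeration budget"
        )

    base_score = sum(scorer.family(c, ()) for c in range(n) if c not in children_nodes)

    # depth-first over children with incremental acyclicity pruning
    dag_scores: list = []
    dag_edges: list = []

    def reaches(src, dst, children_map):
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            for v in children_map.get(u, ()):
                if v == dst:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    children_map: dict = {}

    def recurse(level, acc_score, acc_edges):
        if level == len(children_nodes):
            dag_scores.append(acc_score)
            dag_edges.append(tuple(acc_edges))
            return
        c = children_nodes[level]
        for pa, fscore in cand_sets[level]:
            # cycle iff some chosen parent is reachable FROM c via edges so far
            if pa and any(reaches(c, p, children_map) for p in pa):
                continue
            for p in pa:
                children_map.setdefault(p, set()).add(c)
            recurse(level + 1, acc_score + fscore, acc_edges + [(p, c) for p in pa])
            for p in pa:
                children_map[p].discard(c)

    recurse(0, base_score, [])

    scores = np.asarray(dag_scores)
    mx = scores.max()
    w = np.exp(scores - mx)
    Z = w.sum()
    freq = np.zeros((n, n))
    for wi, edges in zip(w, dag_edges):
        for p, c in edges:
            freq[p, c] += wi
    freq /= Z
    return EdgeFrequencyMatrix(
        freq=freq,
        names=names,
        n_samples_used=len(dag_scores),
        acceptance_rate=float("nan"),
        log_score_final=float(mx + math.log(Z)),
    )
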
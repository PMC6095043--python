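"""Typed node sets and the allowed-parent mask for per-gene networks.

A local regulatory network (LRN) for one gene contains: the phenotype p,
the gene's mRNA level e, its expression-associated DNA-methylation sites m
and H3K9ac peaks h (only those that themselves have a cis-QTL — the
SNP-associated marks), the best anchor SNP of each molecular variable
(g_e, g_m, g_h), and one composite hidden-covariate node per molecular
variable (C_e, C_m, C_h), each the weighted combination of that layer's
hidden factors for that feature.

Genetic anchoring is encoded structurally: SNP nodes can only emit edges,
and each node class has a fixed menu of allowed parents —
P(e) ⊆ {g_e, m, h, p, C_e}, P(m) ⊆ {g_m, e, h, p, C_m},
P(h) ⊆ {g_h, m, e, p, C_h}, P(p) ⊆ {g_e, g_m, g_h, m, h, e} —
with covariate nodes as roots feeding only their own variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import composite_covariate, quantile_normalize

__all__ = [
    "LrnNode",
    "LrnNodeSet",
    "ParentMask",
    "allowed_parent_mask",
    "build_node_set",
    "IneligibleGeneError",
]

#: canonical ordering of node classes inside a node set
_CLASS_ORDER = {"p": 0, "e": 1, "m": 2, "h": 3, "g": 4, "C": 5}


class IneligibleGeneError(ValueError):
    """The gene does not meet the LRN inclusion criteria."""


@dataclass(frozen=True)
class LrnNode:
    """One typed node: name, class symbol, values, and (for SNP / covariate
    nodes) the names of the molecular variables it is attached to."""

    name: str
    klass: str  # one of p, e, m, h, g, C
    values: np.ndarray
    anchors: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass
class LrnNodeSet:
    """The node collection for one gene's network, in canonical order."""

    gene: str
    nodes: list
    phenotype_id: str = "phenotype"
    feature_map: dict = field(default_factory=dict)  # node name -> feature/variant id

    def __post_init__(self):
        self.nodes = sorted(self.nodes, key=lambda nd: (_CLASS_ORDER[nd.klass], nd.name))
        lens = {len(nd.values) for nd in self.nodes}
        if len(lens) > 1:
            raise ValueError("all node value vectors must share the sample dimension")
        classes = [nd.klass for nd in self.nodes]
        if classes.count("e") != 1:
            raise ValueError("a node set must contain exactly one mRNA node")
        if classes.count("p") > 1:
            raise ValueError("at most one phenotype node")

    @property
    def names(self) -> list:
        return [nd.name for nd in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_samples(self) -> int:
        return len(self.nodes[0].values)

    def index(self, name: str) -> int:
        for i, nd in enumerate(self.nodes):
            if nd.name == name:
                return i
        raise KeyError(name)

    def data(self) -> np.ndarray:
        """Node values as a nodes × samples matrix (canonical row order)."""
        return np.vstack([nd.values for nd in self.nodes])


@dataclass
class ParentMask:
    """Boolean matrix allowed[child, parent]; True where the edge
    parent → child may exist."""

    allowed: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.allowed = np.asarray(self.allowed, dtype=bool)
        if self.allowed.ndim != 2 or self.allowed.shape[0] != self.allowed.shape[1]:
            raise ValueError("mask must be square")
        if np.any(np.diag(self.allowed)):
            raise ValueError("self-edges are never allowed")


def allowed_parent_mask(node_set: LrnNodeSet) -> ParentMask:
    """Encode the parent-set menus, SNP-root and covariate-root constraints.

    Each SNP node may parent only the molecular variables it anchors plus
    the phenotype; each covariate node may parent only its own variable;
    SNP and covariate nodes have no parents at all.
    """
    nodes = node_set.nodes
    n = len(nodes)
    allowed = np.zeros((n, n), dtype=bool)
    name_to_class = {nd.name: nd.klass for nd in nodes}
    for ci, child in enumerate(nodes):
        for pi, parent in enumerate(nodes):
            if ci == pi:
                continue
            ck, pk = child.klass, parent.klass
            if ck in ("g", "C"):
                continue  # roots
            if pk == "g":
                if ck == "p" or child.name in parent.anchors:
                    allowed[ci, pi] = True
                continue
            if pk == "C":
                if child.name in parent.anchors:
                    allowed[ci, pi] = True
                continue
            if ck == "e":
                allowed[ci, pi] = pk in ("m", "h", "p")
            elif ck == "m":
                allowed[ci, pi] = pk in ("e", "h", "p")
            elif ck == "h":
                allowed[ci, pi] = pk in ("m", "e", "p")
            elif ck == "p":
                allowed[ci, pi] = pk in ("m", "h", "e")
    _ = name_to_class  # classes fully determined by node objects
    return ParentMask(allowed=allowed, names=node_set.names)


def _qn(v: np.ndarray) -> np.ndarray:
    return quantile_normalize(v[None, :])[0]


def build_node_set(
    gene: str,
    expression_values: np.ndarray,
    phenotype: np.ndarray,
    eqtm=None,
    eqth=None,
    mrna_qtl=None,
    dnam_qtl=None,
    h3k9ac_qtl=None,
    dnam_values=None,
    h3k9ac_values=None,
    genotype_values=None,
    factor_models=None,
    phenotype_id: str = "phenotype",
    require_eqtl: bool = True,
    normalize: bool = True,
    composite_mode: str = "cis_aware",
) -> LrnNodeSet:
    """Assemble the LRN node set for one gene from mapping results.

    Marks enter only if they are significantly expression-associated
    (eQTM/eQTH tables, `significant` column) AND have a significant cis-QTL
    of their own; each included variable brings its best anchor SNP. A SNP
    that anchors several variables (e.g. the gene's best eQTL coincides
    with a mark's QTL) becomes a single node allowed to parent all of them.
    Non-genetic node values are quantile-normalized; SNP dosages are
    centered and scaled. Raises IneligibleGeneError when the gene has no
    SNP-anchored mark, or (with require_eqtl) no eQTL either.

    `dnam_values` / `h3k9ac_values` / `genotype_values` are mappings (or
    DataFrames indexed by feature/variant) giving sample vectors;
    `factor_models` maps layer name ('mrna', 'dnam', 'h3k9ac') to a
    HiddenFactorModel for composite covariates.

    `composite_mode` controls how each variable's composite covariate is
    formed from its layer's hidden factors. 'model' uses the factor-model
    weights directly (Σ_i w_ij F_i). 'cis_aware' (default) re-estimates the
    factor weights of each variable by regressing it on the factors jointly
    with its candidate local regulators — the anchor SNP dosages, plus the
    SNP-associated marks in the case of the mRNA node — and combines the
    factors with those coefficients only. Partialling out the candidate
    regulators (and only those: never a variable's putative targets)
    prevents the composite from absorbing cascade signal mediated through
    local regulation, which would otherwise distort the conditional
    independences that orient the network.
    """

    def _get(source, key):
        if source is None:
            raise KeyError(key)
        if hasattr(source, "loc"):
            return np.asarray(source.loc[key], dtype=float)
        return np.asarray(source[key], dtype=float)

    def _best_snp(table, feature):
        if table is None:
            return None
        rows = table[(table["feature"] == feature) & table["significant"].fillna(False)]
        if rows.empty:
            return None
        return rows.iloc[0]["variant"]

    nodes = []
    feature_map: dict = {}
    snp_anchors: dict = {}  # variant id -> list of anchored node names

    e_snp = _best_snp(mrna_qtl, gene)
    if e_snp is not None:
        snp_anchors.setdefault(e_snp, []).append("e")

    mark_nodes = []  # (name, klass, feature_id, layer)
    for table, qtl_table, klass, layer, prefix in (
        (eqtm, dnam_qtl, "m", "dnam", "m"),
        (eqth, h3k9ac_qtl, "h", "h3k9ac", "h"),
    ):
        if table is None:
            continue
        sig = table[(table["gene"] == gene) & table["significant"].fillna(False)]
        k = 0
        for _, row in sig.iterrows():
            peak = row["peak"]
            snp = _best_snp(qtl_table, peak)
            if snp is None:
                continue  # only SNP-associated marks enter the LRN
            k += 1
            name = f"{prefix}{k}"
            mark_nodes.append((name, klass, peak, layer))
            snp_anchors.setdefault(snp, []).append(name)

    if not any(klass == "m" or klass == "h" for _, klass, _, _ in mark_nodes):
        raise IneligibleGeneError(f"{gene}: no SNP-associated epigenetic mark")
    if require_eqtl and e_snp is None:
        raise IneligibleGeneError(f"{gene}: no significant cis-eQTL for the mRNA node")

    norm = _qn if normalize else (lambda v: np.asarray(v, dtype=float))

    e_vals = norm(np.asarray(expression_values, dtype=float))
    nodes.append(LrnNode("e", "e", e_vals))
    nodes.append(LrnNode("p", "p", norm(np.asarray(phenotype, dtype=float))))

    feature_of = {"e": gene}
    for name, klass, feature, layer in mark_nodes:
        vals = _get(dnam_values if layer == "dnam" else h3k9ac_values, feature)
        nodes.append(LrnNode(name, klass, norm(vals)))
        feature_of[name] = feature

    for gi, (variant, anchored) in enumerate(sorted(snp_anchors.items()), start=1):
        dose = _get(genotype_values, variant)
        sd = dose.std()
        vals = (dose - dose.mean()) / (sd if sd > 0 else 1.0)
        suffix = "_".join(sorted(anchored))
        nodes.append(LrnNode(f"g_{suffix}", "g", vals, anchors=tuple(sorted(anchored))))
        feature_map[f"g_{suffix}"] = variant

    if factor_models:
        layer_of = {"e": "mrna"}
        layer_of.update({name: layer for name, _, _, layer in mark_nodes})
        values_of = {nd.name: nd.values for nd in nodes}
        for node_name, layer in layer_of.items():
            model = factor_models.get(layer)
            if model is None or model.n_factors == 0:
                continue
            if composite_mode == "model":
                try:
                    cov = composite_covariate(model, feature_of[node_name])
                except KeyError:
                    continue
            elif composite_mode == "cis_aware":
                F = model.factors
                regulators = [nd.values for nd in nodes if nd.klass == "g"]
                if node_name == "e":
                    regulators += [values_of[nm] for nm, _, _, _ in mark_nodes]
                X = np.vstack([np.ones(F.shape[1]), F] + regulators).T
                coef, *_ = np.linalg.lstsq(X, values_of[node_name], rcond=None)
                cov = F.T @ coef[1 : 1 + F.shape[0]]
            else:
                raise ValueError("composite_mode must be 'model' or 'cis_aware'")
            if np.ptp(cov) == 0:
                continue
            nodes.append(LrnNode(f"C_{node_name}", "C", norm(cov), anchors=(node_name,)))

    feature_map.update(feature_of)
    return LrnNodeSet(gene=gene, nodes=nodes, phenotype_id=phenotype_id,
                      feature_map=feature_map)
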
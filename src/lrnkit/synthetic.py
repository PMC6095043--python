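"""Synthetic genotype + multi-omics + phenotype cascades with known causal DAGs.

Each simulated gene is a small linear-Gaussian structural-equation cascade
over typed nodes — anchor SNPs (g_e/g_m/g_h), DNA-methylation sites (m),
histone-acetylation peaks (h), one mRNA (e), and one or more phenotype
contexts (p) — wired by a user-specified template such as the chain
g_m → m → e → p. SNP dosages are drawn under Hardy–Weinberg equilibrium;
every non-root node is a standardized-parent linear combination plus shared
hidden-factor loadings plus Gaussian noise. The generator records the true
DAG and the true upstream/downstream/independent relations it implies, so
every downstream stage (QTL mapping, network inference, relation calling)
can be scored against ground truth.

The default configuration is the study condition used throughout the test
suite: n = 400 samples, standardized effect 0.7 on every causal edge, noise
standard deviation 0.5, one DNAm site on the causal chain, one H3K9ac peak
causally unrelated to expression, two hidden confounding factors at loading
scale 0.3, and four phenotype contexts sharing the same structural role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CascadeConfig",
    "GenotypeMatrix",
    "OmicsMatrix",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_lrn_cascade",
    "true_relations",
    "node_class",
]

#: symbolic node classes used in effect-size keys and parent menus
_CLASSES = ("g", "m", "h", "e", "p", "C")


def node_class(name: str) -> str:
    """Map a node name to its class symbol: g (SNP), m, h, e, p, or C."""
    if name.startswith("g_") or name == "g":
        return "g"
    if name.startswith("C"):
        return "C"
    c = name[0]
    if c not in ("m", "h", "e", "p"):
        raise ValueError(f"cannot infer node class from name {name!r}")
    return c


def _default_template(n_dnam: int, n_h3k9ac: int) -> list:
    """Chain g_m1 → m1 → e → p with extra marks as SNP-anchored bystanders.

    The first DNAm site carries the causal cascade into expression; every
    additional DNAm site and every H3K9ac peak gets its own anchor SNP but
    no edge to e, so the truth contains upstream, downstream and independent
    relations for the classifier to recover.
    """
    edges = []
    if n_dnam >= 1:
        edges += [("g_m1", "m1"), ("m1", "e"), ("e", "p")]
    else:
        edges += [("g_e", "e"), ("e", "p")]
    for j in range(2, n_dnam + 1):
        edges.append((f"g_m{j}", f"m{j}"))
    for j in range(1, n_h3k9ac + 1):
        edges.append((f"g_h{j}", f"h{j}"))
    return edges


@dataclass
class CascadeConfig:
    """Study conditions for one simulated multi-omics cascade.

    effect_sizes maps edge classes "parent->child" over class symbols
    (e.g. "m->e") to standardized regression coefficients; the "default"
    key covers unlisted classes. noise_sd is the SD of each node's private
    Gaussian noise; factor_strength scales N(0,1) loadings of the shared
    hidden factors onto every molecular (non-SNP, non-phenotype) node.
    """

    n_samples: int = 400
    n_genes: int = 1
    n_dnam: int = 1
    n_h3k9ac: int = 1
    maf_range: tuple = (0.05, 0.5)
    effect_sizes: dict = field(default_factory=lambda: {"default": 0.7})
    noise_sd: float = 0.5
    n_hidden_factors: int = 2
    factor_strength: float = 0.3
    n_phenotypes: int = 4
    true_dag_template: Optional[list] = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for v in (self.n_samples, self.n_genes, self.n_phenotypes):
            if v < 1:
                raise ValueError("counts must be positive")
        if self.n_dnam < 0 or self.n_h3k9ac < 0:
            raise ValueError("node counts must be nonnegative")
        if self.true_dag_template is None:
            self.true_dag_template = _default_template(self.n_dnam, self.n_h3k9ac)
        g = nx.DiGraph(self.true_dag_template)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("true_dag_template must be acyclic")
        for parent, child in self.true_dag_template:
            if node_class(child) == "g":
                raise ValueError(f"SNP node {child!r} cannot have incoming edges")

    def effect(self, parent: str, child: str) -> float:
        key = f"{node_class(parent)}->{node_class(child)}"
        if key in self.effect_sizes:
            return float(self.effect_sizes[key])
        return float(self.effect_sizes.get("default", 0.7))


@dataclass
class GenotypeMatrix:
    """SNP dosages (SNPs × samples, values 0/1/2) with coordinates and MAF."""

    dosages: pd.DataFrame
    annotations: pd.DataFrame  # index = SNP id; columns chrom, position
    maf: pd.Series

    @property
    def samples(self):
        return list(self.dosages.columns)


@dataclass
class OmicsMatrix:
    """One molecular layer as features × samples, with feature annotations.

    Annotation columns: chrom, position (TSS for genes, peak center for
    marks), strand.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    layer: str = ""

    @property
    def samples(self):
        return list(self.values.columns)


@dataclass
class SyntheticDataset:
    """A simulated cohort with known causal structure.

    phenotypes has one row per (gene, phenotype context); true_dag is over
    namespaced node names "<gene>:<node>" with a single p node per gene
    (contexts are structural replicates). dnam values are on the latent
    (M-like) scale; `dnam_beta` carries the logistic transform to the Beta
    scale for exercising the Beta→M pipeline.
    """

    config: CascadeConfig
    genotypes: GenotypeMatrix
    omics: dict
    phenotypes: pd.DataFrame
    true_dag: nx.DiGraph
    hidden_factors: np.ndarray
    dnam_beta: Optional[pd.DataFrame] = None

    @property
    def genes(self):
        return [f"gene{i+1}" for i in range(self.config.n_genes)]

    @property
    def samples(self):
        return list(self.phenotypes.columns)

    def phenotype_vector(self, gene: str, context: int = 0) -> np.ndarray:
        return self.phenotypes.loc[(gene, context)].to_numpy(dtype=float)

    @property
    def phenotype(self) -> np.ndarray:
        """The single phenotype vector (only for 1-gene, 1-context datasets)."""
        if len(self.phenotypes) != 1:
            raise ValueError("dataset has multiple phenotype rows; use phenotype_vector")
        return self.phenotypes.iloc[0].to_numpy(dtype=float)

    @property
    def true_relations(self) -> pd.DataFrame:
        return true_relations(self)

    def gene_nodes(self, gene: str) -> list:
        prefix = gene + ":"
        return [n for n in self.true_dag.nodes if n.startswith(prefix)]

    def to_dir(self, path) -> None:
        """Export TSV matrices, the true-DAG edge list, and a YAML config echo."""
        import os

        import yaml

        os.makedirs(path, exist_ok=True)
        self.genotypes.dosages.to_csv(os.path.join(path, "genotypes.tsv"), sep="\t")
        self.genotypes.annotations.to_csv(os.path.join(path, "genotype_annotations.tsv"), sep="\t")
        for layer, om in self.omics.items():
            om.values.to_csv(os.path.join(path, f"{layer}.tsv"), sep="\t")
            om.annotations.to_csv(os.path.join(path, f"{layer}_annotations.tsv"), sep="\t")
        self.phenotypes.to_csv(os.path.join(path, "phenotypes.tsv"), sep="\t")
        with open(os.path.join(path, "true_dag.tsv"), "w") as fh:
            for parent, child in self.true_dag.edges:
                fh.write(f"{parent}\t{child}\n")
        cfg = dict(self.config.__dict__)
        cfg["maf_range"] = list(cfg["maf_range"])
        with open(os.path.join(path, "config.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh)


def simulate_genotypes(n_samples: int, n_snps: int, maf_range=(0.05, 0.5), seed: int = 0,
                       rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Draw biallelic SNP dosages under Hardy–Weinberg equilibrium.

    Each SNP's minor-allele frequency is uniform on maf_range and its
    dosages are Binomial(2, MAF) across samples. The recorded `maf` is the
    empirical minor-allele frequency of the simulated column.
    """
    if n_samples < 2 or n_snps < 1:
        raise ValueError("n_samples must be ≥ 2 and n_snps ≥ 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, mafs[:, None], size=(n_snps, n_samples)).astype(float)
    snp_ids = [f"snp{i+1}" for i in range(n_snps)]
    samples = [f"s{i+1}" for i in range(n_samples)]
    freq = dosages.mean(axis=1) / 2.0
    emp_maf = np.minimum(freq, 1.0 - freq)
    annot = pd.DataFrame(
        {"chrom": "1", "position": 1000 * (np.arange(n_snps) + 1)},
        index=pd.Index(snp_ids, name="snp"),
    )
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=snp_ids, columns=samples),
        annotations=annot,
        maf=pd.Series(emp_maf, index=snp_ids, name="maf"),
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def _rank_int(v: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal standardization, offset (r − 0.5)/n."""
    from scipy import stats as _st

    ranks = _st.rankdata(v, method="average")
    return _st.norm.ppf((ranks - 0.5) / len(v))


def _standardize(v: np.ndarray, parent_class: str = "") -> np.ndarray:
    """Standardize a parent before applying its effect.

    SNP dosages are z-scored (genetic nodes are never quantile-normalized
    downstream, so the linear dependence on the z-scored dosage is exact);
    continuous parents are rank-inverse-normal standardized, which makes
    the cascade linear-Gaussian exactly on the scale the network model
    sees after its own quantile normalization.
    """
    if parent_class == "g":
        return _zscore(v)
    return _rank_int(v)


# genomic layout per gene: marks and their anchor SNPs placed inside the
# QTL windows used downstream (50 kb eQTL/haQTL, 5 kb mQTL, 1 Mb eQTM/eQTH)
_GENE_SPACING = 3_000_000
_TSS0 = 1_000_000


def _gene_layout(gene_idx: int, template_nodes) -> dict:
    tss = _TSS0 + gene_idx * _GENE_SPACING
    pos = {"e": tss, "p": None}
    m_idx = h_idx = 0
    for name in sorted(template_nodes):
        cls = node_class(name)
        if cls == "m" :
            m_idx += 1
            pos[name] = tss + 15_000 + 2_000 * m_idx
        elif cls == "h":
            h_idx += 1
            pos[name] = tss - 40_000 - 5_000 * h_idx
    for name in template_nodes:
        if node_class(name) == "g":
            target = name[2:]  # g_m1 -> m1, g_e -> e
            anchor = pos.get(target, tss)
            pos[name] = anchor + (1_000 if target.startswith("m") else 2_000)
    return pos


def simulate_lrn_cascade(config: CascadeConfig) -> SyntheticDataset:
    """Simulate the full cohort for every gene under the config's template.

    Non-root node values are Σ(effect × standardized parent) + hidden-factor
    loadings + N(0, noise_sd²) noise, evaluated in topological order.
    Phenotype contexts are independent noise realizations of the same
    structural equation. Byte-identical for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"s{i+1}" for i in range(n)]
    F = rng.standard_normal((config.n_hidden_factors, n))

    template = nx.DiGraph()
    template.add_edges_from(config.true_dag_template)
    template_nodes = list(template.nodes)
    order = list(nx.topological_sort(template))

    geno_rows, geno_annot, geno_maf = [], [], []
    layer_rows = {"mrna": [], "dnam": [], "h3k9ac": []}
    layer_annot = {"mrna": [], "dnam": [], "h3k9ac": []}
    beta_rows = []
    pheno_rows = {}
    true_dag = nx.DiGraph()

    for gi in range(config.n_genes):
        gene = f"gene{gi+1}"
        layout = _gene_layout(gi, template_nodes)
        values = {}
        for name in order:
            cls = node_class(name)
            parents = list(template.predecessors(name))
            if cls == "g":
                maf = rng.uniform(*config.maf_range)
                dose = rng.binomial(2, maf, size=n).astype(float)
                values[name] = dose
                freq = dose.mean() / 2.0
                geno_rows.append(pd.Series(dose, index=samples, name=f"{gene}:{name}"))
                geno_annot.append(("1", layout[name]))
                geno_maf.append(min(freq, 1 - freq))
                continue
            if cls == "p":
                continue  # handled per phenotype context below
            signal = np.zeros(n)
            for par in parents:
                signal += config.effect(par, name) * _standardize(values[par], node_class(par))
            loadings = config.factor_strength * rng.standard_normal(config.n_hidden_factors)
            val = signal + loadings @ F + config.noise_sd * rng.standard_normal(n)
            values[name] = val
            layer = {"e": "mrna", "m": "dnam", "h": "h3k9ac"}[cls]
            fid = gene if cls == "e" else f"{gene}:{name}"
            layer_rows[layer].append(pd.Series(val, index=samples, name=fid))
            layer_annot[layer].append(("1", layout[name]))
            if cls == "m":
                beta = 1.0 / (1.0 + np.exp(-val))
                beta_rows.append(pd.Series(beta, index=samples, name=fid))
        # phenotype contexts: same parents, independent noise
        p_parents = [u for u in template_nodes if template.has_edge(u, "p")] if "p" in template else []
        for ctx in range(config.n_phenotypes):
            signal = np.zeros(n)
            for par in p_parents:
                signal += config.effect(par, "p") * _standardize(values[par], node_class(par))
            pheno_rows[(gene, ctx)] = signal + config.noise_sd * rng.standard_normal(n)
        for parent, child in template.edges:
            true_dag.add_edge(f"{gene}:{parent}", f"{gene}:{child}")
        for name in template_nodes:
            true_dag.add_node(f"{gene}:{name}")

    geno = GenotypeMatrix(
        dosages=pd.DataFrame(geno_rows),
        annotations=pd.DataFrame(
            geno_annot, columns=["chrom", "position"],
            index=pd.Index([s.name for s in geno_rows], name="snp"),
        ),
        maf=pd.Series(geno_maf, index=[s.name for s in geno_rows], name="maf"),
    )
    omics = {}
    for layer in ("mrna", "dnam", "h3k9ac"):
        if not layer_rows[layer]:
            continue
        vals = pd.DataFrame(layer_rows[layer])
        annot = pd.DataFrame(
            layer_annot[layer], columns=["chrom", "position"],
            index=pd.Index(vals.index, name="feature"),
        )
        annot["strand"] = "+"
        omics[layer] = OmicsMatrix(values=vals, annotations=annot, layer=layer)

    phenotypes = pd.DataFrame(
        {k: v for k, v in pheno_rows.items()}, index=samples
    ).T
    phenotypes.index = pd.MultiIndex.from_tuples(phenotypes.index, names=["gene", "context"])

    return SyntheticDataset(
        config=config,
        genotypes=geno,
        omics=omics,
        phenotypes=phenotypes,
        true_dag=true_dag,
        hidden_factors=F,
        dnam_beta=pd.DataFrame(beta_rows) if beta_rows else None,
    )


def true_relations(dataset) -> pd.DataFrame:
    """Derive upstream/downstream/independent labels from the true DAG.

    For every ordered pair of distinct nodes within each gene: `source` is
    upstream of `reference` iff a directed path source → … → reference
    exists, downstream iff the reverse path exists, independent otherwise.
    A pure function of the DAG.
    """
    dag = dataset.true_dag if hasattr(dataset, "true_dag") else dataset
    rows = []
    desc = {v: nx.descendants(dag, v) for v in dag.nodes}
    by_gene = {}
    for v in dag.nodes:
        gene = v.split(":", 1)[0] if ":" in v else ""
        by_gene.setdefault(gene, []).append(v)
    for gene, nodes in by_gene.items():
        for a in nodes:
            for b in nodes:
                if a == b:
                    continue
                if b in desc[a]:
                    label = "upstream"
                elif a in desc[b]:
                    label = "downstream"
                else:
                    label = "independent"
                rows.append((gene, a, b, label))
    return pd.DataFrame(rows, columns=["gene", "source", "reference", "label"])
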
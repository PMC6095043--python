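"""Node-set assembly rules and the allowed-parent mask menus."""

import numpy as np
import pandas as pd
import pytest

from lrnkit.nodes import (
    IneligibleGeneError,
    LrnNode,
    LrnNodeSet,
    allowed_parent_mask,
    build_node_set,
)


def _tables(gene="g1", marks=("pk1", "pk2"), mark_qtl=("pk1",), e_snp="rs_e"):
    """Minimal mapping tables: eQTM marks for `gene`, QTLs for a subset."""
    eqtm = pd.DataFrame({
        "gene": [gene] * len(marks),
        "peak": list(marks),
        "r": [-0.4] * len(marks),
        "significant": [True] * len(marks),
    })
    dnam_qtl = pd.DataFrame({
        "feature": list(marks),
        "variant": [f"rs_{p}" for p in marks],
        "nominal_p": [1e-6] * len(marks),
        "significant": [p in mark_qtl for p in marks],
    })
    mrna_qtl = pd.DataFrame({
        "feature": [gene],
        "variant": [e_snp],
        "nominal_p": [1e-8],
        "significant": [e_snp is not None],
    })
    return eqtm, dnam_qtl, mrna_qtl


@pytest.fixture
def values(rng):
    n = 120
    vals = {k: rng.standard_normal(n) for k in ["pk1", "pk2"]}
    geno = {k: rng.binomial(2, 0.3, n).astype(float)
            for k in ["rs_e", "rs_pk1", "rs_pk2"]}
    return {
        "expr": rng.standard_normal(n),
        "pheno": rng.standard_normal(n),
        "marks": vals,
        "geno": geno,
    }


class TestBuildNodeSet:
    def test_qtl_less_mark_excluded(self, values):
        eqtm, dnam_qtl, mrna_qtl = _tables()
        ns = build_node_set(
            "g1", values["expr"], values["pheno"], eqtm=eqtm,
            mrna_qtl=mrna_qtl, dnam_qtl=dnam_qtl,
            dnam_values=values["marks"], genotype_values=values["geno"])
        # pk1 has a QTL and enters as m1; pk2 (no QTL) is excluded
        assert "m1" in ns.names and "m2" not in ns.names
        assert ns.feature_map["m1"] == "pk1"
        klasses = [nd.klass for nd in ns.nodes]
        assert klasses.count("g") == 2  # rs_e and rs_pk1

    def test_no_snp_associated_marks_ineligible(self, values):
        eqtm, dnam_qtl, mrna_qtl = _tables(mark_qtl=())
        with pytest.raises(IneligibleGeneError):
            build_node_set("g1", values["expr"], values["pheno"], eqtm=eqtm,
                           mrna_qtl=mrna_qtl, dnam_qtl=dnam_qtl,
                           dnam_values=values["marks"],
                           genotype_values=values["geno"])

    def test_missing_eqtl_ineligible_unless_relaxed(self, values):
        eqtm, dnam_qtl, _ = _tables()
        mrna_qtl = pd.DataFrame({"feature": ["g1"], "variant": [None],
                                 "nominal_p": [0.5], "significant": [False]})
        with pytest.raises(IneligibleGeneError):
            build_node_set("g1", values["expr"], values["pheno"], eqtm=eqtm,
                           mrna_qtl=mrna_qtl, dnam_qtl=dnam_qtl,
                           dnam_values=values["marks"],
                           genotype_values=values["geno"])
        ns = build_node_set("g1", values["expr"], values["pheno"], eqtm=eqtm,
                            mrna_qtl=mrna_qtl, dnam_qtl=dnam_qtl,
                            dnam_values=values["marks"],
                            genotype_values=values["geno"],
                            require_eqtl=False)
        assert not any(nd.anchors == ("e",) for nd in ns.nodes if nd.klass == "g")

    def test_shared_best_snp_becomes_single_node(self, values):
        eqtm, dnam_qtl, mrna_qtl = _tables(e_snp="rs_pk1")
        ns = build_node_set("g1", values["expr"], values["pheno"], eqtm=eqtm,
                            mrna_qtl=mrna_qtl, dnam_qtl=dnam_qtl,
                            dnam_values=values["marks"],
                            genotype_values=values["geno"])
        snps = [nd for nd in ns.nodes if nd.klass == "g"]
        assert len(snps) == 1
        assert snps[0].anchors == ("e", "m1")

    def test_same_inputs_give_identical_ordering(self, values):
        eqtm, dnam_qtl, mrna_qtl = _tables()
        kw = dict(eqtm=eqtm, mrna_qtl=mrna_qtl, dnam_qtl=dnam_qtl,
                  dnam_values=values["marks"], genotype_values=values["geno"])
        a = build_node_set("g1", values["expr"], values["pheno"], **kw)
        b = build_node_set("g1", values["expr"], values["pheno"], **kw)
        assert a.names == b.names


class TestParentMask:
    def _node_set(self, rng):
        n = 80
        return LrnNodeSet(gene="t", nodes=[
            LrnNode("p", "p", rng.standard_normal(n)),
            LrnNode("e", "e", rng.standard_normal(n)),
            LrnNode("m1", "m", rng.standard_normal(n)),
            LrnNode("h1", "h", rng.standard_normal(n)),
            LrnNode("g_e", "g", rng.standard_normal(n), anchors=("e",)),
            LrnNode("g_m1", "g", rng.standard_normal(n), anchors=("m1",)),
            LrnNode("C_e", "C", rng.standard_normal(n), anchors=("e",)),
            LrnNode("C_m1", "C", rng.standard_normal(n), anchors=("m1",)),
        ])

    def test_snp_and_covariate_rows_all_false(self, rng):
        ns = self._node_set(rng)
        mask = allowed_parent_mask(ns)
        for name in ["g_e", "g_m1", "C_e", "C_m1"]:
            assert not mask.allowed[ns.index(name)].any()

    def test_parent_menus_exact(self, rng):
        ns = self._node_set(rng)
        mask = allowed_parent_mask(ns)
        names = ns.names

        def parents_of(child):
            row = mask.allowed[ns.index(child)]
            return {names[i] for i in np.where(row)[0]}

        assert parents_of("e") == {"g_e", "m1", "h1", "p", "C_e"}
        assert parents_of("m1") == {"g_m1", "e", "h1", "p", "C_m1"}
        assert parents_of("h1") == {"m1", "e", "p"}  # no g_h/C_h present
        assert parents_of("p") == {"g_e", "g_m1", "m1", "h1", "e"}

    def test_bidirectional_e_p_candidates(self, rng):
        ns = self._node_set(rng)
        mask = allowed_parent_mask(ns)
        assert mask.allowed[ns.index("e"), ns.index("p")]
        assert mask.allowed[ns.index("p"), ns.index("e")]

    def test_cross_layer_covariate_forbidden(self, rng):
        ns = self._node_set(rng)
        mask = allowed_parent_mask(ns)
        assert not mask.allowed[ns.index("m1"), ns.index("C_e")]
        assert not mask.allowed[ns.index("e"), ns.index("C_m1")]

    def test_anchor_snp_limited_to_its_variables_plus_phenotype(self, rng):
        ns = self._node_set(rng)
        mask = allowed_parent_mask(ns)
        ge = ns.index("g_e")
        allowed_children = {ns.names[i] for i in range(ns.n_nodes)
                            if mask.allowed[i, ge]}
        assert allowed_children == {"e", "p"}

    def test_no_self_edges(self, rng):
        mask = allowed_parent_mask(self._node_set(rng))
        assert not np.diag(mask.allowed).any()
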
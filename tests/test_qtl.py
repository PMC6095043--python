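"""Cis-window arithmetic, association tests, permutation p, FDR and π1."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lrnkit.qtl import (
    bh_fdr,
    best_snp_per_feature,
    define_cis_window,
    map_cis_qtl,
    map_eqtx,
    marginal_association,
    permutation_min_p,
    storey_pi1,
)
from lrnkit.synthetic import GenotypeMatrix, OmicsMatrix


class TestCisWindow:
    def test_gene_window_50kb(self):
        w = define_cis_window("geneA", 50_000, position=100_000, chrom="1")
        assert (w.start, w.end) == (50_000, 150_000)

    def test_left_truncation_at_one(self):
        w = define_cis_window("m1", 5_000, position=3_000, chrom="2")
        assert (w.start, w.end) == (1, 8_000)

    def test_megabase_window(self):
        w = define_cis_window("g", 1_000_000, position=2_500_000, chrom="1")
        assert (w.start, w.end) == (1_500_000, 3_500_000)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            define_cis_window("x", 0, position=100, chrom="1")

    def test_contains_is_inclusive(self):
        w = define_cis_window("x", 10, position=100, chrom="1")
        assert w.contains("1", 90) and w.contains("1", 110)
        assert not w.contains("1", 111)
        assert not w.contains("2", 100)


class TestMarginalAssociation:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = marginal_association(x, x)
        assert res["beta"] == pytest.approx(1.0)
        assert res["p"] < 1e-20

    def test_orthogonal_vectors_zero_slope(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert marginal_association(y, x)["beta"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal(100)
        y = 0.3 * x + rng.standard_normal(100)
        res = marginal_association(y, x)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res["beta"] == pytest.approx(fit.params[1], abs=1e-10)
        assert res["p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_constant_x_rejected(self, rng):
        with pytest.raises(ValueError):
            marginal_association(rng.standard_normal(10), np.ones(10))


class TestPermutationMinP:
    def test_floor_for_perfect_association(self, rng):
        y = rng.standard_normal(60)
        X = np.vstack([y, rng.standard_normal((3, 60))])
        res = permutation_min_p(y, X, n_perm=500, seed=0)
        assert res["empirical_p"] == pytest.approx(1 / 501)
        assert res["best_index"] == 0

    def test_single_candidate_matches_bruteforce_rank(self, rng):
        n = 50
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        seed = 42
        res = permutation_min_p(y, x[None, :], n_perm=1000, seed=seed)
        # independent brute force with the same permutation stream
        rng2 = np.random.default_rng(seed)
        ys = (y - y.mean()) / y.std()
        xs = (x - x.mean()) / x.std()
        obs = abs(np.dot(xs, ys) / n)
        perm_idx = np.argsort(rng2.random((1000, n)), axis=1)
        null = np.array([abs(np.dot(xs, ys[idx]) / n) for idx in perm_idx])
        expect = (1 + np.sum(null >= obs - 1e-12)) / 1001
        assert res["empirical_p"] == pytest.approx(expect)

    def test_null_p_is_approximately_uniform(self, rng):
        n = 40
        ps = []
        for _ in range(200):
            y = rng.standard_normal(n)
            X = rng.standard_normal((4, n))
            ps.append(permutation_min_p(y, X, n_perm=199,
                                        seed=int(rng.integers(2**31)))["empirical_p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_min_p(rng.standard_normal(10),
                              rng.standard_normal((2, 10)), n_perm=10)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_textbook_step_up_on_random_pvalues(self, rng):
        p = rng.uniform(size=1000)
        # independent step-up implementation
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            q[i] = prev
        assert np.allclose(bh_fdr(p), q, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestStoreyPi1:
    def test_uniform_null_near_zero(self, rng):
        res = storey_pi1(rng.uniform(size=10_000))
        assert 0 <= res["pi1"] < 0.05

    def test_mixture_recovers_signal_fraction(self, rng):
        p = np.concatenate([rng.uniform(0, 1e-4, 3000), rng.uniform(0, 1, 7000)])
        res = storey_pi1(p)
        assert res["pi1"] == pytest.approx(0.30, abs=0.05)

    def test_saturated_alternative(self):
        res = storey_pi1(np.full(500, 1e-8))
        assert res["pi1"] == pytest.approx(1.0)


def _toy_mapping_inputs(rng, n_features=8, n_samples=80, signal=(), snps_per=3):
    samples = [f"s{i}" for i in range(n_samples)]
    geno_rows, gannot, feats, fannot = [], [], [], []
    for f in range(n_features):
        center = 100_000 + f * 400_000
        dos = rng.binomial(2, 0.3, size=(snps_per, n_samples)).astype(float)
        y = rng.standard_normal(n_samples)
        if f in signal:
            y = 0.8 * (dos[0] - dos[0].mean()) / dos[0].std() \
                + 0.6 * rng.standard_normal(n_samples)
        for s in range(snps_per):
            geno_rows.append(pd.Series(dos[s], index=samples, name=f"f{f}s{s}"))
            gannot.append(("1", center - 10_000 + 10_000 * s))
        feats.append(pd.Series(y, index=samples, name=f"feat{f}"))
        fannot.append(("1", center))
    geno = GenotypeMatrix(
        dosages=pd.DataFrame(geno_rows),
        annotations=pd.DataFrame(gannot, columns=["chrom", "position"],
                                 index=[r.name for r in geno_rows]),
        maf=pd.Series(dtype=float))
    om = OmicsMatrix(
        values=pd.DataFrame(feats),
        annotations=pd.DataFrame(fannot, columns=["chrom", "position"],
                                 index=[r.name for r in feats]).assign(strand="+"),
        layer="toy")
    return om, geno


class TestMapCisQtl:
    def test_signal_features_found_null_not(self, rng):
        om, geno = _toy_mapping_inputs(rng, signal=(0, 1))
        res = map_cis_qtl(om, geno, w=50_000, n_perm=300, seed=1)
        sig = set(res[res["significant"]]["feature"])
        assert {"feat0", "feat1"} <= sig
        assert len(sig) <= 4

    def test_window_excludes_distant_snps(self, rng):
        om, geno = _toy_mapping_inputs(rng)
        res = map_cis_qtl(om, geno, w=5_000, n_perm=300, seed=2)
        # only the SNP exactly at each feature center is within 5 kb
        assert (res["n_tested"] <= 1).all()

    def test_feature_without_candidates_reported_not_dropped(self, rng):
        om, geno = _toy_mapping_inputs(rng)
        far = om.annotations.copy()
        far.loc["feat0", "position"] = 99_000_000
        om2 = OmicsMatrix(values=om.values, annotations=far, layer="toy")
        res = map_cis_qtl(om2, geno, w=50_000, n_perm=300, seed=3)
        row = res[res["feature"] == "feat0"].iloc[0]
        assert row["n_tested"] == 0 and np.isnan(row["perm_p"])

    def test_insufficient_shared_samples_rejected(self, rng):
        om, geno = _toy_mapping_inputs(rng, n_samples=10)
        with pytest.raises(ValueError):
            map_cis_qtl(om, geno, min_samples=30)


class TestMapEqtx:
    def test_true_pair_significant_with_correct_sign(self, rng):
        n = 120
        samples = [f"s{i}" for i in range(n)]
        m = rng.standard_normal(n)
        e = -0.8 * m + 0.5 * rng.standard_normal(n)
        expr = OmicsMatrix(
            values=pd.DataFrame([pd.Series(e, index=samples, name="gene1")]),
            annotations=pd.DataFrame({"chrom": ["1"], "position": [1_000_000],
                                      "strand": ["+"]}, index=["gene1"]),
            layer="mrna")
        marks = OmicsMatrix(
            values=pd.DataFrame([
                pd.Series(m, index=samples, name="peak1"),
                pd.Series(rng.standard_normal(n), index=samples, name="peak2")]),
            annotations=pd.DataFrame({"chrom": ["1", "1"],
                                      "position": [1_200_000, 900_000],
                                      "strand": ["+", "+"]},
                                     index=["peak1", "peak2"]),
            layer="dnam")
        res = map_eqtx(expr, marks, n_perm=300, seed=4)
        hit = res[(res["gene"] == "gene1") & (res["peak"] == "peak1")].iloc[0]
        assert hit["significant"]
        assert hit["r"] < 0

    def test_distant_peak_never_tested(self, rng):
        n = 60
        samples = [f"s{i}" for i in range(n)]
        expr = OmicsMatrix(
            values=pd.DataFrame([pd.Series(rng.standard_normal(n),
                                           index=samples, name="gene1")]),
            annotations=pd.DataFrame({"chrom": ["1"], "position": [1_000_000],
                                      "strand": ["+"]}, index=["gene1"]),
            layer="mrna")
        marks = OmicsMatrix(
            values=pd.DataFrame([pd.Series(rng.standard_normal(n),
                                           index=samples, name="far")]),
            annotations=pd.DataFrame({"chrom": ["1"], "position": [2_200_000],
                                      "strand": ["+"]}, index=["far"]),
            layer="dnam")
        res = map_eqtx(expr, marks, n_perm=300, seed=5)
        assert res.empty or "far" not in set(res["peak"])


class TestBestSnp:
    def test_best_and_absent(self):
        res = pd.DataFrame({
            "feature": ["a", "b"],
            "variant": ["snp1", "snp9"],
            "nominal_p": [0.001, 0.5],
            "significant": [True, False],
        })
        best = best_snp_per_feature(res)
        assert best == {"a": "snp1"}

    def test_tie_broken_by_position_in_mapping(self, rng):
        # two identical SNP columns: the lower-coordinate one must win
        n = 60
        samples = [f"s{i}" for i in range(n)]
        dose = rng.binomial(2, 0.4, n).astype(float)
        y = 0.9 * dose + 0.3 * rng.standard_normal(n)
        geno = GenotypeMatrix(
            dosages=pd.DataFrame([
                pd.Series(dose, index=samples, name="snpB"),
                pd.Series(dose, index=samples, name="snpA")]),
            annotations=pd.DataFrame({"chrom": ["1", "1"],
                                      "position": [150_000, 120_000]},
                                     index=["snpB", "snpA"]),
            maf=pd.Series(dtype=float))
        om = OmicsMatrix(
            values=pd.DataFrame([pd.Series(y, index=samples, name="feat")]),
            annotations=pd.DataFrame({"chrom": ["1"], "position": [130_000],
                                      "strand": ["+"]}, index=["feat"]),
            layer="toy")
        res = map_cis_qtl(om, geno, w=50_000, n_perm=200, seed=6)
        assert res.iloc[0]["variant"] == "snpA"
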
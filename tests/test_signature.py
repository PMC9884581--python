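import numpy as np
import pandas as pd
import pytest

from tcrtrace.clonotypes import Clonotype, make_key
from tcrtrace.io import ExpressionMatrix, normalize
from tcrtrace.signature import (
    GeneSignature,
    clonotype_score,
    derive_signature,
    gene_zscores,
    random_signature,
    rank_sum_de,
    read_signature,
    score_timecourse,
    signature_set_expression,
    write_signature,
)


def _expr(counts, genes=None, barcodes=None, normalized=True):
    counts = np.asarray(counts)
    g, c = counts.shape
    expr = ExpressionMatrix(
        genes=genes or [f"G{i}" for i in range(g)],
        barcodes=barcodes or [f"b{i}" for i in range(c)],
        counts=counts,
    )
    return normalize(expr) if normalized else expr


def _random_expr(rng, g=30, c=40):
    counts = rng.integers(0, 12, size=(g, c))
    counts[0] += 1  # no zero-total cell
    return _expr(counts)


class TestRankSumDE:
    def test_identical_gene_is_null(self):
        # constant matrix → every gene identical across groups after
        # normalization: lfc 0 and p in the no-evidence region
        counts = np.vstack([np.full(20, 5), np.full(20, 2), np.full(20, 7)])
        expr = _expr(counts)
        de = rank_sum_de(expr, [f"b{i}" for i in range(10)],
                         [f"b{i}" for i in range(10, 20)])
        assert abs(de.loc["G0", "lfc"]) < 1e-12
        assert de.loc["G0", "p"] == 1.0

    def test_group1_only_gene_positive_lfc(self):
        counts = np.ones((2, 12), dtype=int)
        counts[1, :6] = 8
        counts[1, 6:] = 0
        expr = _expr(counts)
        de = rank_sum_de(expr, [f"b{i}" for i in range(6)],
                         [f"b{i}" for i in range(6, 12)])
        assert de.loc["G1", "lfc"] > 0
        assert de.loc["G1", "pct_expr_2"] == 0.0

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        expr = _random_expr(rng, g=25, c=30)
        g1 = [f"b{i}" for i in range(15)]
        g2 = [f"b{i}" for i in range(15, 30)]
        fwd = rank_sum_de(expr, g1, g2)
        rev = rank_sum_de(expr, g2, g1)
        assert np.allclose(fwd["lfc"], -rev["lfc"], atol=1e-12)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)
        assert np.allclose(fwd["p_adj"], np.minimum(1.0, fwd["p"] * len(fwd)))

    def test_overlap_and_small_groups_rejected(self):
        rng = np.random.default_rng(2)
        expr = _random_expr(rng)
        with pytest.raises(ValueError, match="overlap"):
            rank_sum_de(expr, ["b0", "b1", "b2"], ["b2", "b3", "b4"])
        with pytest.raises(ValueError, match="3 cells"):
            rank_sum_de(expr, ["b0", "b1"], ["b2", "b3", "b4"])

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(3)
        g, n = 200, 150
        base = rng.lognormal(0.5, 0.5, size=g)
        mu = np.tile(base[:, None], (1, 2 * n))
        mu[:20, :n] *= 4.0  # 4-fold shift on 20 genes in group1
        counts = rng.poisson(mu)
        counts[20] += 1
        expr = _expr(counts, barcodes=[f"b{i}" for i in range(2 * n)])
        de = rank_sum_de(expr, [f"b{i}" for i in range(n)],
                         [f"b{i}" for i in range(n, 2 * n)])
        hits = de.index[(de["p_adj"] < 0.05) & (de["lfc"] > 0.5)]
        planted = {f"G{i}" for i in range(20)}
        assert len(planted & set(hits)) >= 18


class TestDeriveSignature:
    def _de(self, entries):
        df = pd.DataFrame(entries).set_index("gene")
        df["p"] = df.get("p", pd.Series(1e-8, index=df.index))
        if "p_adj" not in df:
            df["p_adj"] = 1e-6
        return df

    def test_antilog_weight(self):
        pre = self._de([{"gene": "TCF7", "lfc": 1.0}])
        post = self._de([{"gene": "TCF7", "lfc": 1.0}])
        sig = derive_signature(pre, post)
        assert sig.genes == ["TCF7"]
        assert sig.weights[0] == pytest.approx(2.0)

    def test_below_threshold_at_one_timepoint_excluded(self):
        pre = self._de([{"gene": "A", "lfc": 0.30}, {"gene": "B", "lfc": 0.9}])
        post = self._de([{"gene": "A", "lfc": 0.20}, {"gene": "B", "lfc": 0.8}])
        sig = derive_signature(pre, post)
        assert sig.genes == ["B"]

    def test_ribosomal_prefix_excluded(self):
        pre = self._de([{"gene": "RPL13", "lfc": 1.5}, {"gene": "IL7R", "lfc": 1.5}])
        post = self._de([{"gene": "RPL13", "lfc": 1.5}, {"gene": "IL7R", "lfc": 1.5}])
        sig = derive_signature(pre, post)
        assert sig.genes == ["IL7R"]

    def test_insignificant_gene_excluded(self):
        pre = self._de([{"gene": "A", "lfc": 0.9, "p_adj": 0.9},
                        {"gene": "B", "lfc": 0.9, "p_adj": 1e-9}])
        post = self._de([{"gene": "A", "lfc": 0.9, "p_adj": 1e-9},
                         {"gene": "B", "lfc": 0.9, "p_adj": 1e-9}])
        assert derive_signature(pre, post).genes == ["B"]

    def test_empty_intersection_advises(self):
        pre = self._de([{"gene": "A", "lfc": 0.1}])
        post = self._de([{"gene": "A", "lfc": 0.1}])
        with pytest.raises(ValueError, match="threshold"):
            derive_signature(pre, post)

    def test_weight_monotone_in_average_lfc(self):
        pre = self._de([{"gene": f"g{i}", "lfc": 0.3 + 0.1 * i} for i in range(5)])
        post = self._de([{"gene": f"g{i}", "lfc": 0.3 + 0.1 * i} for i in range(5)])
        sig = derive_signature(pre, post)
        order = [sig.genes.index(f"g{i}") for i in range(5)]
        assert np.all(np.diff(sig.weights[order]) > 0)


class TestGeneZScores:
    def test_two_cell_closed_form(self):
        # lognorm values μ±σ → z = ±1
        expr = _expr(np.array([[2, 8], [5, 5]]), normalized=True)
        z = gene_zscores(expr, ["G0"])
        assert np.allclose(sorted(z.loc["G0"]), [-1.0, 1.0])

    def test_constant_gene_zero(self):
        expr = _expr(np.array([[3, 3, 3], [1, 1, 1]]))
        z = gene_zscores(expr, ["G0", "G1"])
        assert np.allclose(z, 0.0)

    def test_matches_loop_oracle_and_standardization(self):
        rng = np.random.default_rng(4)
        expr = _random_expr(rng, g=20, c=30)
        genes = [f"G{i}" for i in range(20)]
        z = gene_zscores(expr, genes)
        dense = expr.lognorm.toarray()
        for gi in range(20):
            mu, sd = dense[gi].mean(), dense[gi].std()
            if sd > 0:
                assert np.abs(z.iloc[gi] - (dense[gi] - mu) / sd).max() < 1e-12
                assert abs(z.iloc[gi].mean()) < 1e-10
                assert abs(z.iloc[gi].std(ddof=0) - 1) < 1e-10

    def test_missing_gene_named(self):
        expr = _expr(np.array([[1, 2]]))
        with pytest.raises(KeyError, match="NOPE"):
            gene_zscores(expr, ["NOPE"])


class TestClonotypeScore:
    def _z(self):
        return pd.DataFrame([[1.0, 0.0], [-1.0, 0.0]], index=["g1", "g2"],
                            columns=["c1", "c2"])

    def test_worked_example(self):
        sig = GeneSignature(["g1", "g2"], np.array([2.0, 1.0]))
        assert clonotype_score(["c1", "c2"], self._z(), sig) == pytest.approx(0.5)

    def test_linearity_in_weights(self):
        z = self._z()
        s1 = clonotype_score(["c1", "c2"], z, GeneSignature(["g1", "g2"], np.array([2.0, 1.0])))
        s2 = clonotype_score(["c1", "c2"], z, GeneSignature(["g1", "g2"], np.array([4.0, 2.0])))
        assert s2 == pytest.approx(2 * s1)

    def test_gene_and_cell_order_invariance(self):
        z = self._z()
        a = clonotype_score(["c1", "c2"], z, GeneSignature(["g1", "g2"], np.array([2.0, 1.0])))
        b = clonotype_score(["c2", "c1"], z, GeneSignature(["g2", "g1"], np.array([1.0, 2.0])))
        assert a == pytest.approx(b)

    def test_no_member_cell_rejected(self):
        with pytest.raises(ValueError):
            clonotype_score(["zzz"], self._z(), GeneSignature(["g1"], np.array([1.0])))


class TestScoreTimecourse:
    def test_single_increasing_clonotype(self):
        z_pre = pd.DataFrame([[0.0, 0.0]], index=["g1"], columns=["p1", "p2"])
        z_post = pd.DataFrame([[1.0, 1.0]], index=["g1"], columns=["q1", "q2"])
        ct = Clonotype(key=make_key(None, "CASSF"), alpha_cdr3=None, beta_cdr3="CASSF",
                       members={("P01", "pre", "blood"): ["p1", "p2"],
                                ("P01", "post", "blood"): ["q1", "q2"]})
        sig = GeneSignature(["g1"], np.array([1.0]))
        res = score_timecourse([ct], [], z_pre, z_post, sig)
        assert res.fraction_increasing == 1.0
        assert res.records[0].delta == pytest.approx(1.0)

    def test_min_cells_filter(self):
        z_pre = pd.DataFrame([[0.0]], index=["g1"], columns=["p1"])
        z_post = pd.DataFrame(index=["g1"], columns=[], dtype=float)
        ct = Clonotype(key=make_key(None, "CASSF"), alpha_cdr3=None, beta_cdr3="CASSF",
                       members={("P01", "pre", "blood"): ["p1"]})
        sig = GeneSignature(["g1"], np.array([1.0]))
        with pytest.raises(ValueError):
            score_timecourse([ct], [], z_pre, z_post, sig, min_cells=2)


class TestRandomSignature:
    def test_deterministic_under_seed(self, small_cohort_normalized):
        expr, _, _ = small_cohort_normalized
        a = random_signature(expr, 15, seed=5)
        b = random_signature(expr, 15, seed=5)
        assert a.genes == b.genes
        assert a.provenance == "random" and np.all(a.weights == 1.0)

    def test_full_gene_set_is_permutation(self, small_cohort_normalized):
        expr, _, _ = small_cohort_normalized
        detected = expr.genes[np.asarray(expr.counts.sum(axis=1)).ravel() > 0]
        sig = random_signature(expr, len(detected), seed=1)
        assert sorted(sig.genes) == sorted(str(g) for g in detected)

    def test_too_many_genes_rejected(self, small_cohort_normalized):
        expr, _, _ = small_cohort_normalized
        with pytest.raises(ValueError):
            random_signature(expr, len(expr.genes) + 1, seed=0)


class TestSignatureSetExpression:
    def test_single_gene_equals_lognorm(self):
        rng = np.random.default_rng(8)
        expr = _random_expr(rng, g=10, c=12)
        vals = signature_set_expression(expr, ["b0", "b3"], ["G4"])
        dense = expr.lognorm.toarray()
        assert vals["b0"] == pytest.approx(dense[4, 0])
        assert vals["b3"] == pytest.approx(dense[4, 3])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        expr = _random_expr(rng, g=15, c=10)
        genes = ["G1", "G5", "G9"]
        vals = signature_set_expression(expr, list(expr.barcodes), genes)
        dense = expr.lognorm.toarray()
        idx = [1, 5, 9]
        for ci, b in enumerate(expr.barcodes):
            assert vals[b] == pytest.approx(sum(dense[gi, ci] for gi in idx), abs=1e-12)

    def test_empty_gene_set_rejected(self):
        rng = np.random.default_rng(10)
        expr = _random_expr(rng)
        with pytest.raises(ValueError):
            signature_set_expression(expr, ["b0"], [])


def test_signature_file_round_trip(tmp_path):
    sig = GeneSignature(["TCF7", "IL7R"], np.array([2.0, 1.5]),
                        provenance="derived", antilog_base=2.0)
    write_signature(sig, tmp_path / "sig.tsv")
    back = read_signature(tmp_path / "sig.tsv")
    assert back.genes == sig.genes
    assert np.allclose(back.weights, sig.weights)
    assert back.provenance == "derived" and back.antilog_base == 2.0
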
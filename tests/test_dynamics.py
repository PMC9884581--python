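import numpy as np
import pytest

from tcrtrace.clonotypes import Clonotype, make_key
from tcrtrace.dynamics import (
    classify_dynamics,
    compare_groups,
    flux_table,
    ne_rate,
)


def _toy(pre_counts, post_counts, patient="P01"):
    """Build clonotypes from {name: count} dicts for pre and post."""
    names = sorted(set(pre_counts) | set(post_counts))
    out = {}
    for i, name in enumerate(names):
        beta = "CASS" + "".join("ACDEFGHIKL"[int(d)] for d in str(i).zfill(3)) + "F"
        members = {}
        if pre_counts.get(name, 0):
            members[(patient, "pre", "blood")] = [f"{name}-pre-{j}"
                                                  for j in range(pre_counts[name])]
        if post_counts.get(name, 0):
            members[(patient, "post", "blood")] = [f"{name}-post-{j}"
                                                   for j in range(post_counts[name])]
        out[name] = Clonotype(key=make_key(None, beta), alpha_cdr3=None,
                              beta_cdr3=beta, members=members)
    return out


class TestClassifyDynamics:
    def test_worked_example(self):
        cts = _toy({"A": 3, "B": 1}, {"A": 5, "B": 1, "C": 4})
        recs = {r.key: r for r in classify_dynamics(list(cts.values()),
                                                    list(cts.values()), "P01")}
        a, b, c = recs[cts["A"].key], recs[cts["B"].key], recs[cts["C"].key]
        # A: post_freq 0.5 < pre_freq 0.75 → static comparator
        assert not a.treatment_expanded and a.baseline_expanded_static
        # C: novel expanded
        assert c.treatment_expanded and c.origin == "novel"
        assert not b.treatment_expanded and b.origin == "pre_existing"

    def test_equal_frequency_does_not_qualify(self):
        cts = _toy({"A": 1}, {"A": 4})
        (rec,) = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        assert rec.pre_freq == 1.0 and rec.post_freq == 1.0
        assert not rec.treatment_expanded
        cts2 = _toy({"A": 1, "B": 1}, {"A": 4})
        recs = {r.key: r for r in classify_dynamics(list(cts2.values()),
                                                    list(cts2.values()), "P01")}
        assert recs[cts2["A"].key].treatment_expanded
        assert recs[cts2["A"].key].origin == "pre_existing"

    def test_absent_post_never_expanded(self):
        cts = _toy({"A": 30}, {"B": 5})
        recs = {r.key: r for r in classify_dynamics(list(cts.values()),
                                                    list(cts.values()), "P01")}
        a = recs[cts["A"].key]
        assert a.post_count == 0 and not a.treatment_expanded
        assert a.baseline_expanded_static

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        pre = {f"c{i}": int(rng.integers(1, 9)) for i in range(25)}
        post = {f"c{i}": int(rng.integers(0, 9)) for i in range(35)}
        post = {k: v for k, v in post.items() if v}
        cts = _toy(pre, post)
        vals = list(cts.values())
        r1 = classify_dynamics(vals, vals, "P01")
        r2 = classify_dynamics(vals[::-1], vals[::-1], "P01")
        assert [vars(r) for r in r1] == [vars(r) for r in r2]

    def test_origin_partition(self):
        rng = np.random.default_rng(2)
        pre = {f"c{i}": int(rng.integers(1, 6)) for i in range(30)}
        post = {f"c{i}": int(rng.integers(1, 12)) for i in range(10, 50)}
        cts = _toy(pre, post)
        recs = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        for r in recs:
            if r.treatment_expanded:
                assert (r.origin == "novel") == (r.pre_count == 0)
            assert r.pre_freq == pytest.approx(r.pre_count / sum(pre.values()))

    def test_zero_cell_sample_rejected(self):
        cts = _toy({"A": 2}, {})
        with pytest.raises(ValueError, match="zero-cell"):
            classify_dynamics(list(cts.values()), list(cts.values()), "P01")

    def test_single_chain_fallback_prevents_false_novelty(self):
        # pre clonotype is β-only; the paired post clonotype matches it
        pre_ct = Clonotype(key=make_key(None, "CASSF"), alpha_cdr3=None,
                           beta_cdr3="CASSF",
                           members={("P01", "pre", "blood"): ["p1", "p2"]})
        post_ct = Clonotype(key=make_key("CAVRF", "CASSF"), alpha_cdr3="CAVRF",
                            beta_cdr3="CASSF",
                            members={("P01", "post", "blood"): ["q1", "q2", "q3"]})
        filler = Clonotype(key=make_key(None, "CATTF"), alpha_cdr3=None,
                           beta_cdr3="CATTF",
                           members={("P01", "pre", "blood"): ["r1", "r2"],
                                    ("P01", "post", "blood"): ["r3"]})
        recs = {r.key: r for r in classify_dynamics([pre_ct, filler],
                                                    [post_ct, filler], "P01")}
        assert recs[post_ct.key].origin == "pre_existing"
        assert recs[post_ct.key].pre_count == 2


class TestFluxTable:
    def _clusters(self, cts):
        clusters = {}
        for ct in cts:
            for (pat, tp, comp), bcs in ct.members.items():
                for b in bcs:
                    clusters[b] = None
        return clusters

    def test_single_transition(self):
        cts = _toy({"A": 2, "B": 8}, {"A": 6, "B": 4})
        recs = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        clusters = {b: "Eff-GZMK" for b in cts["A"].members[("P01", "pre", "blood")]}
        clusters |= {b: "Cycling-MKI67" for b in cts["A"].members[("P01", "post", "blood")]}
        table = flux_table(recs, list(cts.values()), clusters)
        assert table.loc["Eff-GZMK", "Cycling-MKI67"] == 1
        assert table.to_numpy().sum() == 1

    def test_incidence_vs_modal_totals(self):
        cts = _toy({"A": 4, "B": 9}, {"A": 9, "B": 4})
        recs = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        pre_a = cts["A"].members[("P01", "pre", "blood")]
        post_a = cts["A"].members[("P01", "post", "blood")]
        clusters = {pre_a[0]: "X", pre_a[1]: "X", pre_a[2]: "Y", pre_a[3]: "Y"}
        clusters |= {b: "Z" for b in post_a}
        inc = flux_table(recs, list(cts.values()), clusters, mode="incidence")
        mod = flux_table(recs, list(cts.values()), clusters, mode="modal")
        assert inc.to_numpy().sum() == 2
        assert mod.to_numpy().sum() == 1
        assert mod.loc["X", "Z"] == 1  # tie X/Y broken lexicographically

    def test_incidence_matches_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        pre = {f"c{i}": int(rng.integers(1, 6)) for i in range(20)}
        post = {f"c{i}": int(rng.integers(2, 9)) for i in range(20)}
        cts = _toy(pre, post)
        labels = ["c1", "c2", "c3"]
        clusters = {}
        for ct in cts.values():
            for bcs in ct.members.values():
                for b in bcs:
                    clusters[b] = labels[rng.integers(3)]
        recs = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        table = flux_table(recs, list(cts.values()), clusters, mode="incidence")
        expected = {}
        for r in recs:
            if not (r.treatment_expanded and r.pre_count >= 1):
                continue
            ct = next(c for c in cts.values() if c.key == r.key)
            pre_cl = {clusters[b] for b in ct.members[("P01", "pre", "blood")]}
            post_cl = {clusters[b] for b in ct.members[("P01", "post", "blood")]}
            for c1 in pre_cl:
                for c2 in post_cl:
                    expected[(c1, c2)] = expected.get((c1, c2), 0) + 1
        for (c1, c2), v in expected.items():
            assert table.loc[c1, c2] == v
        assert table.to_numpy().sum() == sum(expected.values())

    def test_modal_row_sums_equal_expanded_with_pre_cells(self):
        rng = np.random.default_rng(13)
        pre = {f"c{i}": int(rng.integers(1, 5)) for i in range(30)}
        post = {f"c{i}": int(rng.integers(2, 10)) for i in range(30)}
        cts = _toy(pre, post)
        clusters = {}
        for ct in cts.values():
            for bcs in ct.members.values():
                for b in bcs:
                    clusters[b] = str(rng.choice(["u", "v"]))
        recs = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        table = flux_table(recs, list(cts.values()), clusters, mode="modal")
        n_exp = sum(1 for r in recs if r.treatment_expanded and r.pre_count >= 1)
        assert table.to_numpy().sum() == n_exp

    def test_missing_cluster_label_names_barcode(self):
        cts = _toy({"A": 2, "C": 8}, {"A": 5, "B": 2, "C": 3})
        recs = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        assert any(r.treatment_expanded and r.pre_count >= 1 for r in recs)
        clusters = self._clusters(cts.values())
        with pytest.raises(ValueError, match="A-pre-0"):
            flux_table(recs, list(cts.values()), clusters)


class TestNERate:
    def test_simple_rates(self):
        cts = _toy({f"p{i}": 1 for i in range(98)},
                   {f"p{i}": 1 for i in range(98)} | {"n1": 3, "n2": 4})
        recs = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        assert ne_rate(recs) == pytest.approx(2 / 100)
        assert ne_rate(recs, "expanded_clonotypes") == pytest.approx(1.0)

    def test_no_novelty_gives_zero(self):
        cts = _toy({"A": 5, "B": 5}, {"A": 7, "B": 3})
        recs = classify_dynamics(list(cts.values()), list(cts.values()), "P01")
        assert ne_rate(recs) == 0.0

    def test_planted_fraction_recovered(self):
        from tcrtrace.clonotypes import call_clonotypes
        from tcrtrace.simulate import SimConfig, simulate_cohort

        cfg = SimConfig(n_patients=1, cells_pre_blood=2000, cells_post_blood=2000,
                        cells_tumor=0, frac_ne=0.05, seed=77)
        co = simulate_cohort(cfg, with_expression=False)
        clonos = call_clonotypes(co.chains, co.cells)
        recs = classify_dynamics(clonos, clonos, "P01")
        n_ne_truth = sum(1 for c in co.clones if c.cls == "NE")
        rate = ne_rate(recs, "post_clonotypes")
        n_post = sum(1 for r in recs if r.post_count > 0)
        assert rate == pytest.approx(n_ne_truth / n_post)


class TestCompareGroups:
    def test_identical_groups_high_p(self):
        u, p = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_exact_three_vs_three(self):
        u, p = compare_groups([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        n_rep = 10_000
        rej = 0
        for _ in range(n_rep):
            _, p = compare_groups(rng.normal(size=15), rng.normal(size=15))
            rej += p < 0.05
        assert 0.04 <= rej / n_rep <= 0.06
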
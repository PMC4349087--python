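"""NJ trees, clade calling, fixed differences, and Dxy against oracles."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from polydiv.clades import (
    CladePartition,
    bootstrap_support,
    call_clades,
    clade_summary,
    distance_matrix,
    dxy,
    dxy_table,
    fixed_differences,
    nj_tree,
    tree_bipartitions,
)
from polydiv.simulate import BalancedConfig, simulate_balanced_locus

from conftest import make_alignment


class TestNJTree:
    def test_additive_distances_recover_tree(self):
        # tree: ((a:1,b:2):1,c:3,d:4) -> additive distance matrix
        d = {
            ("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
            ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7,
        }
        ids = ["a", "b", "c", "d"]
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = nj_tree(DistanceMatrix(mat, ids))
        # topology: {a,b} | {c,d}
        splits = tree_bipartitions(tree, set(ids))
        assert frozenset({"c", "d"}) in splits or frozenset({"b", "a"}) in splits
        # additive distances are reproduced exactly as patristic distances
        for (x, y), v in d.items():
            tx = tree.find(x)
            assert tx.distance(tree.find(y)) == pytest.approx(v)

    def test_three_taxa_solves_three_point_equations(self):
        mat = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        ids = ["a", "b", "c"]
        tree = nj_tree(DistanceMatrix(mat, ids))
        # branch lengths: la = (dab+dac-dbc)/2 = 1, lb = 3, lc = 5
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1)
        assert lengths["b"] == pytest.approx(3)
        assert lengths["c"] == pytest.approx(5)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))

    def test_taxon_order_invariance(self):
        alns, _ = simulate_balanced_locus(BalancedConfig(seed=2))
        aln = alns["sp1"]
        dm1 = distance_matrix(aln.ingroup_seqs, aln.ingroup_ids)
        order = list(reversed(range(aln.n)))
        dm2 = distance_matrix(
            [aln.ingroup_seqs[i] for i in order], [aln.ingroup_ids[i] for i in order]
        )
        s1 = tree_bipartitions(nj_tree(dm1), set(aln.ingroup_ids))
        s2 = tree_bipartitions(nj_tree(dm2), set(aln.ingroup_ids))
        assert s1 == s2


class TestDxy:
    def test_single_pair_two_of_hundred(self):
        g1 = ["A" * 100]
        g2 = ["T" * 2 + "A" * 98]
        assert dxy(g1, g2) == pytest.approx(0.02)

    def test_identical_groups_zero(self):
        g = ["ACGT" * 10] * 3
        assert dxy(g, g) == 0.0

    def test_three_by_three_brute_force(self):
        rng = np.random.default_rng(17)
        g1 = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(3)]
        g2 = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(3)]
        expected = np.mean(
            [sum(a != b for a, b in zip(s1, s2)) / 50 for s1 in g1 for s2 in g2]
        )
        assert dxy(g1, g2) == pytest.approx(expected)

    def test_dxy_table_self_is_within_group_pi(self):
        g = {"A": ["AAAA", "AAAT"], "B": ["TTTT", "TTTT"]}
        tab = dxy_table(g)
        self_a = tab[(tab.group1 == "A") & (tab.group2 == "A")]["dxy"].iloc[0]
        assert self_a == pytest.approx(0.25)
        self_b = tab[(tab.group1 == "B") & (tab.group2 == "B")]["dxy"].iloc[0]
        assert self_b == 0.0


class TestFixedDifferences:
    def _partition(self, n_a, n_b):
        assignments = {f"a{i:02d}": ("A" if i < n_a else "B") for i in range(n_a + n_b)}
        return CladePartition(assignments=assignments)

    def test_engineered_columns_recovered(self):
        aln = make_alignment(
            ["AAAACA", "AAAACA", "TATACC", "TATACC"], "AAAACA"
        )
        part = self._partition(2, 2)
        diffs, span = fixed_differences(aln, part)
        assert [d[0] for d in diffs] == [0, 2, 5]
        assert span == {"count": 3, "first": 1, "last": 6}

    def test_shared_allele_excludes_column(self):
        aln = make_alignment(["AAAA", "ATAA", "ATAA", "ATAA"], "AAAA")
        part = self._partition(2, 2)
        diffs, _ = fixed_differences(aln, part)
        assert diffs == []

    def test_missing_data_does_not_break_fixation(self):
        aln = make_alignment(["AA", "A-", "TA", "TN"], "AA")
        part = self._partition(2, 2)
        diffs, _ = fixed_differences(aln, part)
        assert [d[0] for d in diffs] == [0]

    def test_simulator_truth_positions_recovered(self):
        alns, truth = simulate_balanced_locus(BalancedConfig(seed=23))
        aln = alns["sp1"]
        part = CladePartition(
            assignments={k: v for k, v in truth.clades.items() if k in aln.ingroup_ids}
        )
        diffs, _ = fixed_differences(aln, part)
        found = {d[0] for d in diffs}
        assert set(truth.positions["diagnostic"]) <= found


class TestCladeCallingAndSummary:
    def test_recovers_engineered_clades(self):
        alns, truth = simulate_balanced_locus(BalancedConfig(seed=31))
        aln = alns["sp1"]
        part = call_clades(aln)
        true_a = {k for k, v in truth.clades.items() if v == "A" and k in aln.ingroup_ids}
        called_a = set(part.members("A"))
        assert called_a in (true_a, set(aln.ingroup_ids) - true_a)

    def test_override_respected(self):
        aln = make_alignment(["AAAA", "AAAT", "TTTT", "TTTA"], "AAAA")
        override = {"a00": "A", "a01": "B", "a02": "A", "a03": "B"}
        part = call_clades(aln, override=override)
        assert part.assignments == override

    def test_label_permutation_invariance(self):
        alns, _ = simulate_balanced_locus(BalancedConfig(seed=3))
        aln = alns["sp1"]
        part = call_clades(aln)
        swapped = CladePartition(
            assignments={k: ("A" if v == "B" else "B") for k, v in part.assignments.items()}
        )
        s1 = clade_summary(aln, part)
        s2 = clade_summary(aln, swapped)
        assert s1["A"].pi_total == pytest.approx(s2["B"].pi_total)
        assert s1["B"].S == s2["A"].S

    def test_identical_sequence_clades_have_zero_pi(self):
        aln = make_alignment(["AAAA"] * 2 + ["TTTT"] * 2, "AAAA")
        part = call_clades(
            aln, override={"a00": "A", "a01": "A", "a02": "B", "a03": "B"}
        )
        s = clade_summary(aln, part)
        assert s["A"].pi_total == 0.0
        assert s["B"].pi_total == 0.0
        from polydiv.popstats import pairwise_diversity

        assert pairwise_diversity(aln, "all") > 0

    def test_singleton_clade_diversity_absent(self):
        aln = make_alignment(["AAAA", "AAAT", "TTTT"], "AAAA")
        part = call_clades(aln, override={"a00": "A", "a01": "A", "a02": "B"})
        s = clade_summary(aln, part)
        assert s["B"].pi_total is None


class TestBootstrap:
    def test_single_replicate_is_zero_or_one(self):
        alns, _ = simulate_balanced_locus(BalancedConfig(seed=5))
        aln = alns["sp1"]
        part = call_clades(aln)
        sup = bootstrap_support(aln, part, replicates=1, seed=0)
        assert sup in (0.0, 1.0)

    def test_deep_split_high_support(self):
        alns, _ = simulate_balanced_locus(BalancedConfig(seed=7))
        aln = alns["sp1"]
        part = call_clades(aln)
        sup = bootstrap_support(aln, part, replicates=100, seed=0)
        assert sup >= 0.99

    def test_random_labels_on_starlike_data_low_support(self):
        rng = np.random.default_rng(19)
        base = rng.choice(list("ACGT"), 400)
        seqs = []
        for _ in range(12):
            s = base.copy()
            cols = rng.choice(400, size=6, replace=False)  # private singletons only
            for c in cols:
                s[c] = rng.choice([b for b in "ACGT" if b != base[c]])
            seqs.append("".join(s))
        aln = make_alignment(seqs, "".join(base))
        labels = {f"a{i:02d}": ("A" if i % 2 == 0 else "B") for i in range(12)}
        part = call_clades(aln, override=labels)
        sup = bootstrap_support(aln, part, replicates=100, seed=1)
        assert sup < 0.7

    def test_seeded_reproducibility(self):
        alns, _ = simulate_balanced_locus(BalancedConfig(seed=9))
        aln = alns["sp1"]
        part = call_clades(aln)
        s1 = bootstrap_support(aln, part, replicates=50, seed=42)
        s2 = bootstrap_support(aln, part, replicates=50, seed=42)
        assert s1 == s2
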
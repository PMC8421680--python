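"""Sliding-window diversity, p-distances, NJ trees and bootstrap."""

import numpy as np
import pytest

from satkit.consensus import Alignment
from satkit.divphylo import (
    DistanceMatrix,
    bootstrap_support,
    classify_windows,
    group_divergence,
    neighbor_joining,
    p_distance_matrix,
    read_newick,
    sliding_pi,
    write_newick,
)


def make_alignment(rows):
    return Alignment(ids=tuple(f"t{i}" for i in range(len(rows))), rows=tuple(rows))


# ---------------------------------------------------------------------------
# Sliding pi


class TestSlidingPi:
    def test_identical_rows_zero_everywhere(self):
        prof = sliding_pi(make_alignment(["ACGTACGTAC"] * 3), window=5)
        assert all(p == 0 for p in prof.pi)

    def test_hand_enumerated_three_rows(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAAAC"]
        prof = sliding_pi(make_alignment(rows), window=10, step=1)
        # pairs: (0,1)=0, (0,2)=1, (1,2)=1 -> pi = 2 / (3 * 10)
        assert prof.pi[0] == pytest.approx(2 / 30)

    def test_gap_and_ambiguity_columns_excluded(self):
        rows = ["AC-TA", "ACNTA", "ACGTC"]
        prof = sliding_pi(make_alignment(rows), window=5)
        # the gap/N column is excluded -> 4 usable sites; the last column
        # differs for pairs (0,2) and (1,2)
        assert prof.sites_used[0] == 4
        assert prof.pi[0] == pytest.approx(2 / (3 * 4))

    def test_pi_equals_mean_pairwise_distance_per_window(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(5)]
        aln = make_alignment(rows)
        prof = sliding_pi(aln, window=20, step=7)
        for w_idx, start in enumerate(prof.starts):
            s0 = start - 1
            sub = make_alignment([r[s0:s0 + 20] for r in rows])
            dm = p_distance_matrix(sub)
            iu = np.triu_indices(5, k=1)
            assert prof.pi[w_idx] == pytest.approx(dm.matrix[iu].mean())

    def test_window_wider_than_alignment_rejected(self):
        with pytest.raises(ValueError):
            sliding_pi(make_alignment(["ACGT"] * 2), window=10)


class TestClassifyWindows:
    def test_equal_pi_all_neutral(self):
        prof = sliding_pi(make_alignment(["ACGTACGTAC"] * 3), window=5)
        assert set(classify_windows(prof).classes) == {"neutral"}

    def test_outlier_classification_by_direct_arithmetic(self):
        rows = ["A" * 30, "A" * 29 + "C"]
        prof = sliding_pi(make_alignment(rows), window=1, step=1)
        values = np.array(prof.pi)
        lo, hi = prof.mean - 2 * prof.sd, prof.mean + 2 * prof.sd
        classes = classify_windows(prof).classes
        for v, c in zip(values, classes):
            expected = "conserved" if v < lo else "variable" if v > hi else "neutral"
            assert c == expected

    def test_uniform_rate_mostly_neutral(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(4)]
        prof = classify_windows(sliding_pi(make_alignment(rows), window=10))
        frac_non_neutral = np.mean([c != "neutral" for c in prof.classes])
        assert frac_non_neutral <= 0.10

    def test_label_invariant_under_taxon_relabeling(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        a = classify_windows(sliding_pi(make_alignment(rows), window=10))
        b = classify_windows(sliding_pi(make_alignment(rows[::-1]), window=10))
        assert a.classes == b.classes

    def test_too_few_windows_rejected(self):
        prof = sliding_pi(make_alignment(["ACGT"] * 2), window=4)
        with pytest.raises(ValueError):
            classify_windows(prof)


# ---------------------------------------------------------------------------
# p-distances


class TestPDistance:
    def test_identical_and_single_substitution(self):
        dm = p_distance_matrix(make_alignment(["ACGT", "ACGT", "ACGA"]))
        assert dm.matrix[0, 1] == 0
        assert dm.matrix[0, 2] == pytest.approx(0.25)

    def test_equals_brute_force_recount(self, rng):
        rows = ["".join(rng.choice(list("ACGT-N"), 100)) for _ in range(6)]
        aln = make_alignment(rows)
        dm = p_distance_matrix(aln, deletion="pairwise")
        for i in range(6):
            for j in range(6):
                comparable = mismatch = 0
                for x, y in zip(rows[i], rows[j]):
                    if x in "ACGT" and y in "ACGT":
                        comparable += 1
                        mismatch += x != y
                assert dm.matrix[i, j] == pytest.approx(mismatch / comparable)

    def test_complete_deletion_uses_clean_columns_only(self):
        rows = ["ACGT", "AC-T", "ACGA"]
        dm = p_distance_matrix(make_alignment(rows), deletion="complete")
        # only columns 0,1,3 are unambiguous in all rows
        assert dm.matrix[0, 2] == pytest.approx(1 / 3)

    def test_zero_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            p_distance_matrix(make_alignment(["A-", "-A"]))


class TestGroupDivergence:
    def test_within_and_between(self):
        m = np.array(
            [[0, 0, 0.3, 0.3], [0, 0, 0.3, 0.3], [0.3, 0.3, 0, 0], [0.3, 0.3, 0, 0]]
        )
        dm = DistanceMatrix(
            labels=("a1", "a2", "b1", "b2"),
            matrix=m,
            groups={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        gd = group_divergence(dm)
        assert gd.within == {"A": 0.0, "B": 0.0}
        assert gd.between[("A", "B")] == pytest.approx(0.3)

    def test_overall_equals_upper_triangle_mean(self, rng):
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(labels=tuple("abcde"), matrix=m)
        gd = group_divergence(dm)
        assert gd.overall == pytest.approx(m[np.triu_indices(5, k=1)].mean())

    def test_singleton_group_within_missing(self):
        m = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        dm = DistanceMatrix(
            labels=("a", "b", "c"), matrix=m, groups={"a": "X", "b": "X", "c": "Y"}
        )
        assert group_divergence(dm).within["Y"] is None


# ---------------------------------------------------------------------------
# Neighbor joining


def skbio_reference_bipartitions(matrix, labels):
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj

    tree = sknj(SkDM(matrix, list(labels)))
    allnames = frozenset(labels)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(labels) - 2:
            other = allnames - side
            if len(other) < len(side) or (
                len(other) == len(side)
                and tuple(sorted(other)) < tuple(sorted(side))
            ):
                side = other
            parts.add(side)
    return parts


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        ptree = neighbor_joining(DistanceMatrix(labels=("a", "b", "c"), matrix=m))
        tips = {t.name: t.length for t in ptree.tree.tips()}
        assert tips["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert tips["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert tips["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_additive_four_taxon_matrix_reproduced_exactly(self):
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        ptree = neighbor_joining(DistanceMatrix(labels=tuple("ABCD"), matrix=m))
        assert ptree.bipartitions() == {frozenset({"A", "B"})}
        tips = {t.name: t for t in ptree.tree.tips()}
        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i < j:
                    assert tips[x].distance(tips[y]) == pytest.approx(
                        m[i, j], abs=1e-9
                    )

    def test_matches_independent_reference_for_small_n(self):
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            n = int(rng.integers(4, 8))
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = tuple(f"t{i}" for i in range(n))
            mine = neighbor_joining(DistanceMatrix(labels=labels, matrix=m))
            assert mine.bipartitions() == skbio_reference_bipartitions(m, labels)

    def test_negative_branch_lengths_clamped(self, rng):
        m = rng.random((5, 5)) * 0.01
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ptree = neighbor_joining(DistanceMatrix(labels=tuple("abcde"), matrix=m))
        assert all(
            (n.length or 0) >= 0 for n in ptree.tree.traverse(include_self=False)
        )

    def test_fewer_than_three_taxa_rejected(self):
        m = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(labels=("a", "b"), matrix=m))


# ---------------------------------------------------------------------------
# Bootstrap


def conflict_alignment():
    """Half the sites support t0t1|t2t3, half support t0t2|t1t3."""
    half1 = ["A", "A", "C", "C"]
    half2 = ["A", "C", "A", "C"]
    rows = ["".join(h[i] for h in [half1] * 100 + [half2] * 100) for i in range(4)]
    return make_alignment(rows)


class TestBootstrap:
    def test_congruent_sites_full_support(self):
        rows = ["A" * 100 + "C" * 100, "A" * 100 + "C" * 100,
                "C" * 100 + "A" * 100, "C" * 100 + "A" * 100]
        ptree = bootstrap_support(make_alignment(rows), replicates=100, seed=3)
        assert set(ptree.supports.values()) == {1.0}

    def test_fixed_seed_reproducible(self):
        aln = conflict_alignment()
        t1 = bootstrap_support(aln, replicates=100, seed=5)
        t2 = bootstrap_support(aln, replicates=100, seed=5)
        assert t1.supports == t2.supports

    def test_conflicting_signal_near_half_support(self):
        ptree = bootstrap_support(conflict_alignment(), replicates=500, seed=2)
        (support,) = ptree.supports.values()
        assert abs(support - 0.5) <= 0.1


# ---------------------------------------------------------------------------
# Newick I/O


class TestNewick:
    def test_round_trip_random_trees(self, tmp_path, rng):
        for k in range(5):
            n = int(rng.integers(4, 20))
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = tuple(f"t{i}" for i in range(n))
            ptree = neighbor_joining(DistanceMatrix(labels=labels, matrix=m))
            path = tmp_path / f"tree{k}.nwk"
            write_newick(ptree, path)
            back = read_newick(path)
            assert back.bipartitions() == ptree.bipartitions()
            back_lengths = sorted(
                round(t.length, 6) for t in back.tree.tips()
            )
            orig_lengths = sorted(
                round(t.length, 6) for t in ptree.tree.tips()
            )
            assert back_lengths == orig_lengths

    def test_internal_label_parsed_as_support(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:1,B:2,(C:3,D:4)90:1);\n")
        ptree = read_newick(path)
        # the CD clade's canonical bipartition side is the lexicographically
        # smaller half {A, B}
        assert ptree.supports == {frozenset({"A", "B"}): 0.9}

    def test_zero_length_branch_survives(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:0.0,B:1.0,(C:1.0,D:0.0):0.0);\n")
        ptree = read_newick(path)
        assert {t.name for t in ptree.tree.tips()} == {"A", "B", "C", "D"}
        write_newick(ptree, tmp_path / "t2.nwk")
        assert read_newick(tmp_path / "t2.nwk").bipartitions() == ptree.bipartitions()
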
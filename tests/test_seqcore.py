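"""Sequence I/O, alignment, identity, dotplot and composition primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from satkit.seqcore import (
    FormatError,
    SequenceRecord,
    at_content,
    dotplot,
    global_align,
    percent_identity,
    read_fasta,
    reverse_complement,
    write_fasta,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)
IUPAC = st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# FASTA I/O


class TestFastaIO:
    def test_case_normalization_and_u_mapping(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">m1\nacgu\n")
        (rec,) = read_fasta(p)
        assert rec.id == "m1" and rec.residues == "ACGT"

    def test_multi_record_order(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">a\nACGT\n>b\nTTTT\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]

    @pytest.mark.parametrize(
        "content",
        [">m1\nACGT\n>m1\nA\n", ">m1\nACXT\n", ""],
        ids=["duplicate-id", "bad-residue", "empty-file"],
    )
    def test_format_errors(self, tmp_path, content):
        p = tmp_path / "in.fa"
        p.write_text(content)
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_round_trip_and_wrap(self, tmp_path, rng):
        recs = [
            SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), 137)))
            for i in range(3)
        ]
        p = tmp_path / "out.fa"
        write_fasta(recs, p, wrap=60)
        assert all(
            len(line) <= 60 for line in p.read_text().splitlines() if not line.startswith(">")
        )
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]

    def test_empty_record_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_fasta([], tmp_path / "x.fa")


# ---------------------------------------------------------------------------
# Reverse complement


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", "ACGT"), ("AAC", "GTT"), ("ANW", "WNT")]
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(SequenceRecord("x", seq)).residues == expected

    @settings(max_examples=50, derandomize=True)
    @given(IUPAC)
    def test_involution(self, seq):
        rec = SequenceRecord("x", seq)
        assert reverse_complement(reverse_complement(rec)).residues == seq


# ---------------------------------------------------------------------------
# Global alignment


def exhaustive_affine_score(a, b, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Plain recursion over every gapped alignment path (oracle, len <= 6)."""

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            best = max(best, cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            best = max(best, cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


class TestGlobalAlign:
    def test_identity_case(self):
        res = global_align("ACGT", "ACGT")
        assert res.identity == 1.0 and "-" not in res.aligned_a + res.aligned_b

    def test_single_substitution(self):
        assert global_align("ACGT", "ACGA").identity == 0.75

    def test_single_gap(self):
        res = global_align("AAAA", "AAA")
        assert (res.aligned_a + res.aligned_b).count("-") == 1

    def test_score_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list("ACGT"), la))
            b = "".join(rng.choice(list("ACGT"), lb))
            assert global_align(a, b).score == exhaustive_affine_score(a, b), (a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_degapping_recovers_inputs(self):
        res = global_align("ACGTACGT", "ACGGT")
        assert res.aligned_a.replace("-", "") == "ACGTACGT"
        assert res.aligned_b.replace("-", "") == "ACGGT"


class TestPercentIdentity:
    def test_identical_sequences_both_modes(self):
        res = global_align("ACGTACGTAC", "ACGTACGTAC")
        assert percent_identity(res, "columns") == 1.0
        assert percent_identity(res, "ungapped") == 1.0

    def test_gapless_counting(self):
        res = global_align("A" * 17, "A" * 15 + "CC")
        assert percent_identity(res, "columns") == 15 / 17

    @settings(max_examples=30, derandomize=True)
    @given(DNA, DNA)
    def test_symmetry(self, a, b):
        fwd = percent_identity(global_align(a, b), "columns")
        rev = percent_identity(global_align(b, a), "columns")
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_subunit_pair_identity_near_generator_target(self, default_monomer):
        res = global_align(default_monomer["a"], default_monomer["b"])
        realized = percent_identity(res, "columns")
        assert realized == pytest.approx(default_monomer["identity"], abs=1e-12)
        assert abs(realized - 0.558) <= 0.05


# ---------------------------------------------------------------------------
# Dotplot


def brute_force_dotplot(a, b, window, threshold):
    hits = set()
    need = math.ceil(threshold * window - 1e-9)
    for i in range(len(a) - window + 1):
        for j in range(len(b) - window + 1):
            matches = sum(
                1
                for x, y in zip(a[i:i + window], b[j:j + window])
                if x == y and x in "ACGT"
            )
            if matches >= need:
                hits.add((i, j))
    return hits


class TestDotplot:
    def test_equals_brute_force_recount(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 160))
        dp = dotplot(seq, seq, window=20, identity_threshold=0.60)
        assert set(dp.hits) == brute_force_dotplot(seq, seq, 20, 0.60)

    def test_self_dotplot_symmetric_and_diagonal(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        dp = dotplot(seq, seq, window=50, identity_threshold=0.60)
        assert all((j, i) in dp.hits for i, j in dp.hits)
        assert all((i, i) in dp.hits for i in range(200 - 50 + 1))

    def test_duplicated_block_gives_offset_band(self, rng):
        u = "".join(rng.choice(list("ACGT"), 100))
        dp = dotplot(u + u, u + u, window=50, identity_threshold=0.9)
        assert (0, 100) in dp.hits and (100, 0) in dp.hits

    def test_exact_threshold_keeps_only_diagonal(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        dp = dotplot(seq, seq, window=50, identity_threshold=1.0)
        assert set(dp.hits) == {(i, i) for i in range(150 - 50 + 1)}

    def test_window_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            dotplot("ACGT", "ACGT", window=10)


# ---------------------------------------------------------------------------
# AT content


class TestAtContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 1.0), ("ACGT", 0.5), ("ANT", 1.0)]
    )
    def test_known_values(self, seq, expected):
        assert at_content(SequenceRecord("x", seq)) == expected

    @settings(max_examples=30, derandomize=True)
    @given(DNA)
    def test_at_plus_gc_is_one(self, seq):
        gc = 1.0 - at_content(SequenceRecord("x", seq))
        counts = {b: seq.count(b) for b in "ACGT"}
        assert gc == pytest.approx((counts["C"] + counts["G"]) / len(seq))

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            at_content(SequenceRecord("x", "NNN"))
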
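"""Core sequence machinery: FASTA I/O, pairwise alignment, identity, dotplots.

Every downstream stage (array detection, consensus building, motif scanning,
diversity) is built on the primitives in this module.  Conventions used
throughout the package:

* residues are upper-case nucleotides over the IUPAC alphabet; ``U`` is mapped
  to ``T`` on input and gap characters are never stored in a
  :class:`SequenceRecord`;
* coordinates are 0-based half-open internally and 1-based inclusive in
  anything written to reports;
* wherever identities are counted, IUPAC ambiguity codes count as mismatches —
  only identical unambiguous bases (A/C/G/T) match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align, SeqIO

__all__ = [
    "SequenceRecord",
    "PairwiseAlignmentResult",
    "DotplotMatrix",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "global_align",
    "percent_identity",
    "dotplot",
    "at_content",
]

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

#: IUPAC code -> set of unambiguous bases it stands for.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class FormatError(ValueError):
    """Raised for malformed sequence input (FASTA, residues, Newick...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (contig, monomer or motif)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_NUCLEOTIDES
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    """A global pairwise alignment of two sequences.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; removing the
    gaps recovers the aligned (sub)sequences.  ``identity`` is the
    columns-mode identity (matches / alignment columns, gap columns counted
    as mismatch); use :func:`percent_identity` for the alternative
    denominator.  Coordinates are 0-based half-open into the input sequences.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    start_a: int = 0
    end_a: int = 0
    start_b: int = 0
    end_b: int = 0

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    def report_coordinates(self) -> tuple[int, int, int, int]:
        """Aligned region of each input as 1-based inclusive intervals."""
        return (self.start_a + 1, self.end_a, self.start_b + 1, self.end_b)


@dataclass(frozen=True)
class DotplotMatrix:
    """Sparse dotplot: window-start pairs whose ungapped identity passes.

    ``hits`` holds 0-based window start pairs ``(i, j)`` such that
    ``a[i:i+window]`` vs ``b[j:j+window]`` has positional identity >=
    ``identity_threshold`` (ambiguity = mismatch).
    """

    window: int
    identity_threshold: float
    hits: frozenset
    len_a: int
    len_b: int
    id_a: str = ""
    id_b: str = ""

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# window=%d\tidentity_threshold=%g\n"
                     % (self.window, self.identity_threshold))
            fh.write("i\tj\n")
            for i, j in sorted(self.hits):
                fh.write(f"{i}\t{j}\n")


# ---------------------------------------------------------------------------
# FASTA I/O


def _normalize(raw: str, rec_id: str) -> str:
    residues = raw.upper().replace("U", "T")
    if not residues:
        raise FormatError(f"record {rec_id!r}: empty sequence")
    bad = set(residues) - IUPAC_NUCLEOTIDES
    if bad:
        raise FormatError(
            f"record {rec_id!r}: non-nucleotide characters {sorted(bad)}"
        )
    return residues


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into validated, upper-cased records.

    ``U`` is mapped to ``T``.  Duplicate ids, empty files and residues
    outside the IUPAC alphabet raise :class:`FormatError` naming the
    offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _normalize(str(rec.seq), rec.id)
        records.append(SequenceRecord(rec.id, residues, rec.description))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, wrap: int = 60) -> None:
    """Write records as wrapped multi-FASTA; round-trips through read_fasta."""
    if not records:
        raise ValueError("refusing to write an empty record list")
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header += " " + rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i:i + wrap] + "\n")


def reverse_complement(record: SequenceRecord) -> SequenceRecord:
    """Reverse complement with full IUPAC support (an involution)."""
    return SequenceRecord(
        record.id,
        record.residues.translate(_COMPLEMENT)[::-1],
        record.description,
    )


def revcomp(residues: str) -> str:
    """Reverse complement of a bare residue string."""
    return residues.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Pairwise alignment


def _residues(x) -> str:
    return x.residues if isinstance(x, SequenceRecord) else str(x)


def _count_matches(aligned_a: str, aligned_b: str) -> int:
    return sum(
        1
        for ca, cb in zip(aligned_a, aligned_b)
        if ca == cb and ca in "ACGT"
    )


def global_align(
    a,
    b,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment with affine gap costs.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  End gaps
    are penalized.  Among co-optimal alignments a single deterministic
    traceback is returned, so repeated calls are bit-identical.
    """
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(sa, sb)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    matches = _count_matches(aligned_a, aligned_b)
    return PairwiseAlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identity=matches / len(aligned_a),
        start_a=0,
        end_a=len(sa),
        start_b=0,
        end_b=len(sb),
    )


def percent_identity(result: PairwiseAlignmentResult, mode: str = "columns") -> float:
    """Identity of an alignment under an explicit denominator convention.

    ``columns``: matches / all alignment columns (gap columns = mismatch).
    ``ungapped``: matches / columns where neither sequence is gapped.
    A match requires identical unambiguous bases; ambiguity codes mismatch.
    """
    if result.n_columns == 0:
        raise ValueError("zero-length alignment")
    matches = _count_matches(result.aligned_a, result.aligned_b)
    if mode == "columns":
        return matches / result.n_columns
    if mode == "ungapped":
        non_gap = sum(
            1
            for ca, cb in zip(result.aligned_a, result.aligned_b)
            if ca != "-" and cb != "-"
        )
        if non_gap == 0:
            raise ValueError("alignment has no ungapped columns")
        return matches / non_gap
    raise ValueError(f"unknown identity mode {mode!r}")


# ---------------------------------------------------------------------------
# Dotplots and composition

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i


def encode(residues: str) -> np.ndarray:
    """Encode residues as uint8: A,C,G,T -> 0..3, anything else -> 255."""
    return _ENCODE_TABLE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def dotplot(
    seq_a,
    seq_b,
    window: int = 50,
    identity_threshold: float = 0.60,
) -> DotplotMatrix:
    """All-window ungapped dotplot of two sequences.

    A hit is recorded at ``(i, j)`` iff the positional identity of
    ``a[i:i+window]`` vs ``b[j:j+window]`` is >= ``identity_threshold``.
    The self-dotplot of any sequence therefore contains the full main
    diagonal.  Computed per diagonal with a sliding match count, which is
    equivalent to the naive O(n*m*window) recount.
    """
    sa, sb = _residues(seq_a), _residues(seq_b)
    if window > len(sa) or window > len(sb):
        raise ValueError("window larger than a sequence")
    a = encode(sa)
    b = encode(sb)
    n, m = len(a), len(b)
    need = math.ceil(identity_threshold * window - 1e-9)
    hits: set[tuple[int, int]] = set()
    kernel = np.ones(window, dtype=np.int32)
    # diagonal offset o = j - i
    for o in range(-(n - window), m - window + 1):
        i0 = max(0, -o)
        i1 = min(n, m - o)
        seg_a = a[i0:i1]
        seg_b = b[i0 + o:i1 + o]
        eq = ((seg_a == seg_b) & (seg_a != 255)).astype(np.int32)
        counts = np.convolve(eq, kernel, mode="valid")
        for k in np.nonzero(counts >= need)[0]:
            i = i0 + int(k)
            hits.add((i, i + o))
    return DotplotMatrix(
        window=window,
        identity_threshold=identity_threshold,
        hits=frozenset(hits),
        len_a=n,
        len_b=m,
        id_a=getattr(seq_a, "id", ""),
        id_b=getattr(seq_b, "id", ""),
    )


def at_content(record) -> float:
    """(A+T) / (A+C+G+T); ambiguity codes and N are excluded entirely."""
    residues = _residues(record)
    counts = {b: residues.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["A"] + counts["T"]) / total
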
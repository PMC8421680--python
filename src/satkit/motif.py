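"""CENP-B box / ECD motif scanning and cross-species motif comparison.

The CENP-B box is a 17 bp motif bound by centromere protein B in mammalian
centromeric satellites; nine of its positions form the evolutionarily
conserved domain (ECD), written as the degenerate pattern
``nTTCGnnnnAnnCGGGn``.  All scoring here is positional (ungapped): a
window position matches a defined pattern position only when both carry
the same unambiguous base — ambiguity codes in the window (or in a motif
being compared) count as mismatches.  At 17 bp with no meaningful gap
model this is the reproducible way to score candidate boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seqcore import IUPAC_SETS, SequenceRecord, revcomp

__all__ = [
    "DegeneratePattern",
    "MotifHit",
    "ECD_PATTERN",
    "AFROTHERIA_CENPB_BOX",
    "SIRENIA_CENPB_MOTIFS",
    "scan_ecd",
    "motif_identity",
    "compare_to_reference_box",
]

#: The 17 bp CENP-B box pattern whose nine defined positions form the ECD.
ECD_PATTERN = "NTTCGNNNNANNCGGGN"

#: CENP-B box reported from Loxodonta africana / Dasypus novemcinctus,
#: used as a concrete (non-degenerate) reference box.
AFROTHERIA_CENPB_BOX = "CTTTGCCGAGAACGGAG"

#: Published CENP-B-box-like 17-mers from the sirenian centromeric
#: satellite consensus of each species: motif 1 sits at consensus positions
#: 196-212, motif 2 at 518-534 (1-based inclusive).
SIRENIA_CENPB_MOTIFS = {
    "T_manatus": {"motif1": "CTTTGCATAACAGGGAA", "motif2": "TTTACAGCTTTCCGGGA"},
    "T_inunguis": {"motif1": "CTTTGCAWAACAGGAAT", "motif2": "TTTGCAGCATTCCGGGA"},
    "D_dugon": {"motif1": "CTTTGCATTACAGGGAA", "motif2": "TTTACAGCTTTCCGGGA"},
    "H_gigas": {"motif1": "CTTTGCATTACAGGGAA", "motif2": "TTTACAGCTTTCCGGGA"},
}


@dataclass(frozen=True)
class DegeneratePattern:
    """A degenerate IUPAC motif pattern; non-N positions are 'defined'."""

    pattern: str

    def __post_init__(self):
        bad = set(self.pattern.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def defined_positions(self) -> tuple:
        return tuple(i for i, c in enumerate(self.pattern) if c != "N")

    def matches_at(self, window: str) -> int:
        """Count defined positions matched by an equal-length window.

        A window base matches a defined pattern position when it is
        unambiguous and contained in the pattern code's base set (for plain
        A/C/G/T pattern codes this is exact equality).
        """
        if len(window) != len(self.pattern):
            raise ValueError("window length differs from pattern length")
        count = 0
        for i in self.defined_positions:
            w = window[i]
            if w in "ACGT" and w in IUPAC_SETS[self.pattern[i]]:
                count += 1
        return count


@dataclass(frozen=True)
class MotifHit:
    """A scored 17 bp (pattern-length) window of a scanned sequence.

    ``start``/``end`` are 1-based inclusive on the forward strand of the
    scanned sequence; for '-' hits ``window`` is the reverse-complemented
    (motif-forward) sequence of that interval.
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    window: str
    ecd_matches: int
    full_matches: int


def _coerce_pattern(pattern) -> DegeneratePattern:
    if isinstance(pattern, DegeneratePattern):
        return pattern
    if isinstance(pattern, SequenceRecord):
        return DegeneratePattern(pattern.residues)
    return DegeneratePattern(str(pattern))


def _iter_windows(residues: str, length: int, both_strands: bool):
    for s in range(len(residues) - length + 1):
        yield s, "+", residues[s:s + length]
    if both_strands:
        for s in range(len(residues) - length + 1):
            yield s, "-", revcomp(residues[s:s + length])


def scan_ecd(
    record: SequenceRecord,
    pattern=ECD_PATTERN,
    min_matches: int = 5,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan a sequence for windows matching a degenerate ECD-style pattern.

    Every window (on both strands by default) is scored by the number of
    matched defined positions; hits reaching ``min_matches`` are returned
    sorted by (matches descending, position ascending, strand).  The
    default floor of 5/9 mirrors the weakest ECD agreement still treated
    as a reportable box in sirenian satellites.
    """
    pat = _coerce_pattern(pattern)
    if len(record.residues) < len(pat):
        raise ValueError("record shorter than pattern")
    hits = []
    for s, strand, window in _iter_windows(record.residues, len(pat), both_strands):
        m = pat.matches_at(window)
        if m >= min_matches:
            hits.append(
                MotifHit(
                    sequence_id=record.id,
                    start=s + 1,
                    end=s + len(pat),
                    strand=strand,
                    window=window,
                    ecd_matches=m,
                    full_matches=m,
                )
            )
    hits.sort(key=lambda h: (-h.ecd_matches, h.start, h.strand))
    return hits


def motif_identity(motif_a: str, motif_b: str) -> int:
    """Ungapped positional matches between two equal-length motifs.

    Equals length minus the Hamming distance under the
    ambiguity-as-mismatch convention (a W never matches anything, including
    another W's underlying base).
    """
    a = motif_a.residues if isinstance(motif_a, SequenceRecord) else str(motif_a)
    b = motif_b.residues if isinstance(motif_b, SequenceRecord) else str(motif_b)
    if len(a) != len(b):
        raise ValueError("motif lengths differ")
    a, b = a.upper(), b.upper()
    return sum(1 for x, y in zip(a, b) if x == y and x in "ACGT")


def compare_to_reference_box(
    record: SequenceRecord,
    reference_box: str = AFROTHERIA_CENPB_BOX,
    min_identity: float = 0.51,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan for windows positionally similar to a concrete reference box.

    Windows are scored by full positional identity (all positions defined);
    hits with identity >= ``min_identity`` are returned sorted by
    (matches descending, position ascending, strand).
    """
    ref = (
        reference_box.residues
        if isinstance(reference_box, SequenceRecord)
        else str(reference_box)
    ).upper()
    if len(record.residues) < len(ref):
        raise ValueError("record shorter than reference box")
    hits = []
    for s, strand, window in _iter_windows(record.residues, len(ref), both_strands):
        m = motif_identity(window, ref)
        if m / len(ref) >= min_identity:
            hits.append(
                MotifHit(
                    sequence_id=record.id,
                    start=s + 1,
                    end=s + len(ref),
                    strand=strand,
                    window=window,
                    ecd_matches=m,
                    full_matches=m,
                )
            )
    hits.sort(key=lambda h: (-h.full_matches, h.start, h.strand))
    return hits


def hits_to_tsv(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tstart\tend\tstrand\twindow\tecd_matches\tfull_matches\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.strand}"
                f"\t{h.window}\t{h.ecd_matches}\t{h.full_matches}\n"
            )
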
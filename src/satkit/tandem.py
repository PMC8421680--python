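"""Tandem array detection, monomer extraction, period estimation, HOR labels.

Array detection is a seed-and-extend search: exact k-mers of the query
monomer are located in the contigs (both strands), seed hits voting for the
same unit start are clustered, candidate units are verified by global
alignment against the query, and verified units closer than one query
length are merged into arrays.  This keeps the whole search deterministic
and dependency-free at desk scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .seqcore import (
    SequenceRecord,
    dotplot,
    encode,
    global_align,
    percent_identity,
    revcomp,
)

__all__ = [
    "TandemArray",
    "HORAnnotation",
    "PeriodEstimate",
    "find_arrays",
    "extract_monomers",
    "estimate_period",
    "annotate_hor",
    "genome_proportion",
]


@dataclass(frozen=True)
class TandemArray:
    """A located tandem array of repeat units on a contig.

    All coordinates are 0-based half-open on the forward strand of the
    contig; ``units`` are ordered, non-overlapping intervals covering the
    individual repeat copies.  ``strand`` is '+' when units match the query
    directly and '-' when they match its reverse complement.
    """

    contig_id: str
    strand: str
    start: int
    end: int
    units: tuple
    unit_identities: tuple

    def __post_init__(self):
        if len(self.units) < 2:
            raise ValueError("a tandem array needs >= 2 units")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def mean_identity(self) -> float:
        return float(np.mean(self.unit_identities))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HORAnnotation:
    """Per-unit subunit labels plus higher-order pattern summary.

    ``labels`` is a string over {A, B, U}; ``runs`` is its run-length
    encoding; adjacent-pair counts distinguish alternating structure (AB or
    BA pairs) from subunit dimers (AA / BB).
    """

    labels: str
    runs: tuple
    identities_a: tuple
    identities_b: tuple
    n_alternating_pairs: int
    n_aa_dimers: int
    n_bb_dimers: int
    max_run: dict

    def __post_init__(self):
        decoded = "".join(lab * n for lab, n in self.runs)
        if decoded != self.labels:
            raise ValueError("run-length encoding does not decode to labels")


@dataclass(frozen=True)
class PeriodEstimate:
    """Estimated repeat period of a sequence; ``period`` None = aperiodic."""

    period: Optional[int]
    support: int

    @property
    def periodic(self) -> bool:
        return self.period is not None


# ---------------------------------------------------------------------------
# Seed-and-extend array search

_POWERS_CACHE: dict = {}


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; -1 where the window contains non-ACGT."""
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    c = np.where(arr == 255, 0, arr).astype(np.int64)
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes += c[j:j + m] << (2 * j)
    bad = np.concatenate([[0], np.cumsum(arr == 255)])
    codes[(bad[k:] - bad[:-k]) > 0] = -1
    return codes


def _candidate_unit_starts(
    contig_arr: np.ndarray,
    query: str,
    seed_k: int,
    min_units_span: int,
) -> list[int]:
    """Cluster seed votes (contig_pos - query_pos) into candidate unit starts."""
    q_arr = encode(query)
    q_codes = _kmer_codes(q_arr, seed_k)
    qmap: dict[int, list[int]] = {}
    for qp, code in enumerate(q_codes):
        if code >= 0:
            qmap.setdefault(int(code), []).append(qp)
    c_codes = _kmer_codes(contig_arr, seed_k)
    if c_codes.size == 0:
        return []
    uniq = np.fromiter(qmap.keys(), dtype=np.int64, count=len(qmap))
    mask = np.isin(c_codes, uniq)
    votes: list[int] = []
    for cp in np.nonzero(mask)[0]:
        for qp in qmap[int(c_codes[cp])]:
            votes.append(int(cp) - qp)
    if not votes:
        return []
    votes.sort()
    half = len(query) // 2
    starts = []
    cluster: list[int] = [votes[0]]
    for v in votes[1:]:
        if v - cluster[-1] <= half:
            cluster.append(v)
        else:
            starts.append(_cluster_rep(cluster))
            cluster = [v]
    starts.append(_cluster_rep(cluster))
    return [s for s in starts if s > -len(query)]


def _cluster_rep(cluster: list[int]) -> int:
    counts = Counter(cluster)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def find_arrays(
    contigs: Sequence[SequenceRecord],
    query,
    min_unit_identity: float = 0.70,
    min_units: int = 2,
    seed_k: int = 12,
) -> list[TandemArray]:
    """Locate tandem arrays of a query monomer in contigs (both strands).

    Exact ``seed_k``-mers of the query vote for candidate unit starts;
    consecutive candidate starts delimit candidate units, each verified by
    global alignment to the query at columns-identity >= ``min_unit_identity``;
    verified units separated by at most one query length are merged into
    arrays, and arrays with >= ``min_units`` units are reported sorted by
    (contig, start).
    """
    q = query.residues if isinstance(query, SequenceRecord) else str(query)
    if len(q) < seed_k:
        raise ValueError("query shorter than seed_k")
    lq = len(q)
    arrays: list[TandemArray] = []
    for contig in contigs:
        contig_arr = encode(contig.residues)
        n = len(contig.residues)
        for strand, qseq in (("+", q), ("-", revcomp(q))):
            starts = _candidate_unit_starts(contig_arr, qseq, seed_k, lq)
            units = []
            for idx, s in enumerate(starts):
                nxt = starts[idx + 1] if idx + 1 < len(starts) else None
                if nxt is not None and 0.5 * lq <= nxt - s <= 1.5 * lq:
                    e = nxt
                else:
                    e = s + lq
                s_clip, e_clip = max(0, s), min(n, e)
                if e_clip - s_clip < 0.5 * lq:
                    continue
                unit_seq = contig.residues[s_clip:e_clip]
                ident = percent_identity(global_align(unit_seq, qseq), "columns")
                if ident >= min_unit_identity:
                    units.append((s_clip, e_clip, ident))
            # merge verified units into arrays
            run: list[tuple[int, int, float]] = []
            for u in units:
                if run and u[0] - run[-1][1] > lq:
                    arrays.extend(_emit(contig.id, strand, run, min_units))
                    run = []
                run.append(u)
            arrays.extend(_emit(contig.id, strand, run, min_units))
    arrays.sort(key=lambda a: (a.contig_id, a.start, a.strand))
    return arrays


def _emit(contig_id: str, strand: str, run, min_units: int):
    if len(run) < min_units:
        return []
    return [
        TandemArray(
            contig_id=contig_id,
            strand=strand,
            start=run[0][0],
            end=run[-1][1],
            units=tuple((s, e) for s, e, _ in run),
            unit_identities=tuple(i for _, _, i in run),
        )
    ]


def extract_monomers(
    contigs: Sequence[SequenceRecord],
    arrays: Sequence[TandemArray],
    max_monomers: Optional[int] = None,
    seed: Optional[int] = None,
) -> list[SequenceRecord]:
    """Extract per-unit monomer sequences in query-forward orientation.

    Units from '-' arrays are reverse complemented.  When ``max_monomers``
    is given, a uniform subsample is drawn with the mandatory ``seed``
    (deterministic, order-preserving).
    """
    by_id = {c.id: c for c in contigs}
    records: list[SequenceRecord] = []
    for ai, arr in enumerate(arrays):
        contig = by_id[arr.contig_id]
        unit_iter = list(enumerate(arr.units))
        if arr.strand == "-":
            unit_iter = list(reversed(unit_iter))  # array-forward order
        for order, (ui, (s, e)) in enumerate(unit_iter):
            if not (0 <= s < e <= len(contig.residues)):
                raise ValueError(
                    f"unit {ui} of array {ai} out of contig {arr.contig_id} range"
                )
            seq = contig.residues[s:e]
            if arr.strand == "-":
                seq = revcomp(seq)
            records.append(
                SequenceRecord(
                    f"{arr.contig_id}_a{ai}_u{order}_{'fwd' if arr.strand == '+' else 'rev'}",
                    seq,
                    f"{arr.contig_id}:{s + 1}-{e}({arr.strand})",
                )
            )
    if max_monomers is not None and max_monomers < len(records):
        if seed is None:
            raise ValueError("subsampling requires a seed")
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(records), size=max_monomers, replace=False))
        records = [records[i] for i in keep]
    return records


def estimate_period(
    array_sequence,
    window: int = 50,
    identity_threshold: float = 0.60,
) -> PeriodEstimate:
    """Estimate the repeat period from self-dotplot diagonal spacing.

    Off-diagonal hit offsets are clustered (within half a window); the
    period is the modal spacing between consecutive concordant diagonals,
    smallest first on ties.  A sequence whose self-dotplot has no
    off-diagonal structure is reported aperiodic.
    """
    seq = (
        array_sequence.residues
        if isinstance(array_sequence, SequenceRecord)
        else str(array_sequence)
    )
    if len(seq) < 4 * window:
        raise ValueError("sequence shorter than four windows")
    dp = dotplot(seq, seq, window=window, identity_threshold=identity_threshold)
    offsets = sorted(
        Counter(j - i for i, j in dp.hits if j - i >= window).items()
    )
    if not offsets:
        return PeriodEstimate(period=None, support=0)
    # cluster offsets within window/2 into diagonals
    diagonals: list[tuple[int, int]] = []  # (representative offset, support)
    cluster: list[tuple[int, int]] = [offsets[0]]
    for o, c in offsets[1:]:
        if o - cluster[-1][0] <= window // 2:
            cluster.append((o, c))
        else:
            diagonals.append(_diagonal_rep(cluster))
            cluster = [(o, c)]
    diagonals.append(_diagonal_rep(cluster))
    # discard weak diagonals (e.g. partial matches between diverged
    # subunits at a fraction of the monomer period): keep those with at
    # least half the support of the strongest diagonal
    max_support = max(c for _, c in diagonals)
    reps = [o for o, c in diagonals if c >= max_support / 2]
    if len(reps) == 1:
        return PeriodEstimate(period=reps[0], support=1)
    spacings = Counter(b - a for a, b in zip(reps, reps[1:]))
    top = max(spacings.values())
    period = min(s for s, c in spacings.items() if c == top)
    tol = max(2, window // 10)
    support = sum(
        1 for a, b in zip(reps, reps[1:]) if abs((b - a) - period) <= tol
    ) + 1
    return PeriodEstimate(period=period, support=support)


def _diagonal_rep(cluster) -> tuple:
    """(support-weighted representative offset, total support) of a diagonal."""
    top = max(c for _, c in cluster)
    rep = min(o for o, c in cluster if c == top)
    return rep, sum(c for _, c in cluster)


def annotate_hor(
    units: Sequence,
    subunit_a_consensus,
    subunit_b_consensus,
    min_identity: float = 0.50,
) -> HORAnnotation:
    """Label ordered repeat units by their closest subunit consensus.

    Each unit gets the label of the subunit consensus with the higher
    global-alignment columns-identity, provided that identity reaches
    ``min_identity``; otherwise (or on an exact tie) it is 'U'.  The floor
    must sit below the winning identity but above the cross-subunit
    identity (~0.5 for subunits that are themselves ~56% identical).
    """
    ca = (
        subunit_a_consensus.residues
        if isinstance(subunit_a_consensus, SequenceRecord)
        else str(subunit_a_consensus)
    )
    cb = (
        subunit_b_consensus.residues
        if isinstance(subunit_b_consensus, SequenceRecord)
        else str(subunit_b_consensus)
    )
    if not ca or not cb:
        raise ValueError("empty subunit consensus")
    labels = []
    ids_a, ids_b = [], []
    for unit in units:
        seq = unit.residues if isinstance(unit, SequenceRecord) else str(unit)
        ia = percent_identity(global_align(seq, ca), "columns")
        ib = percent_identity(global_align(seq, cb), "columns")
        ids_a.append(ia)
        ids_b.append(ib)
        if ia == ib or max(ia, ib) < min_identity:
            labels.append("U")
        else:
            labels.append("A" if ia > ib else "B")
    label_str = "".join(labels)
    runs = []
    for ch in label_str:
        if runs and runs[-1][0] == ch:
            runs[-1][1] += 1
        else:
            runs.append([ch, 1])
    runs_t = tuple((lab, n) for lab, n in runs)
    pairs = [label_str[i:i + 2] for i in range(len(label_str) - 1)]
    max_run = {lab: max((n for l, n in runs_t if l == lab), default=0) for lab in "ABU"}
    return HORAnnotation(
        labels=label_str,
        runs=runs_t,
        identities_a=tuple(ids_a),
        identities_b=tuple(ids_b),
        n_alternating_pairs=sum(1 for p in pairs if p in ("AB", "BA")),
        n_aa_dimers=sum(1 for p in pairs if p == "AA"),
        n_bb_dimers=sum(1 for p in pairs if p == "BB"),
        max_run=max_run,
    )


def genome_proportion(
    contigs: Sequence[SequenceRecord],
    arrays: Sequence[TandemArray],
) -> float:
    """Fraction of assembled bases covered by detected arrays."""
    total = sum(len(c.residues) for c in contigs)
    if total == 0:
        raise ValueError("no contig sequence")
    return sum(a.length for a in arrays) / total


def arrays_to_tsv(arrays: Sequence[TandemArray], path, bed: bool = False) -> None:
    """Write arrays as TSV; 1-based inclusive by default, 0-based if bed."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tn_units\tmean_identity\n")
        for a in arrays:
            start = a.start if bed else a.start + 1
            fh.write(
                f"{a.contig_id}\t{start}\t{a.end}\t{a.strand}"
                f"\t{a.n_units}\t{a.mean_identity:.4f}\n"
            )


def hor_to_tsv(annotation: HORAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tlabel\tidentity_A\tidentity_B\n")
        for i, lab in enumerate(annotation.labels):
            fh.write(
                f"{i}\t{lab}\t{annotation.identities_a[i]:.4f}"
                f"\t{annotation.identities_b[i]:.4f}\n"
            )
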
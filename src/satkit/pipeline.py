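"""End-to-end satellite characterization: detect -> extract -> align ->
consensus -> structure -> motifs -> diversity -> tree.

``run_pipeline`` orchestrates the stage functions of the other modules,
writes each stage's output in its native text format under an output
directory, and returns a :class:`Report` whose summary numbers are all
recomputable from those stage outputs.  Defaults reproduce the standard
settings of the satellite-characterization workflow this package
implements (25% consensus threshold, 50 bp / 60% dotplots, 10 bp / 1 bp
diversity windows, 500 bootstrap replicates, the 17 bp ECD pattern);
rerunning with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .consensus import (
    Alignment,
    detect_internal_duplication,
    duplications_to_tsv,
    most_common_sequence,
    segment_identity,
    star_msa,
)
from .divphylo import (
    bootstrap_support,
    classify_windows,
    group_divergence,
    p_distance_matrix,
    sliding_pi,
    write_newick,
)
from .motif import AFROTHERIA_CENPB_BOX, ECD_PATTERN, compare_to_reference_box, hits_to_tsv, scan_ecd
from .seqcore import SequenceRecord, at_content, global_align, percent_identity, read_fasta, write_fasta
from .tandem import (
    annotate_hor,
    arrays_to_tsv,
    estimate_period,
    extract_monomers,
    find_arrays,
    genome_proportion,
    hor_to_tsv,
)

__all__ = ["PipelineConfig", "Report", "run_pipeline", "ZeroArraysFound"]


class ZeroArraysFound(RuntimeError):
    """No tandem array of the query was found (handled, not a crash)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs plus every stage parameter of the characterization pipeline."""

    contigs: str = ""
    query: str = ""
    outdir: str = "satkit_out"
    seed: int = 0
    aligned_monomers: Optional[str] = None  # pre-aligned FASTA, skips star MSA
    species_map: Optional[str] = None       # TSV: monomer_id <tab> species
    # detection
    min_unit_identity: float = 0.70
    min_units: int = 2
    seed_k: int = 12
    max_monomers: Optional[int] = 66
    # consensus & structure
    mcs_threshold: float = 0.25
    dotplot_window: int = 50
    dotplot_identity: float = 0.60
    min_band_hits: int = 3
    # motifs
    ecd_pattern: str = ECD_PATTERN
    reference_box: str = AFROTHERIA_CENPB_BOX
    min_ecd_matches: int = 5
    # diversity & tree
    pi_window: int = 10
    pi_step: int = 1
    bootstrap_replicates: int = 500
    period_max_bp: int = 10000

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Report:
    """Consolidated pipeline summary with provenance."""

    version: str
    config_hash: str
    seed: int
    summary: dict
    outputs: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _map_split_to_unit(mcs: str, unit_seq: str, split0: int) -> int:
    """Map an MCS coordinate onto a unit via global alignment columns."""
    res = global_align(mcs, unit_seq)
    mi = ui = 0
    for ca, cb in zip(res.aligned_a, res.aligned_b):
        if mi >= split0:
            break
        if ca != "-":
            mi += 1
        if cb != "-":
            ui += 1
    return max(1, min(len(unit_seq) - 1, ui))


def run_pipeline(config: PipelineConfig) -> Report:
    """Run the full characterization and write all stage outputs.

    Raises :class:`ZeroArraysFound` when no array passes the detection
    thresholds; callers (e.g. the CLI) may still emit the partial report
    carried by the exception.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = read_fasta(config.contigs)
    query = read_fasta(config.query)[0]
    outputs: dict[str, str] = {}
    summary: dict = {"n_contigs": len(contigs), "query_length": len(query)}

    # --- detection -------------------------------------------------------
    arrays = find_arrays(
        contigs,
        query,
        min_unit_identity=config.min_unit_identity,
        min_units=config.min_units,
        seed_k=config.seed_k,
    )
    arrays_path = outdir / "arrays.tsv"
    arrays_to_tsv(arrays, arrays_path)
    outputs["arrays"] = str(arrays_path)
    summary["n_arrays"] = len(arrays)
    summary["genome_proportion"] = genome_proportion(contigs, arrays)
    if not arrays:
        report = _finalize(config, summary, outputs, outdir)
        exc = ZeroArraysFound("no tandem arrays found")
        exc.report = report
        raise exc
    summary["n_units_total"] = sum(a.n_units for a in arrays)
    summary["mean_unit_identity"] = sum(
        sum(a.unit_identities) for a in arrays
    ) / summary["n_units_total"]

    # --- period ----------------------------------------------------------
    longest = max(arrays, key=lambda a: a.length)
    by_id = {c.id: c for c in contigs}
    arr_seq = by_id[longest.contig_id].residues[longest.start:longest.end]
    pe = estimate_period(
        arr_seq[: config.period_max_bp],
        window=config.dotplot_window,
        identity_threshold=config.dotplot_identity,
    )
    summary["estimated_period"] = pe.period
    summary["period_support"] = pe.support

    # --- monomers & alignment -------------------------------------------
    monomers = extract_monomers(
        contigs, arrays, max_monomers=config.max_monomers, seed=config.seed
    )
    monomers_path = outdir / "monomers.fasta"
    write_fasta(monomers, monomers_path)
    outputs["monomers"] = str(monomers_path)
    summary["n_monomers"] = len(monomers)
    if config.aligned_monomers:
        alignment = Alignment.read_fasta(config.aligned_monomers)
    else:
        alignment = star_msa(monomers)
    aligned_path = outdir / "monomers_aligned.fasta"
    alignment.write_fasta(aligned_path)
    outputs["alignment"] = str(aligned_path)

    # --- consensus -------------------------------------------------------
    profile = most_common_sequence(alignment, threshold=config.mcs_threshold)
    mcs = profile.mcs
    consensus_path = outdir / "consensus.json"
    profile.to_json(consensus_path)
    outputs["consensus"] = str(consensus_path)
    write_fasta([SequenceRecord("MCS", mcs)], outdir / "mcs.fasta")
    outputs["mcs"] = str(outdir / "mcs.fasta")
    summary["mcs_length"] = len(mcs)
    summary["mcs_at_content"] = at_content(mcs)

    # --- internal structure ---------------------------------------------
    dups = detect_internal_duplication(
        mcs,
        window=config.dotplot_window,
        identity_threshold=config.dotplot_identity,
        min_band_hits=config.min_band_hits,
    )
    dup_path = outdir / "duplications.tsv"
    duplications_to_tsv(dups, dup_path)
    outputs["duplications"] = str(dup_path)
    summary["internal_duplications"] = [
        {
            "segment_a": list(d.segment_a),
            "segment_b": list(d.segment_b),
            "identity": d.identity,
            "support": d.support,
        }
        for d in dups
    ]

    if dups:
        split0 = dups[0].split - 1  # 0-based start of segment B on the MCS
        sub_a, sub_b = mcs[:split0], mcs[split0:]
        seg_res = segment_identity(mcs, (1, split0), (split0 + 1, len(mcs)))
        summary["subunit_identity_columns"] = percent_identity(seg_res, "columns")
        summary["subunit_identity_ungapped"] = percent_identity(seg_res, "ungapped")
        # segment-scale HOR labels: each unit is cut at the MCS split point
        segments = []
        for ai, arr in enumerate(arrays):
            units = extract_monomers(contigs, [arr])
            for u in units:
                cut = _map_split_to_unit(mcs, u.residues, split0)
                segments.append(u.residues[:cut])
                segments.append(u.residues[cut:])
        hor = annotate_hor(segments, sub_a, sub_b)
        hor_path = outdir / "hor.tsv"
        hor_to_tsv(hor, hor_path)
        outputs["hor"] = str(hor_path)
        summary["hor"] = {
            "labels": hor.labels,
            "n_alternating_pairs": hor.n_alternating_pairs,
            "n_aa_dimers": hor.n_aa_dimers,
            "n_bb_dimers": hor.n_bb_dimers,
            "max_run": hor.max_run,
        }

    # --- motifs ----------------------------------------------------------
    mcs_rec = SequenceRecord("MCS", mcs)
    ecd_hits = scan_ecd(mcs_rec, config.ecd_pattern, min_matches=config.min_ecd_matches)
    box_hits = compare_to_reference_box(mcs_rec, config.reference_box)
    hits_to_tsv(ecd_hits, outdir / "motifs_ecd.tsv")
    hits_to_tsv(box_hits, outdir / "motifs_reference_box.tsv")
    outputs["motifs_ecd"] = str(outdir / "motifs_ecd.tsv")
    outputs["motifs_reference_box"] = str(outdir / "motifs_reference_box.tsv")
    summary["ecd_hits"] = [
        {"start": h.start, "end": h.end, "strand": h.strand,
         "window": h.window, "ecd_matches": h.ecd_matches}
        for h in ecd_hits[:10]
    ]

    # --- diversity -------------------------------------------------------
    profile_pi = classify_windows(
        sliding_pi(alignment, window=config.pi_window, step=config.pi_step)
    )
    pi_path = outdir / "diversity.tsv"
    profile_pi.to_tsv(pi_path)
    outputs["diversity"] = str(pi_path)
    classes = [c for c in profile_pi.classes if c is not None]
    summary["diversity"] = {
        "mean_pi": profile_pi.mean,
        "sd_pi": profile_pi.sd,
        "n_windows": len(classes),
        "n_conserved": classes.count("conserved"),
        "n_variable": classes.count("variable"),
    }

    # --- distances & tree ------------------------------------------------
    groups = None
    if config.species_map:
        groups = {}
        with open(config.species_map) as fh:
            for line in fh:
                if line.strip():
                    mid, sp = line.split()[:2]
                    groups[mid] = sp
    dm = p_distance_matrix(alignment, groups=groups)
    dm.to_tsv(outdir / "distances.tsv")
    outputs["distances"] = str(outdir / "distances.tsv")
    div = group_divergence(dm)
    summary["divergence"] = {
        "overall_d": div.overall,
        "within": div.within,
        "between": {f"{a}|{b}": v for (a, b), v in div.between.items()},
    }
    tree = bootstrap_support(
        alignment, replicates=config.bootstrap_replicates, seed=config.seed
    )
    tree_path = outdir / "tree.nwk"
    write_newick(tree, tree_path)
    outputs["tree"] = str(tree_path)
    summary["tree"] = {
        "n_leaves": len(tree.leaf_names),
        "n_bipartitions": len(tree.supports or {}),
        "discarded_replicates": tree.n_discarded_replicates,
    }

    return _finalize(config, summary, outputs, outdir)


def _finalize(config: PipelineConfig, summary: dict, outputs: dict, outdir: Path) -> Report:
    report = Report(
        version=__version__,
        config_hash=config.hash(),
        seed=config.seed,
        summary=summary,
        outputs=outputs,
    )
    report.to_json(outdir / "report.json")
    return report
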
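# Methods

This note documents the models, numerical conventions and design choices
behind `satkit`, in the spirit of a methods appendix.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Satellite DNA characterization starts from a candidate monomer (here a
~687 bp centromeric repeat of sirenians, built from two diverged internal
subunits) and an assembly, and asks: where are the tandem arrays, what is
the consensus monomer, what internal and higher-order structure does it
have, does it carry CENP-B-box-like motifs, which monomer regions are
conserved, and do monomers cluster by species?  Every stage below is
deterministic given its inputs and an integer seed.

## Sequence primitives

**Alignment.** Global pairwise alignment is Needleman–Wunsch with affine
gaps, scored match +1, mismatch −1, gap open −2, gap extend −1 (a gap of
length L costs −2 −(L−1)); end gaps are penalized.  These simple scores are
transparent and configurable; the optimal score is verified in tests
against exhaustive enumeration of all alignments for sequences up to length
6.  Among co-optimal alignments, one deterministic traceback is returned
(biopython's `PairwiseAligner` enumeration order), so all downstream
results are reproducible.

**Identity.** Two denominators are exposed because published identity
figures rarely state gap handling: `columns` (matches / all alignment
columns, gap columns counted as mismatches — the default everywhere) and
`ungapped` (matches / columns where neither sequence is gapped).  A match
always requires identical unambiguous bases; IUPAC ambiguity codes count as
mismatches in every identity computed by the package.  This convention is
forced by the motif arithmetic: a W shared between two motifs must count as
a difference for the published cross-species counts to be reproducible.

**Dotplots.** The dotplot is ungapped: a hit at (i, j) means the two
windows (default 50 bp) agree at ≥ 60% of positions.  It is computed per
diagonal with a sliding match count, which is exactly equivalent to the
naive O(n·m·w) recount (tested).  Coordinates are 0-based half-open
internally and 1-based inclusive in all reports.

## Array detection

BLAST-style search is replaced by a self-contained seed-and-extend scheme:
exact 12-mers of the query (both strands) are located in the contigs via a
rolling 2-bit hash; each seed hit votes for a candidate unit start
(contig position − query position); votes are clustered (single linkage at
half the query length, cluster representative = modal start, ties to the
smallest).  Consecutive candidate starts delimit candidate units (falling
back to the query length where spacing is implausible); each unit is
verified by global alignment to the query at columns-identity ≥ 0.70.
Verified units separated by at most one query length merge into arrays;
arrays need ≥ 2 units.  `seed_k = 12` keeps seeds abundant at the ≤ 15%
per-copy divergence regime this targets (at 10% substitution an expected
~28% of query 12-mers survive intact in each copy).  A subunit dimer or
other HOR discontinuity can phase-shift the unit grid and split an array
in two; this is reported as-is rather than bridged.

The assembly-wide satellite fraction is the summed array span divided by
the summed contig length — an assembly-side surrogate for read-based
abundance estimates, reported as such.

## Star alignment and the MCS

Monomer copies are aligned by a deterministic star alignment: the center is
the medoid under edlib edit distance to a fixed probe subset (≤ 10
monomers at evenly spaced indices), every other monomer is globally aligned
to the center, and center-relative insertions are merged column-
consistently (left-aligned, padded to the maximum insertion length at each
center position).  A star alignment is exact for substitution-only
divergence and adequate at the ≤ 2% indel rates typical of young satellite
families; it trades some optimality in indel-rich regions for bit-for-bit
reproducibility, which a heuristic progressive aligner cannot give.
Pre-aligned FASTA is accepted wherever an alignment is consumed.

The most common sequence (MCS) uses a 25% plurality floor: per column,
drop the column if its gap fraction exceeds 0.5 (keeps the MCS length
comparable to the monomer length); otherwise emit the plurality
unambiguous base if its frequency among non-gap characters is ≥ the
threshold, else `N`; plurality ties break alphabetically.  The rule is
echoed into the consensus JSON so consumers need not guess the semantics.

## Internal duplication and split point

Off-diagonal self-dotplot hits are clustered into diagonal bands (offsets
within half a window; positional chaining with gaps up to 4 windows —
generous because windows over a ~56%-identical duplication clear a 60%
threshold only sporadically; offsets below one window are ignored as
self-overlap).  For each band the diagonal offset d is the modal hit
offset.  Band extent alone localizes the duplication poorly at high
divergence, so the duplicated region is located by a change-point
estimator: the per-position equality profile eq[i] = [seq[i] = seq[i+d]]
has elevated mean inside the in-register region (~1 − divergence) versus
background (~0.25); the maximal-sum subarray of eq − m, with m the midpoint
between background and the window threshold, estimates the region [a0, r),
giving segment_a = [a0, a0+d), segment_b = [a0+d, r+d) and the split at
a0 + d.  The reported identity of the pair comes from a global alignment
of the two segments.  At ~45% subunit divergence this recovers a planted
split at position 333 within ±15 bp for most seeds; the acceptance script
therefore reports the *median* split over 7 independently built monomers.
Only direct (same-strand) duplications are considered; inverted repeats
are out of scope.

## Period estimation

The repeat period comes from the self-dotplot of an array: off-diagonal
offsets are clustered into diagonals, diagonals with less than half the
support of the strongest are discarded, and the period is the modal
spacing between consecutive surviving diagonals (smallest on ties).  The
support filter matters for two-subunit monomers: cross-subunit similarity
creates weak diagonals at the half-period which would otherwise masquerade
as the fundamental period.

## HOR annotation

Each ordered unit is labeled by the subunit consensus (A or B) with the
higher global-alignment identity, provided it reaches 0.50; ties and
sub-floor units get `U`.  The 0.50 floor sits below the winning identity
(≥ ~0.85 at ≤ 10% per-copy mutation) but above the cross-subunit identity
(~0.56) and far above random (~0.25).  The label string is summarized as a
run-length encoding plus adjacent-pair counts (alternating AB/BA pairs,
AA and BB dimers) and maximal runs per label.  In the pipeline, monomer
units are cut into subunit-scale segments by mapping the MCS split point
through a global alignment of each unit to the MCS.

## Motif scanning

The CENP-B box is scored positionally (ungapped).  For a 17 bp window and
a pattern of nine defined positions there is no meaningful gap model, and
positional scoring is the only reading that exactly reproduces the
published sirenian counts (6/9, 5/9 ECD matches; 14/17 and 15/17
cross-species sharing).  Pattern codes other than N are matched by IUPAC
set membership of an unambiguous window base; ambiguity in the window
never matches.  The default reporting floor is 5 of 9 ECD positions, the
weakest agreement still treated as a reportable box in this family.  Both
strands are scanned; minus-strand hits report the reverse-complemented
(motif-forward) window at forward-strand coordinates.

## Diversity, distances, trees

**π.** Within each sliding window (10 bp, step 1 bp), columns containing
any gap or ambiguity in any row are excluded (DnaSP-like behavior);
π = Σ pairwise differences / (n_pairs × usable sites).  Windows with zero
usable sites are excluded from the across-window mean and SD (population
SD, ddof 0) rather than entered as 0, which would bias the ±2 SD
thresholds.  Classification is strict: conserved iff π < mean − 2 SD,
variable iff π > mean + 2 SD; with SD = 0 everything is neutral.

**Distances.** "Substitutions per site" is read as the uncorrected
p-distance — the only choice reproducible without a model assumption —
with pairwise deletion by default (per pair, sites where both rows are
unambiguous) or complete deletion on request.  Group (species) summaries
report within-group means (missing, not zero, for singleton groups),
between-group means per pair, and the overall mean over the strict upper
triangle.  Note that distances are measured on the multiple alignment;
at ~20% cross-group divergence the star alignment can inflate
within-group distances slightly relative to direct pairwise comparison
(about +0.01 on a within-group p-distance of 0.06 in the simulated
concerted regime).

**Neighbor joining.** Saitou–Nei agglomeration with the standard Q
criterion; ties on Q break to the smallest (i, j) pair in working order;
negative branch lengths are clamped to 0; the result is unrooted
(trifurcating root).  Tests check exact reproduction of additive matrices
and topological agreement with an independent NJ implementation
(scikit-bio) over random matrices up to n = 7.

**Bootstrap.** Replicates resample alignment columns with replacement to
the original width, driven by a single NumPy generator seeded from the
user seed; draws depend only on column indices, so supports are invariant
to taxon order.  A replicate in which some pair has no comparable site is
discarded and counted.  Support of each internal bipartition of the
full-data tree is the fraction of kept replicates containing it; Newick
output writes supports as internal-node labels on the 0–100 scale, and
branch lengths to 6 decimals.

## The simulator

`simulate_satdna` generates the study conditions end-to-end from one seed
(one NumPy stream, draws consumed in a fixed order: monomer, array
segments in pattern order, background, monomer set, species sets):

- **Monomer**: subunit A is drawn at 54.5% AT (the AT content of the
  family this emulates); subunit B starts from A extended to 355 bp and is
  substituted at the fixed rate 1 − target identity, redrawing until the
  realized global-alignment identity of A vs B is within ±0.03 of the
  target (default 0.558, the published subunit identity).  Substituting at
  the analytic rate pins the *in-register* identity at the target; chasing
  the alignment identity with a higher rate instead would let gap-driven
  matches mask a lower positional identity and starve the dotplot stages.
  Motif 17-mers are written verbatim at monomer positions 196 and 518
  after mutation.
- **Arrays**: the HOR pattern grammar (`(AB)x13 + BB + (AB)x12` by
  default — 25 alternating AB monomers plus one BB dimer, echoing the
  "mostly alternating with occasional subunit dimers/runs" organization)
  expands to a segment list; each segment is an independently mutated copy
  of its subunit (default 5% substitutions, 0.2% indels of geometric mean
  length 3).  Arrays are placed on one contig each with alternating
  strands, inside random background sized so the satellite occupies 0.87%
  of the assembly (the published genome fraction of the emulated family).
- **Monomer set**: 66 copies of the monomer at 2% substitutions (matching
  the 66-monomer consensus experiment this emulates).
- **Species sets**: under `library`, every species draws copies from the
  same pool (each copy mutated from the ancestor at 20%, chosen so the
  expected overall pairwise p-distance is ≈ 0.34); under `concerted`,
  each species first fixes its own consensus (18% from the ancestor) and
  copies diverge only 3% from it (expected within-species d ≈ 0.06).
  The two modes make the "do monomers cluster by species?" question a
  recovery property with known truth: concerted yields species-
  monophyletic NJ clusters, library does not.
- **Truth manifest**: JSON with the ancestral monomer, subunits, realized
  subunit identity, per-segment intervals, sequences and realized mutation
  counts, strands, motif positions and species assignments; every interval
  extracts from the emitted contigs to exactly the recorded sequence
  (tested).

What the simulator does *not* model: coalescent-realistic evolution,
transposable-element insertions, sequencing error, or assembly collapse of
arrays.  Passing tests on simulated data therefore demonstrate correctness
of the algorithms under the stated generative model, not performance on
raw short-read assemblies, where array collapse and chimerism add error
modes outside this package's control.

## Problem sizes and degenerate inputs

The default test and acceptance workloads are desk-scale by design: ~2 Mb
simulated contigs per array for detection, 50–66 monomers for consensus
and diversity, 60 taxa for trees, 100–500 bootstrap replicates, and period
estimation capped at the first 10 kb of an array.  Degenerate inputs are
handled explicitly: empty FASTA, duplicate ids and non-nucleotide residues
raise format errors naming the record; zero detected arrays aborts the
pipeline with a distinct exit status after writing the partial report;
windows with no usable sites, singleton species groups and discarded
bootstrap replicates are reported as missing/counted rather than silently
zeroed.
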
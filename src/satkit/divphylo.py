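"""Sliding-window nucleotide diversity, p-distances, neighbor joining.

Diversity (pi) is computed DnaSP-style over a monomer alignment: within
each window, columns containing any gap or ambiguity are excluded, and pi
is the mean per-site pairwise difference over the usable sites.  Windows
are classified conserved / variable when pi falls strictly more than two
standard deviations below / above the across-window mean.

Distances are uncorrected p-distances ("number of base substitutions per
site" with no model correction), with pairwise or complete deletion of
gapped/ambiguous sites.  Trees are built with the Saitou-Nei
neighbor-joining agglomeration, deterministic tie-breaking and clamping of
negative branch lengths; bootstrap support resamples alignment columns.
Tree containers are scikit-bio ``TreeNode`` objects; Newick is the
interchange format, with supports written as internal-node labels on a
0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from skbio import TreeNode

from .consensus import Alignment

__all__ = [
    "DiversityProfile",
    "DistanceMatrix",
    "PhyloTree",
    "GroupDivergence",
    "sliding_pi",
    "classify_windows",
    "p_distance_matrix",
    "group_divergence",
    "neighbor_joining",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class DiversityProfile:
    """Window-pi track over an alignment, with optional class labels.

    ``starts`` are 1-based window starts; ``pi`` is NaN for windows with
    zero usable sites (those windows are excluded from mean/SD and never
    classified).  ``classes`` entries are 'conserved' / 'neutral' /
    'variable', or None before classification / for undefined windows.
    """

    starts: tuple
    window: int
    step: int
    sites_used: tuple
    pi: tuple
    mean: float
    sd: float
    classes: tuple = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(np.asarray(self.pi))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tsites_used\tpi\tclass\n")
            classes = self.classes or (None,) * len(self.starts)
            for s, n, p, c in zip(self.starts, self.sites_used, self.pi, classes):
                pv = "NA" if np.isnan(p) else f"{p:.6f}"
                fh.write(f"{s}\t{n}\t{pv}\t{c or 'NA'}\n")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with optional group labels."""

    labels: tuple
    matrix: np.ndarray
    groups: Optional[dict] = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("negative distances")
        object.__setattr__(self, "matrix", m)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


@dataclass(frozen=True)
class GroupDivergence:
    """Within/between-group mean distances; groups with < 2 members have
    no within-group value (None, reported as missing rather than zero)."""

    within: dict
    between: dict
    overall: float


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and bootstrap supports.

    ``tree`` is a scikit-bio TreeNode whose root has (up to) three
    children, the usual unrooted convention.  ``supports`` maps canonical
    bipartitions (frozenset of the smaller leaf-name side) to a fraction in
    [0, 1]; on Newick output supports become internal-node labels scaled
    to 0-100.
    """

    tree: TreeNode
    supports: dict = None
    n_discarded_replicates: int = 0

    @property
    def leaf_names(self) -> tuple:
        return tuple(sorted(t.name for t in self.tree.tips()))

    def bipartitions(self) -> set:
        """Non-trivial bipartitions as canonical frozensets of leaf names."""
        all_names = frozenset(t.name for t in self.tree.tips())
        parts = set()
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_names) - 2:
                parts.add(_canonical(side, all_names))
        return parts


def _canonical(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


# ---------------------------------------------------------------------------
# Encoding helpers

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """(n_rows, n_columns) int8 codes: A..T -> 0..3, gap/ambiguity -> 4."""
    return _CODE[
        np.frombuffer("".join(alignment.rows).encode("ascii"), dtype=np.uint8)
    ].reshape(alignment.n_rows, alignment.n_columns)


# ---------------------------------------------------------------------------
# Sliding-window diversity


def sliding_pi(alignment: Alignment, window: int = 10, step: int = 1) -> DiversityProfile:
    """Sliding-window nucleotide diversity over an alignment.

    Within each window, columns with any gap or ambiguity in any row are
    excluded; pi = (sum over pairs of per-site differences) /
    (n_pairs * usable_sites).  Windows with zero usable sites get NaN and
    do not enter the across-window mean/SD.
    """
    if alignment.n_rows < 2:
        raise ValueError("need >= 2 rows")
    L = alignment.n_columns
    if window > L:
        raise ValueError("window wider than alignment")
    codes = encode_alignment(alignment)
    n = alignment.n_rows
    valid = (codes < 4).all(axis=0)
    base_counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    # pairwise differences per column: (n^2 - sum_b c_b^2) / 2
    diffs = (n * n - (base_counts.astype(np.int64) ** 2).sum(axis=0)) // 2
    diffs = np.where(valid, diffs, 0)
    n_pairs = n * (n - 1) // 2
    cs_valid = np.concatenate([[0], np.cumsum(valid)])
    cs_diffs = np.concatenate([[0], np.cumsum(diffs)])
    starts0 = np.arange(0, L - window + 1, step)
    sites = cs_valid[starts0 + window] - cs_valid[starts0]
    total = cs_diffs[starts0 + window] - cs_diffs[starts0]
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(sites > 0, total / (n_pairs * np.maximum(sites, 1)), np.nan)
    defined = pi[~np.isnan(pi)]
    mean = float(defined.mean()) if defined.size else float("nan")
    sd = float(defined.std(ddof=0)) if defined.size else float("nan")
    return DiversityProfile(
        starts=tuple(int(s) + 1 for s in starts0),
        window=window,
        step=step,
        sites_used=tuple(int(s) for s in sites),
        pi=tuple(float(p) for p in pi),
        mean=mean,
        sd=sd,
    )


def classify_windows(profile: DiversityProfile) -> DiversityProfile:
    """Label windows conserved / neutral / variable against mean +/- 2 SD.

    Strict inequalities: conserved iff pi < mean - 2 SD, variable iff
    pi > mean + 2 SD, otherwise neutral.  With SD = 0 everything is
    neutral.  Requires >= 3 defined windows.
    """
    pi = np.asarray(profile.pi)
    defined = ~np.isnan(pi)
    if defined.sum() < 3:
        raise ValueError("need >= 3 defined windows to classify")
    lo = profile.mean - 2 * profile.sd
    hi = profile.mean + 2 * profile.sd
    classes = []
    for p in profile.pi:
        if np.isnan(p):
            classes.append(None)
        elif p < lo:
            classes.append("conserved")
        elif p > hi:
            classes.append("variable")
        else:
            classes.append("neutral")
    return replace(profile, classes=tuple(classes))


# ---------------------------------------------------------------------------
# p-distances


def _pairwise_counts(codes: np.ndarray):
    """(matches, comparable) over pairs via one-hot matrix products."""
    onehot = np.stack([(codes == b) for b in range(4)]).astype(np.float64)
    matches = np.einsum("bij,bkj->ik", onehot, onehot)
    validf = (codes < 4).astype(np.float64)
    comparable = validf @ validf.T
    return matches, comparable


def p_distance_matrix(
    alignment: Alignment,
    deletion: str = "pairwise",
    groups: Optional[dict] = None,
) -> DistanceMatrix:
    """Uncorrected p-distances between all alignment rows.

    ``deletion='pairwise'`` uses, per pair, the sites where both rows carry
    unambiguous bases; ``'complete'`` restricts all pairs to columns
    unambiguous in every row.  A pair with zero comparable sites is an
    error.
    """
    codes = encode_alignment(alignment)
    if deletion == "complete":
        codes = codes[:, (codes < 4).all(axis=0)]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    matches, comparable = _pairwise_counts(codes)
    off = ~np.eye(len(codes), dtype=bool)
    if np.any(comparable[off] == 0):
        raise ValueError("a sequence pair has zero comparable sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 1.0 - matches / np.maximum(comparable, 1)
    np.fill_diagonal(p, 0.0)
    p = np.clip((p + p.T) / 2.0, 0.0, None)  # symmetrize exactly
    return DistanceMatrix(labels=tuple(alignment.ids), matrix=p, groups=groups)


def group_divergence(dm: DistanceMatrix) -> GroupDivergence:
    """Mean within-group, between-group and overall pairwise distances."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    groups = dm.groups or {lab: "all" for lab in dm.labels}
    glabels = sorted(set(groups.values()))
    iu = np.triu_indices(n, k=1)
    overall = float(dm.matrix[iu].mean())
    garr = np.array([groups[lab] for lab in dm.labels])
    within = {}
    for g in glabels:
        idx = np.nonzero(garr == g)[0]
        if len(idx) < 2:
            within[g] = None
            continue
        sub = dm.matrix[np.ix_(idx, idx)]
        within[g] = float(sub[np.triu_indices(len(idx), k=1)].mean())
    between = {}
    for a_i, ga in enumerate(glabels):
        for gb in glabels[a_i + 1:]:
            ia = np.nonzero(garr == ga)[0]
            ib = np.nonzero(garr == gb)[0]
            if len(ia) and len(ib):
                between[(ga, gb)] = float(dm.matrix[np.ix_(ia, ib)].mean())
    return GroupDivergence(within=within, between=between, overall=overall)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is joined each round; ties go to
    the smallest (i, j) index pair in current working order.  Negative
    branch lengths are clamped to zero.  The returned tree is unrooted
    (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.matrix.copy()
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        Q[np.tril_indices(r)] = np.inf  # scan i < j only
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        i, j = min((int(a), int(b)) for a, b in ties)
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, float(li))
        child_j.length = max(0.0, float(lj))
        new = TreeNode(children=[child_i, child_j])
        dn = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dn[keep]
        D2[:-1, -1] = dn[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        node.length = max(0.0, float(length))
    root = TreeNode(children=list(nodes))
    return PhyloTree(tree=root, supports=None)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 500,
    seed: int = 0,
    deletion: str = "pairwise",
) -> PhyloTree:
    """Column-resampling bootstrap supports on the full-data NJ tree.

    Each replicate resamples alignment columns with replacement to the
    original width, recomputes p-distances and the NJ tree; the support of
    each internal bipartition of the full-data tree is the fraction of
    kept replicate trees containing it.  Replicates in which some pair has
    no comparable site are discarded and counted.  Column draws are driven
    purely by column indices, so supports do not depend on taxon order.
    """
    full_dm = p_distance_matrix(alignment, deletion=deletion)
    full_tree = neighbor_joining(full_dm)
    parts = full_tree.bipartitions()
    codes = encode_alignment(alignment)
    L = codes.shape[1]
    rng = np.random.default_rng(seed)
    counts = {p: 0 for p in parts}
    kept = 0
    discarded = 0
    labels = tuple(alignment.ids)
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        sub = codes[:, cols]
        matches, comparable = _pairwise_counts(sub)
        off = ~np.eye(len(labels), dtype=bool)
        if np.any(comparable[off] == 0):
            discarded += 1
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 1.0 - matches / np.maximum(comparable, 1)
        np.fill_diagonal(p, 0.0)
        p = np.clip((p + p.T) / 2.0, 0.0, None)
        rep_tree = neighbor_joining(DistanceMatrix(labels=labels, matrix=p))
        rep_parts = rep_tree.bipartitions()
        kept += 1
        for part in parts:
            if part in rep_parts:
                counts[part] += 1
    supports = {p: (counts[p] / kept if kept else float("nan")) for p in parts}
    _attach_supports(full_tree, supports)
    full_tree.supports = supports
    full_tree.n_discarded_replicates = discarded
    return full_tree


def _attach_supports(ptree: PhyloTree, supports: dict) -> None:
    universe = frozenset(t.name for t in ptree.tree.tips())
    for node in ptree.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(universe) - 2:
            s = supports.get(_canonical(side, universe))
            if s is not None:
                node.name = _format_support(s)


def _format_support(fraction: float) -> str:
    v = fraction * 100.0
    return str(int(round(v))) if abs(v - round(v)) < 1e-9 else f"{v:.4g}"


# ---------------------------------------------------------------------------
# Newick I/O (supports as internal-node labels, 0-100)


def write_newick(ptree: PhyloTree, path) -> None:
    """Write a tree as Newick; branch lengths to 6 decimals, supports as
    internal-node labels (iTOL-compatible dialect)."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            label = "".join(
                ["(", ",".join(render(c) for c in node.children), ")",
                 node.name or ""]
            )
        if node.length is not None:
            label += f":{node.length:.6f}"
        return label

    with open(path, "w") as fh:
        fh.write(render(ptree.tree) + ";\n")


def read_newick(path) -> PhyloTree:
    """Read a Newick tree; numeric internal labels become supports.

    Labels in (1, 100] are interpreted on the 0-100 scale and divided by
    100; labels already in [0, 1] are taken as fractions.
    """
    tree = TreeNode.read(str(path), format="newick")
    if tree.length is None:
        tree.length = None
    universe = frozenset(t.name for t in tree.tips())
    supports = {}
    for node in tree.non_tips(include_self=False):
        if node.name is None:
            continue
        try:
            v = float(node.name)
        except ValueError:
            continue
        frac = v / 100.0 if v > 1.0 else v
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(universe) - 2:
            supports[_canonical(side, universe)] = frac
    return PhyloTree(tree=tree, supports=supports or None)
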
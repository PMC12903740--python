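"""Concatenated-protein distance phylogeny with bootstrap supports.

The pipeline mirrors the classic quick-tree recipe for multi-protein
phylogenies: align each conserved protein family (progressive alignment
guided by a UPGMA tree over pairwise global-alignment distances),
filter uninformative alignment columns (gap-tolerant columns in
sufficiently long clean blocks, in the spirit of GBlocks), concatenate
families into a supermatrix, compute pairwise distances (p-distance or
its Poisson correction −ln(1−p)), infer a neighbor-joining tree, and
attach bootstrap supports from seeded column resampling.

Neighbor joining reconstructs any additive (tree-like) distance matrix
exactly, which is the workhorse guarantee the tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GAP = "-"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class EmptyAlignmentError(ValueError):
    """Column filtering removed every column."""


@dataclass
class Alignment:
    """Named, equal-length aligned rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows are not equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    family_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """Rows as a (taxa x columns) byte matrix, taxa in listed order."""
        return np.array([list(self.rows[t].encode()) for t in self.taxa],
                        dtype=np.uint8)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Unrooted tree stored with an arbitrary root; supports live on nodes."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def postorder(self) -> Iterable["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def newick(self, with_support: bool = True) -> str:
        return self._newick_inner(with_support, top=True) + ";"

    def _newick_inner(self, with_support: bool, top: bool = False) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.branch_length:g}"
        inner = ",".join(c._newick_inner(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:g}"
        if top:
            return f"({inner}){label}"
        return f"({inner}){label}:{self.branch_length:g}"


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the leaf side not
    containing the alphabetically first taxon."""
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaves())
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            continue
        if anchor in side:
            side = all_leaves - side
        parts.add(side)
    return parts


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Symmetric-difference (Robinson-Foulds) distance between two
    unrooted trees over the same leaf set."""
    if set(tree_a.leaves()) != set(tree_b.leaves()):
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


# ---------------------------------------------------------------------------
# Family alignment
# ---------------------------------------------------------------------------

def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _aligned_pair(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[str, str]:
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def _consensus(profile: list[str]) -> str:
    """Per-column majority residue (ties alphabetical; all-gap column -> X)."""
    out = []
    for j in range(len(profile[0])):
        counts: dict[str, int] = {}
        for row in profile:
            c = row[j]
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("X")
        else:
            out.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(out)


def _inject_gaps(profile: list[str], aligned_consensus: str) -> list[str]:
    """Copy gaps introduced into a profile's consensus back into each row."""
    rows = ["" for _ in profile]
    src = 0
    for c in aligned_consensus:
        if c == GAP:
            for i in range(len(rows)):
                rows[i] += GAP
        else:
            for i, row in enumerate(profile):
                rows[i] += row[src]
            src += 1
    return rows


def align_family(seqs: Mapping[str, str]) -> Alignment:
    """Progressive multiple alignment of one protein family.

    Pairwise global alignments (BLOSUM62, affine 11/1 gaps) give identity
    distances; a UPGMA guide tree orders profile merges, each realized by
    globally aligning the two profiles' consensus sequences and copying
    the induced gaps into the member rows. Taxa are canonicalized by name
    first, so the result is independent of input order.
    """
    if len(seqs) < 2:
        raise ValueError("align_family requires at least 2 sequences")
    names = sorted(seqs)
    aligner = _pairwise_aligner()

    if len(set(len(seqs[n]) for n in names)) == 1 and len(set(seqs.values())) == 1:
        return Alignment(names, [seqs[n] for n in names])

    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = _aligned_pair(aligner, seqs[names[i]], seqs[names[j]])
            ident = sum(a == b for a, b in zip(ra, rb) if a != GAP and b != GAP)
            comparable = sum(1 for a, b in zip(ra, rb) if a != GAP and b != GAP)
            d = 1.0 - (ident / comparable if comparable else 0.0)
            dist[i, j] = dist[j, i] = d

    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [seqs[names[i]]]) for i in range(n)
    }
    next_id = n
    for left, right, _, _ in linkage:
        la, ra = profiles.pop(int(left))
        lb, rb = profiles.pop(int(right))
        ca, cb = _consensus(ra), _consensus(rb)
        aligned_ca, aligned_cb = _aligned_pair(aligner, ca, cb)
        merged_rows = _inject_gaps(ra, aligned_ca) + _inject_gaps(rb, aligned_cb)
        profiles[next_id] = (la + lb, merged_rows)
        next_id += 1

    merged_names, merged_rows = profiles.popitem()[1]
    order = [merged_names.index(name) for name in names]
    return Alignment(names, [merged_rows[i] for i in order])


def filter_columns(aln: Alignment, max_gap_fraction: float = 0.0,
                   min_block_length: int = 10) -> Alignment:
    """Keep columns with gap fraction <= ``max_gap_fraction`` that lie in
    runs of at least ``min_block_length`` qualifying columns.

    Raises :class:`EmptyAlignmentError` when nothing survives.
    """
    ncols = aln.n_columns
    nrows = len(aln.rows)
    qualifies = [
        sum(1 for row in aln.rows if row[j] == GAP) / nrows <= max_gap_fraction
        for j in range(ncols)
    ]
    keep = [False] * ncols
    j = 0
    while j < ncols:
        if not qualifies[j]:
            j += 1
            continue
        k = j
        while k < ncols and qualifies[k]:
            k += 1
        if k - j >= min_block_length:
            for idx in range(j, k):
                keep[idx] = True
        j = k
    if not any(keep):
        raise EmptyAlignmentError("no columns survive filtering")
    rows = ["".join(row[j] for j in range(ncols) if keep[j]) for row in aln.rows]
    return Alignment(list(aln.names), rows)


def build_supermatrix(family_alignments: Mapping[str, Alignment],
                      taxa: Sequence[str]) -> Supermatrix:
    """Concatenate family alignments over a shared taxon set; taxa absent
    from a family are gap-padded across that family's block."""
    taxa = list(taxa)
    rows = {t: "" for t in taxa}
    boundaries: dict[str, tuple[int, int]] = {}
    offset = 0
    for family_id in sorted(family_alignments):
        aln = family_alignments[family_id]
        width = aln.n_columns
        for t in taxa:
            rows[t] += aln.row(t) if t in aln.names else GAP * width
        boundaries[family_id] = (offset, offset + width)
        offset += width
    return Supermatrix(taxa, rows, boundaries)


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def distances(sm: Supermatrix, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances over columns where neither taxon has a gap.

    ``p_distance`` is the mismatch proportion; ``poisson`` applies the
    correction −ln(1−p).
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    if len(sm.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    mat = sm.matrix()
    gap_code = ord(GAP)
    n = len(sm.taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != gap_code) & (mat[j] != gap_code)
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(
                    f"no comparable columns between {sm.taxa[i]!r} and {sm.taxa[j]!r}"
                )
            p = float((mat[i][ok] != mat[j][ok]).sum()) / n_ok
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("saturated distance (p = 1)")
                d = -np.log(1.0 - p)
            else:
                d = p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(sm.taxa), out)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic Saitou-Nei neighbor joining.

    Deterministic: among equal Q values the lexicographically smallest
    node-index pair wins. Negative branch lengths are clamped to zero
    with the deficit moved to the sister edge, so path lengths between
    the joined leaves are preserved.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.values.astype(float).copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int) -> None:
        nonlocal d, active, nodes
        i, j = active[i_pos], active[j_pos]
        m = len(active)
        r = d[np.ix_(active, active)].sum(axis=1)
        dij = d[i, j]
        li = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new_node = TreeNode(children=[child_i, child_j])
        new_index = len(nodes)
        nodes.append(new_node)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[new_index, k] = d[k, new_index] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_index]

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        join(best[1], best[2])

    # final three-way join at a central node
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = max(0.0, 0.5 * (dij + dik - djk))
    lj = max(0.0, 0.5 * (dij + djk - dik))
    lk = max(0.0, 0.5 * (dik + djk - dij))
    for idx, ln in zip((i, j, k), (li, lj, lk)):
        nodes[idx].branch_length = ln
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def bootstrap_support(sm: Supermatrix, n_replicates: int = 100,
                      seed: int = 0, model: str = "poisson",
                      block_bootstrap: bool = False) -> TreeNode:
    """NJ tree on the full supermatrix with bootstrap supports attached.

    Columns (or whole family blocks when ``block_bootstrap``) are
    resampled with replacement per replicate; the support of each
    internal edge of the reference tree is the percentage of replicates
    whose NJ tree contains the same bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    reference = neighbor_joining(distances(sm, model))
    ref_parts = bipartitions(reference)
    counts = {part: 0 for part in ref_parts}
    rng = np.random.default_rng(seed)
    mat = sm.matrix()
    ncols = sm.n_columns

    for _ in range(n_replicates):
        if block_bootstrap and sm.family_boundaries:
            blocks = sorted(sm.family_boundaries.values())
            chosen = rng.integers(0, len(blocks), size=len(blocks))
            cols = np.concatenate(
                [np.arange(blocks[b][0], blocks[b][1]) for b in chosen])
        else:
            cols = rng.integers(0, ncols, size=ncols)
        resampled = Supermatrix(
            list(sm.taxa),
            {t: bytes(mat[idx, cols]).decode()
             for idx, t in enumerate(sm.taxa)},
        )
        try:
            rep_tree = neighbor_joining(distances(resampled, model))
        except ValueError:
            continue  # saturated or incomparable replicate carries no signal
        rep_parts = bipartitions(rep_tree)
        for part in ref_parts:
            if part in rep_parts:
                counts[part] += 1

    all_leaves = frozenset(sm.taxa)
    anchor = min(all_leaves)
    for node in reference.postorder():
        if node is reference or node.is_leaf:
            continue
        side = frozenset(node.leaves())
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            continue
        key = all_leaves - side if anchor in side else side
        node.support = 100.0 * counts[key] / n_replicates
    return reference
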
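"""Pairwise identity, distance matrices, and neighbor-joining 16S trees.

Pairwise global alignment (affine gaps) gives percent identities for
arguments such as the <90% genus boundary and the near-identity of rRNA
operon copies.  From a pre-aligned sequence set, p-distances (pairwise gap
deletion) or Jukes-Cantor corrected distances feed the Saitou-Nei
neighbor-joining agglomeration; bootstrap support comes from resampling
alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from skbio import TreeNode


@dataclass
class AlignedPair:
    seq_a_gapped: str
    seq_b_gapped: str
    score: float

    def __post_init__(self):
        if len(self.seq_a_gapped) != len(self.seq_b_gapped):
            raise ValueError("gapped sequences differ in length")
        for a, b in zip(self.seq_a_gapped, self.seq_b_gapped):
            if a == "-" and b == "-":
                raise ValueError("column gapped in both rows")


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -5.0, gap_extend: float = -1.0) -> AlignedPair:
    """Optimal global alignment with affine gap penalties.

    A gap of length k scores ``gap_open + (k - 1) * gap_extend``.  The
    first optimal alignment in Biopython's deterministic enumeration order
    is returned (score is unique; the traceback tie-break is fixed).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.upper(), b.upper())
    best = aln[0]
    return AlignedPair(str(best[0]), str(best[1]), float(best.score))


def percent_identity(pair: AlignedPair,
                     gap_mode: str = "exclude_gap_columns") -> float:
    """Matches over compared columns x 100.

    The default drops columns containing a gap or N from the comparison;
    ``include_gaps`` counts them as compared (mismatching) columns.
    """
    matches = 0
    compared = 0
    for x, y in zip(pair.seq_a_gapped, pair.seq_b_gapped):
        gappy = "-" in (x, y) or "N" in (x, y)
        if gap_mode == "exclude_gap_columns" and gappy:
            continue
        compared += 1
        if x == y and x != "-":
            matches += 1
    if compared == 0:
        raise ValueError("no compared columns; identity undefined")
    return 100.0 * matches / compared


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def _pairwise_p(a: str, b: str) -> float:
    diffs = 0
    compared = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue  # pairwise gap deletion
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable columns between two sequences")
    return diffs / compared


def distance_matrix(aligned_seqs, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances from a pre-aligned set of (label, sequence).

    p_distance: mismatches over compared columns, pairwise gap deletion.
    jukes_cantor: d = -(3/4) ln(1 - 4p/3); saturated pairs (p >= 3/4)
    raise with both labels.
    """
    pairs = list(aligned_seqs)
    labels = [lab for lab, _ in pairs]
    seqs = [s.upper() for _, s in pairs]
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p(seqs[i], seqs[j])
            if model == "p_distance":
                dist = p
            elif model == "jukes_cantor":
                if p >= 0.75:
                    raise ValueError(
                        f"saturated pair ({labels[i]}, {labels[j]}): "
                        f"p = {p:.3f} >= 0.75, Jukes-Cantor undefined"
                    )
                dist = -0.75 * math.log1p(-4.0 * p / 3.0)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The pair minimizing the Q criterion is joined at each step, ties broken
    on the lowest (i, j) label-index pair.  A negative estimated branch
    length is clamped to 0 and the deficit moved to the sister branch, so
    path lengths through the new node are preserved.  The returned TreeNode
    has a trifurcating root (unrooted convention); all other internal nodes
    are binary.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = {i: TreeNode(name=str(lab)) for i, lab in enumerate(m.labels)}
    D = {(i, j): m.d[i, j] for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (len(active) - 2) * D[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[next_id, k] = D[k, next_id] = duk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def write_newick(tree: TreeNode, path) -> str:
    """Write newick with branch lengths at full precision; re-readable."""
    tree.write(str(path), format="newick")
    with open(path) as fh:
        return fh.read()


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def tip_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree, labels sorted."""
    dm = tree.tip_tip_distances()
    order = sorted(dm.ids)
    sub = dm.filter(order)
    return DistanceMatrix(list(sub.ids), sub.data.copy())


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of an unrooted tree, each as the smaller-or-
    lexicographically-first side's tip-name frozenset."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        splits.add(canon)
    return splits


def bootstrap_support(aligned_seqs, model: str = "jukes_cantor",
                      replicates: int = 100, seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap support (% of column-resampled replicates
    containing each internal split) as internal node names."""
    pairs = [(lab, s.upper()) for lab, s in aligned_seqs]
    tree = neighbor_joining(distance_matrix(pairs, model))
    length = len(pairs[0][1])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [
            (lab, "".join(s[c] for c in cols)) for lab, s in pairs
        ]
        try:
            rep = neighbor_joining(distance_matrix(resampled, model))
        except ValueError:
            continue  # saturated or degenerate replicate
        for split in _bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        node.name = str(round(100 * counts.get(canon, 0) / replicates))
    return tree
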
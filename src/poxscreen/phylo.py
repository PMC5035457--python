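"""Neighbour-joining protein phylogeny with Poisson-corrected distances.

Pairwise distances between aligned protein sequences use the Poisson
correction d = -ln(1 - p), where p is the proportion of differing sites
over the columns comparable for that pair (pairwise deletion by default;
complete deletion optionally).  Trees are built with the Saitou-Nei
neighbour-joining algorithm and reported unrooted (trifurcating root);
bipartition support comes from bootstrap resampling of alignment
columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


class PhyloError(ValueError):
    pass


@dataclass
class ProteinAlignment:
    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise PhyloError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise PhyloError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise PhyloError("aligned sequences must all have the same length")
        self.seqs = [s.upper() for s in self.seqs]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def resample_columns(self, idx: np.ndarray) -> "ProteinAlignment":
        return ProteinAlignment(
            list(self.ids), ["".join(s[i] for i in idx) for s in self.seqs]
        )

    @classmethod
    def from_fasta(cls, path: str) -> "ProteinAlignment":
        ids, seqs = [], []
        for rec in SeqIO.parse(path, "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        if not ids:
            raise PhyloError(f"{path}: no records")
        return cls(ids, seqs)


def _comparable(a: str, b: str) -> list[int]:
    return [i for i in range(len(a)) if a[i] in AA20 and b[i] in AA20]


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance -ln(1-p) with pairwise deletion.

    Columns where either sequence has a gap or an ambiguous residue
    (X/B/Z/...) are excluded from the comparison.
    """
    if len(a) != len(b):
        raise PhyloError("sequences must be aligned to equal length")
    sites = _comparable(a, b)
    if not sites:
        raise PhyloError("no comparable sites between the two sequences")
    p = sum(a[i] != b[i] for i in sites) / len(sites)
    if p >= 1.0:
        raise PhyloError("saturated pair (p >= 1); distance undefined")
    return -math.log(1.0 - p)


def alignment_distance_matrix(
    aln: ProteinAlignment, deletion: str = "pairwise"
) -> DistanceMatrix:
    """All pairwise Poisson distances as a skbio DistanceMatrix."""
    if deletion not in ("pairwise", "complete"):
        raise PhyloError("deletion must be 'pairwise' or 'complete'")
    seqs = aln.seqs
    if deletion == "complete":
        keep = [
            i
            for i in range(aln.n_columns)
            if all(s[i] in AA20 for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = poisson_distance(seqs[i], seqs[j])
    return DistanceMatrix(mat, ids=aln.ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; unrooted tree with a trifurcating root.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties are broken by the lexicographically smallest index pair.
    Negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch so the pair's path length is kept.
    """
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise PhyloError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 3:
        raise PhyloError("need at least three taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin implements the smallest-(i,j) tie break
        i, j = divmod(int(np.argmin(q)), n)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d[i, :] = dnew
        d[:, i] = dnew
        d[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = parent
        nodes.pop(j)
        n -= 1
    # resolve the final three around an unrooted trifurcation
    x = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    y = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    z = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, length in zip(nodes, (x, y, z)):
        node.length = max(length, 0.0)
        root.append(node)
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, canonicalized against a reference tip."""
    tips = {t.name for t in tree.tips()}
    ref = min(tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips) - len(side) < 2:
            continue
        if ref in side:
            side = frozenset(tips - side)
        parts.add(side)
    return parts


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Bootstrap column resampling; percent recovery of original bipartitions.

    Replicates in which some pair becomes uncomparable or saturated are
    skipped and logged; supports are percentages of completed replicates.
    The returned tree carries supports as internal-node names.
    """
    tree = nj_tree(alignment_distance_matrix(aln, deletion))
    original = _bipartitions(tree)
    counts = {b: 0 for b in original}
    rng = np.random.default_rng(seed)
    completed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, aln.n_columns, aln.n_columns)
        try:
            rep_tree = nj_tree(
                alignment_distance_matrix(aln.resample_columns(idx), deletion)
            )
        except PhyloError as exc:
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        completed += 1
        rep_parts = _bipartitions(rep_tree)
        for b in original:
            if b in rep_parts:
                counts[b] += 1
    if completed == 0:
        raise PhyloError("no bootstrap replicate completed")
    support = {b: 100.0 * c / completed for b, c in counts.items()}
    tips = {t.name for t in tree.tips()}
    ref = min(tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(tips - side)
        if side in support:
            node.name = f"{support[side]:.0f}"
    return tree, support


def write_newick(tree: TreeNode, path: str) -> None:
    tree.write(path)


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator, min_branch: float = 0.05, max_branch: float = 1.0
) -> tuple[TreeNode, DistanceMatrix]:
    """A random unrooted binary tree and its exact additive distance matrix.

    Used as an independent oracle: neighbour joining must reconstruct the
    generating topology (and branch lengths) from the matrix.
    """
    if n_taxa < 4:
        raise PhyloError("need at least four taxa for a non-trivial topology")
    ids = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=i) for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_branch, max_branch))
        b.length = float(rng.uniform(min_branch, max_branch))
        parent = TreeNode()
        parent.extend([a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for nd in nodes:
        nd.length = float(rng.uniform(min_branch, max_branch))
        root.append(nd)
    dm = root.tip_tip_distances()
    mat = DistanceMatrix(dm.data, ids=list(dm.ids))
    return root, mat
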
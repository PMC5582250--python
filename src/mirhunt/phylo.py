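"""Pairwise alignment, identity distances and neighbor-joining trees.

Family members are related by all-pairs global alignment identity; the
resulting ``1 - identity`` distances feed a Saitou-Nei neighbor-joining
reconstruction.  NJ is exact on additive matrices: path lengths on the
returned tree reproduce the input distances to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io_formats import SequenceRecord, ValidationError

logger = logging.getLogger(__name__)

MATCH = 1
MISMATCH = -1
GAP = -2


@njit(cache=True)
def _nw_fill(a, b, match, mismatch, gap):  # pragma: no cover - via pairwise_align
    m, n = a.shape[0], b.shape[0]
    score = np.zeros((m + 1, n + 1), np.int64)
    ptr = np.zeros((m + 1, n + 1), np.uint8)  # 1 diag, 2 up, 3 left
    for i in range(1, m + 1):
        score[i, 0] = i * gap
        ptr[i, 0] = 2
    for j in range(1, n + 1):
        score[0, j] = j * gap
        ptr[0, j] = 3
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = score[i - 1, j] + gap
            l = score[i, j - 1] + gap
            best, p = d, 1
            if u > best:
                best, p = u, 2
            if l > best:
                best, p = l, 3
            score[i, j] = best
            ptr[i, j] = p
    return score, ptr


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: int
    identity: float


def pairwise_align(a: str, b: str, match: int = MATCH, mismatch: int = MISMATCH,
                   gap: int = GAP) -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment.

    Identity is the fraction of alignment columns that are exact matches.
    Tie-breaking prefers diagonal, then up, then left moves, so the
    alignment is deterministic.
    """
    if not a or not b:
        raise ValidationError("cannot align empty sequences")
    ca = np.frombuffer(a.encode(), dtype=np.uint8).astype(np.int64)
    cb = np.frombuffer(b.encode(), dtype=np.uint8).astype(np.int64)
    score, ptr = _nw_fill(ca, cb, match, mismatch, gap)
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 1:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 2:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
    aa = "".join(reversed(ra))
    ab = "".join(reversed(rb))
    matches = sum(1 for x, y in zip(aa, ab) if x == y and x != "-")
    return Alignment(aa, ab, int(score[len(a), len(b)]), matches / len(aa))


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(self.d < -1e-12) or np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("distances must be non-negative with zero diagonal")


def identity_distance(records: list[SequenceRecord]) -> DistanceMatrix:
    """All-pairs ``1 - identity`` distances from global alignments."""
    if len(records) < 3:
        raise ValidationError("need at least 3 sequences for a distance matrix")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(records[i].residues, records[j].residues)
            d[i, j] = d[j, i] = 1.0 - aln.identity
    return DistanceMatrix([r.id for r in records], d)


@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(f"{c._newick()}:{ln:.10g}" for c, ln in self.children)
        return f"({inner}){self.name}"

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class Tree:
    """Unrooted tree (serialized with a trifurcating root node)."""

    root: TreeNode

    def newick(self) -> str:
        return self.root.newick()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths along tree branches."""
        dists: dict[tuple[str, str], float] = {}

        def below(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf():
                return [(node.name, 0.0)]
            groups = []
            for child, blen in node.children:
                sub = [(name, d + blen) for name, d in below(child)]
                for other in groups:
                    for na, da in sub:
                        for nb, db in other:
                            key = (min(na, nb), max(na, nb))
                            dists[key] = da + db
                groups.append(sub)
            return [x for g in groups for x in g]

        below(self.root)
        return dists

    def ascii(self) -> str:
        lines: list[str] = []

        def draw(node: TreeNode, prefix: str) -> None:
            label = node.name or "*"
            lines.append(prefix + label)
            for child, blen in node.children:
                draw(child, prefix + f"  |-{blen:.3f}- ")

        draw(self.root, "")
        return "\n".join(lines)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken toward the smallest (i, j) index pair in the
    current node ordering.  Negative branch-length estimates are clamped to
    zero (logged); this is the usual practical convention.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    D = dm.d.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("clamping negative NJ branch length %.3g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        totals = D.sum(axis=1)
        Q = (m - 2) * D - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = smallest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = D2
    # terminal 3-node star: closed-form branch lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return Tree(root=root)
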
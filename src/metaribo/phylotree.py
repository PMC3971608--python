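"""Distance-based phylogeny over the concatenated ribosomal-protein
alignment, with bootstrap support and nearest-reference classification.

Trees are built by Saitou-Nei neighbor joining on protein p-distances
(pairwise deletion of gap/missing columns, since concatenated rows carry
whole missing partitions).  Bootstrap support resamples alignment columns
with replacement and reports, per internal bipartition of the point-estimate
tree, the percentage of replicate trees containing it.  Taxonomic placement
of a query row is by minimum p-distance to labelled references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import GAP, MISSING, MultipleAlignment

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "pdistance",
    "nj",
    "bootstrap_support",
    "classify",
]

MIN_PAIR_COLUMNS = 10
FLAG_PAIR_COLUMNS = 50


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("diagonal must be zero")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and non-negative")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.values[i, j])


@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree: the root is a trifurcation (or the final NJ join)."""

    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each represented by the side not containing
        the lexicographically first leaf (rooting-invariant)."""
        all_leaves = frozenset(self.root.leaves())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = all_leaves - below if ref in below else below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def to_newick(self, digits: int = 6) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{digits}g}"

        def walk(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{fmt(node.length)}"
            inner = ",".join(walk(ch) for ch in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{fmt(node.length)}"

        return walk(self.root) + ";"


# ---------------------------------------------------------------------------


def _comparable(row1: np.ndarray, row2: np.ndarray) -> np.ndarray:
    ok1 = (row1 != GAP) & (row1 != MISSING)
    ok2 = (row2 != GAP) & (row2 != MISSING)
    return ok1 & ok2


def pdistance(aln: MultipleAlignment, min_overlap: int = FLAG_PAIR_COLUMNS) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion.

    d(i, j) = mismatches / compared columns over columns where both taxa have
    residues.  Pairs with fewer than ``min_overlap`` comparable columns are
    flagged; fewer than 10 is an error naming the pair.
    """
    n = len(aln.names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    M = aln.matrix
    vals = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = _comparable(M[i], M[j])
            n_ok = int(ok.sum())
            if n_ok < MIN_PAIR_COLUMNS:
                raise ValueError(
                    f"pair ({aln.names[i]}, {aln.names[j]}) shares only {n_ok} comparable columns"
                )
            if n_ok < min_overlap:
                flagged.append((aln.names[i], aln.names[j]))
            d = float((M[i][ok] != M[j][ok]).sum()) / n_ok
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(taxa=list(aln.names), values=vals, flagged_pairs=flagged)


def nj(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    The Q-matrix minimum is joined at each step, ties broken by the
    lexicographically smallest (sorted) taxon-name pair; negative branch
    lengths are clamped to zero with a warning.
    """
    n = len(dist.taxa)
    if n < 4:
        raise ValueError("neighbor joining requires at least 4 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dist.taxa]
    labels: list[str] = list(dist.taxa)  # tie-break identity of each working node
    D = dist.values.copy()
    clamped = False

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in zip(*np.where(np.isclose(Q, qmin)))
            if i < j
        ]
        _key, i, j = min(candidates)
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final trifurcating root
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    if min(la, lb, lc) < 0:
        clamped = True
    a.length, b.length, c.length = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    return Tree(root=TreeNode(children=[a, b, c]))


def bootstrap_support(
    aln: MultipleAlignment, n_reps: int = 100, seed: int = 0,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Point-estimate NJ tree with column-resampling bootstrap supports.

    Each replicate resamples alignment columns with replacement (same
    width), recomputes p-distances, and rebuilds the NJ tree; the support of
    each internal bipartition of the point tree is the percentage of
    replicates containing it.  With ``n_reps`` = 0 supports are absent.
    """
    point = nj(pdistance(aln))
    if n_reps == 0:
        return point, {}
    rng = np.random.default_rng(seed)
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}
    width = aln.width
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep = MultipleAlignment(names=list(aln.names), matrix=aln.matrix[:, cols])
        try:
            rep_tree = nj(pdistance(rep))
        except ValueError:
            continue  # a replicate can lose all comparable columns for a pair
        rep_bips = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bips:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    _annotate_supports(point, supports)
    return point, supports


def _annotate_supports(tree: Tree, supports: dict[frozenset[str], float]) -> None:
    all_leaves = frozenset(tree.root.leaves())
    ref = min(all_leaves)

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(walk(ch) for ch in node.children))
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            side = all_leaves - below if ref in below else below
            if side in supports:
                node.support = supports[side]
        return below

    walk(tree.root)


def classify(
    query: str | np.ndarray,
    references: MultipleAlignment,
    taxa: dict[str, str],
    min_overlap: int = FLAG_PAIR_COLUMNS,
) -> tuple[str | None, float | None, float | None]:
    """Nearest-reference taxonomic placement of an aligned query row.

    Returns (taxon, distance, margin); margin is second-best minus best
    distance.  A tie between references of different taxa, or fewer than
    ``min_overlap`` comparable columns against every reference, gives
    (None, ..., ...) — unclassified.
    """
    q = np.asarray(list(query) if isinstance(query, str) else query, dtype="<U1")
    if q.shape[0] != references.width:
        raise ValueError("query must be aligned to the reference columns")
    dists = []
    for name, row in zip(references.names, references.matrix):
        ok = _comparable(q, row)
        n_ok = int(ok.sum())
        if n_ok < min_overlap:
            continue
        dists.append((float((q[ok] != row[ok]).sum()) / n_ok, name))
    if not dists:
        return None, None, None
    dists.sort()
    best_d, best_name = dists[0]
    margin = (dists[1][0] - best_d) if len(dists) > 1 else None
    if len(dists) > 1 and np.isclose(dists[1][0], best_d) and taxa[dists[1][1]] != taxa[best_name]:
        return None, best_d, 0.0
    return taxa[best_name], best_d, margin
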
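"""Progressive multiple alignment of protein families, column masking, and
partitioned concatenation.

The aligner is a compact progressive scheme: pairwise k-mer distances feed a
UPGMA guide tree, and profiles are merged by affine-gap (Gotoh)
Needleman-Wunsch on profile columns scored with BLOSUM62.  It targets the
scale this pipeline needs — tens of ribosomal-protein sequences per family —
not genome-scale alignment.

Alignment columns use "-" for gaps; concatenated matrices use "?" for whole
partitions missing from a taxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io_formats import SequenceSet

__all__ = [
    "MultipleAlignment",
    "ConcatAlignment",
    "align_family",
    "pairwise_align_score",
    "mask_columns",
    "concatenate",
    "GAP",
    "MISSING",
]

GAP = "-"
MISSING = "?"

_AA = "ARNDCQEGHILKMFPSTWYV"  # BLOSUM62 ordering used internally


def _blosum62() -> tuple[np.ndarray, dict[str, int]]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    idx = {a: i for i, a in enumerate(_AA)}
    S = np.zeros((len(_AA), len(_AA)))
    for a in _AA:
        for b in _AA:
            S[idx[a], idx[b]] = mat[a, b]
    return S, idx


_BLOSUM_CACHE: tuple[np.ndarray, dict[str, int]] | None = None


def _matrix() -> tuple[np.ndarray, dict[str, int]]:
    global _BLOSUM_CACHE
    if _BLOSUM_CACHE is None:
        _BLOSUM_CACHE = _blosum62()
    return _BLOSUM_CACHE


@dataclass
class MultipleAlignment:
    """Equal-width aligned rows; ungapping any row returns its input."""

    names: list[str]
    matrix: np.ndarray  # (n_rows, width) of single characters

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise ValueError("alignment matrix shape does not match names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names in alignment")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.names)

    def row(self, name: str) -> str:
        return "".join(self.matrix[self.names.index(name)])

    def ungapped(self, name: str) -> str:
        return self.row(name).replace(GAP, "").replace(MISSING, "")

    def to_sequence_set(self) -> SequenceSet:
        return SequenceSet(
            records=[(n, "", "".join(r)) for n, r in zip(self.names, self.matrix)],
            alphabet="aa",
        )


@dataclass
class ConcatAlignment:
    """Concatenation of per-family alignments with partition bookkeeping."""

    alignment: MultipleAlignment
    partitions: list[tuple[str, int, int]]  # (family, start, end) 0-based half-open

    def partition_presence(self, name: str) -> int:
        """Number of partitions for which this taxon has real residues."""
        row = self.alignment.matrix[self.alignment.names.index(name)]
        n = 0
        for _fam, a, b in self.partitions:
            if not np.all(row[a:b] == MISSING):
                n += 1
        return n


# ---------------------------------------------------------------------------
# profile-profile Needleman-Wunsch with affine gaps (Gotoh)

_NEG = -1e30


def _profile(matrix: np.ndarray, idx: dict[str, int]) -> np.ndarray:
    """Column residue-frequency profile (gap mass excluded, renormalized)."""
    n_aa = len(_AA)
    prof = np.zeros((matrix.shape[1], n_aa))
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        for c in col:
            if c in idx:
                prof[j, idx[c]] += 1.0
        tot = prof[j].sum()
        if tot > 0:
            prof[j] /= tot
    return prof


def _gotoh_profile(
    A: np.ndarray, B: np.ndarray, S: np.ndarray, gap_open: float, gap_extend: float,
) -> tuple[float, list[tuple[int, int]]]:
    """Global affine-gap DP over profile columns.

    Returns the optimal score and a traceback path of (i, j) moves where
    i/j = 1 means consuming a column of A/B.  Gap costs: ``gap_open`` for the
    first gapped column, ``gap_extend`` for each subsequent one.
    """
    la, lb = A.shape[0], B.shape[0]
    colscore = A @ S @ B.T  # (la, lb) expected substitution score
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        cs = colscore[i - 1]
        best_prev = np.maximum(np.maximum(Mi1, Xi1), Yi1)
        Xi[:] = np.maximum(
            np.maximum(Mi1, Yi1) - gap_open, Xi1 - gap_extend
        )
        Mi[1:] = best_prev[:-1] + cs
        # Y is sequential along j
        for j in range(1, lb + 1):
            Yi[j] = max(Mi[j - 1] - gap_open, Xi[j - 1] - gap_open, Yi[j - 1] - gap_extend)
    score = max(M[la, lb], X[la, lb], Y[la, lb])
    # traceback
    path: list[tuple[int, int]] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0:  # M
            path.append((1, 1))
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:  # X: consumed A[i-1]
            path.append((1, 0))
            cand = [M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open]
            i -= 1
            state = int(np.argmax(cand))
        else:  # Y: consumed B[j-1]
            path.append((0, 1))
            cand = [M[i, j - 1] - gap_open, X[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend]
            j -= 1
            state = int(np.argmax(cand))
    path.reverse()
    return float(score), path


def _merge(
    a: MultipleAlignment, b: MultipleAlignment, S: np.ndarray, idx: dict[str, int],
    gap_open: float, gap_extend: float,
) -> MultipleAlignment:
    _score, path = _gotoh_profile(_profile(a.matrix, idx), _profile(b.matrix, idx), S, gap_open, gap_extend)
    cols_a, cols_b = [], []
    ia = ib = 0
    for da, db in path:
        cols_a.append(a.matrix[:, ia] if da else np.full(len(a), GAP))
        cols_b.append(b.matrix[:, ib] if db else np.full(len(b), GAP))
        ia += da
        ib += db
    mat = np.vstack([np.column_stack(cols_a), np.column_stack(cols_b)])
    return MultipleAlignment(names=a.names + b.names, matrix=mat)


def _kmer_distance(s1: str, s2: str, k: int = 3) -> float:
    k1 = {s1[i : i + k] for i in range(max(1, len(s1) - k + 1))}
    k2 = {s2[i : i + k] for i in range(max(1, len(s2) - k + 1))}
    if not k1 or not k2:
        return 1.0
    return 1.0 - len(k1 & k2) / min(len(k1), len(k2))


def pairwise_align_score(
    seq1: str, seq2: str, gap_open: float = 11.0, gap_extend: float = 1.0,
) -> float:
    """Global pairwise alignment score under BLOSUM62 with affine gaps
    (first gapped position costs ``gap_open``, each further one
    ``gap_extend``)."""
    S, idx = _matrix()
    a = MultipleAlignment(names=["a"], matrix=np.array([list(seq1)]))
    b = MultipleAlignment(names=["b"], matrix=np.array([list(seq2)]))
    score, _path = _gotoh_profile(_profile(a.matrix, idx), _profile(b.matrix, idx), S, gap_open, gap_extend)
    return score


def align_family(
    seqs: SequenceSet, gap_open: float = 11.0, gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Progressive multiple alignment of one protein family.

    Pairwise 3-mer distances -> UPGMA guide tree -> profile-profile merges in
    guide-tree order.  A single sequence is returned unchanged as a
    width-L alignment.
    """
    if seqs.alphabet != "aa":
        raise ValueError("align_family expects amino-acid sequences")
    names = seqs.ids()
    if len(names) == 1:
        rid, _d, s = seqs.records[0]
        return MultipleAlignment(names=[rid], matrix=np.array([list(s)]))
    S, idx = _matrix()
    singles = {
        rid: MultipleAlignment(names=[rid], matrix=np.array([list(s)]))
        for rid, _d, s in seqs
    }
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _kmer_distance(seqs.records[i][2], seqs.records[j][2])
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, MultipleAlignment] = {i: singles[names[i]] for i in range(n)}
    for step, (ci, cj, _d, _cnt) in enumerate(Z):
        merged = _merge(clusters.pop(int(ci)), clusters.pop(int(cj)), S, idx, gap_open, gap_extend)
        clusters[n + step] = merged
    (aln,) = clusters.values()
    # restore input row order
    order = [aln.names.index(nm) for nm in names]
    return MultipleAlignment(names=names, matrix=aln.matrix[order])


# ---------------------------------------------------------------------------
# masking and concatenation


def mask_columns(
    aln: MultipleAlignment,
    max_gap_frac: float = 0.5,
    trim_terminal: bool = True,
    reference_rows: list[str] | None = None,
) -> tuple[MultipleAlignment, list[int]]:
    """Automated surrogate for manual alignment curation.

    With ``trim_terminal``, leading/trailing columns that are gaps in at
    least one designated reference row (default: every row) are removed;
    interior columns with gap fraction strictly above ``max_gap_frac`` are
    removed.  Returns the masked alignment and the retained-column map.
    """
    mat = aln.matrix
    width = aln.width
    keep = np.ones(width, dtype=bool)
    refs = reference_rows if reference_rows is not None else aln.names
    ref_idx = [aln.names.index(r) for r in refs]
    if trim_terminal and ref_idx:
        any_gap = (mat[ref_idx] == GAP).any(axis=0)
        lead = 0
        while lead < width and any_gap[lead]:
            lead += 1
        trail = width
        while trail > lead and any_gap[trail - 1]:
            trail -= 1
        keep[:lead] = False
        keep[trail:] = False
    gap_frac = (mat == GAP).mean(axis=0)
    keep &= ~(gap_frac > max_gap_frac)
    if not keep.any():
        raise ValueError("masking removed every column")
    column_map = [int(j) for j in np.flatnonzero(keep)]
    return MultipleAlignment(names=aln.names, matrix=mat[:, keep]), column_map


def concatenate(
    family_alignments: dict[str, MultipleAlignment],
    family_order: list[str],
    min_partitions: int = 8,
) -> ConcatAlignment:
    """Concatenate per-family alignments into one partitioned matrix.

    Partitions follow ``family_order``; a taxon missing a family receives the
    missing symbol "?" across that partition; taxa present in fewer than
    ``min_partitions`` families are dropped (the >= 8-of-16 retention rule).
    """
    taxa: list[str] = []
    for fam in family_order:
        if fam not in family_alignments:
            continue
        fam_names = family_alignments[fam].names
        if len(set(fam_names)) != len(fam_names):
            raise ValueError(f"duplicate taxon within family {fam}")
        for nm in fam_names:
            if nm not in taxa:
                taxa.append(nm)
    present = {
        nm: sum(1 for fam in family_order if fam in family_alignments and nm in family_alignments[fam].names)
        for nm in taxa
    }
    kept = [nm for nm in taxa if present[nm] >= min_partitions]
    if not kept:
        raise ValueError("no taxon passes the minimum-partition rule")
    blocks, partitions = [], []
    offset = 0
    for fam in family_order:
        if fam not in family_alignments:
            continue
        fam_aln = family_alignments[fam]
        w = fam_aln.width
        block = np.full((len(kept), w), MISSING, dtype="<U1")
        for r, nm in enumerate(kept):
            if nm in fam_aln.names:
                block[r] = fam_aln.matrix[fam_aln.names.index(nm)]
        blocks.append(block)
        partitions.append((fam, offset, offset + w))
        offset += w
    matrix = np.hstack(blocks)
    return ConcatAlignment(
        alignment=MultipleAlignment(names=kept, matrix=matrix),
        partitions=partitions,
    )
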
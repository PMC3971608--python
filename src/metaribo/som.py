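"""Emergent self-organizing map over tetranucleotide vectors.

Classic online Kohonen training: per input, the best-matching unit (BMU) is
found by Euclidean distance and the neighbourhood is pulled toward the input
with a Gaussian kernel; learning rate and radius decay linearly to
(0.01, 1) over the training run.  The map is toroidal by default — large
enough maps let genome clusters "emerge" as U-matrix valleys, which
:func:`harvest_components` extracts as connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SOMap", "train_som", "umatrix", "smoothed_umatrix", "bmu_indices",
    "harvest_components",
]

FINAL_LR = 0.01
FINAL_RADIUS = 1.0


@dataclass
class SOMap:
    weights: np.ndarray          # (rows*cols, dim)
    rows: int
    cols: int
    toroidal: bool = True
    training_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows * self.cols != self.weights.shape[0]:
            raise ValueError("weights do not match grid shape")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_rc(self, node: int) -> tuple[int, int]:
        return divmod(node, self.cols)


def _grid_sq_distances(rows: int, cols: int, toroidal: bool) -> np.ndarray:
    """(n, n) squared grid distances between all node pairs."""
    r = np.arange(rows * cols) // cols
    c = np.arange(rows * cols) % cols
    dr = np.abs(r[:, None] - r[None, :])
    dc = np.abs(c[:, None] - c[None, :])
    if toroidal:
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    return (dr ** 2 + dc ** 2).astype(np.float64)


def bmu_indices(som: SOMap, vectors: np.ndarray) -> np.ndarray:
    """Best-matching unit (flat node index) for each vector."""
    w2 = (som.weights ** 2).sum(axis=1)
    d = w2[None, :] - 2.0 * vectors @ som.weights.T
    return np.asarray(d.argmin(axis=1))


def quantization_error(som: SOMap, vectors: np.ndarray) -> float:
    bmus = bmu_indices(som, vectors)
    return float(np.sqrt(((vectors - som.weights[bmus]) ** 2).sum(axis=1)).mean())


def train_som(
    vectors: np.ndarray,
    rows: int = 50,
    cols: int = 50,
    epochs: int = 20,
    lr0: float = 0.5,
    radius0: float | None = None,
    toroidal: bool = True,
    seed: int = 0,
) -> SOMap:
    """Train a Kohonen map on row vectors; deterministic given ``seed``.

    ``radius0`` defaults to max(rows, cols)/4.  The training log records the
    learning rate, radius, and quantization error at each epoch end.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or len(vectors) < 10:
        raise ValueError("need at least 10 input vectors")
    if not np.isfinite(vectors).all():
        raise ValueError("input vectors contain NaN/inf")
    if rows < 10 or cols < 10:
        raise ValueError("grid must be at least 10x10")
    if rows * cols < 4 * len(vectors):
        warnings.warn(
            f"grid of {rows * cols} nodes is below 4x the {len(vectors)} inputs; "
            "cluster structure may not emerge cleanly",
            stacklevel=2,
        )
    radius0 = radius0 if radius0 is not None else max(rows, cols) / 4.0
    rng = np.random.default_rng(seed)
    n_nodes = rows * cols
    lo = vectors.min(axis=0)
    hi = vectors.max(axis=0)
    weights = rng.uniform(lo, hi, size=(n_nodes, vectors.shape[1]))
    grid_d2 = _grid_sq_distances(rows, cols, toroidal)
    som = SOMap(weights=weights, rows=rows, cols=cols, toroidal=toroidal)
    total_steps = max(epochs * len(vectors) - 1, 1)
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(len(vectors))
        for i in order:
            t = step / total_steps
            lr = lr0 + (FINAL_LR - lr0) * t
            radius = radius0 + (FINAL_RADIUS - radius0) * t
            v = vectors[i]
            d = ((weights - v) ** 2).sum(axis=1)
            bmu = int(d.argmin())
            h = np.exp(-grid_d2[bmu] / (2.0 * radius * radius))
            weights += (lr * h)[:, None] * (v - weights)
            step += 1
        som.training_log.append(
            {"epoch": epoch, "lr": lr, "radius": radius,
             "quantization_error": quantization_error(som, vectors)}
        )
    return som


def umatrix(som: SOMap) -> np.ndarray:
    """Per-node mean Euclidean distance to its (up to 8) grid neighbours."""
    W = som.weights.reshape(som.rows, som.cols, -1)
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    acc = np.zeros((som.rows, som.cols))
    cnt = np.zeros((som.rows, som.cols))
    for dr, dc in shifts:
        shifted = np.roll(np.roll(W, dr, axis=0), dc, axis=1)
        d = np.sqrt(((W - shifted) ** 2).sum(axis=2))
        if som.toroidal:
            acc += d
            cnt += 1.0
        else:
            valid = np.ones((som.rows, som.cols), dtype=bool)
            if dr == 1:
                valid[0, :] = False
            elif dr == -1:
                valid[-1, :] = False
            if dc == 1:
                valid[:, 0] = False
            elif dc == -1:
                valid[:, -1] = False
            acc[valid] += d[valid]
            cnt[valid] += 1.0
    return acc / np.maximum(cnt, 1.0)


def _neighbors(node: int, rows: int, cols: int, toroidal: bool):
    r, c = divmod(node, cols)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nr, nc = r + dr, c + dc
            if toroidal:
                nr %= rows
                nc %= cols
            elif not (0 <= nr < rows and 0 <= nc < cols):
                continue
            yield nr * cols + nc


def smoothed_umatrix(som: SOMap, passes: int = 2) -> np.ndarray:
    """U-matrix after ``passes`` rounds of 3x3 mean smoothing.

    Raw U-matrices are speckled; displayed ESOM surfaces are smoothed, and
    valley extraction needs the same treatment or one genome's basin
    fragments into several components.
    """
    from scipy.ndimage import uniform_filter

    U = umatrix(som)
    for _ in range(passes):
        U = uniform_filter(U, size=3, mode="wrap" if som.toroidal else "nearest")
    return U


def harvest_components(
    som: SOMap, valley_percentile: float = 30.0, smooth_passes: int = 2,
) -> tuple[np.ndarray, int]:
    """Label U-matrix valley nodes by connected component (8-adjacency,
    toroidal when the map is).

    Nodes with smoothed U-value strictly below the ``valley_percentile``
    threshold form the mask; returns (labels, n_components) with -1 for
    off-mask nodes.
    """
    U = smoothed_umatrix(som, smooth_passes).ravel()
    thresh = np.percentile(U, valley_percentile)
    mask = U < thresh
    labels = np.full(som.n_nodes, -1, dtype=int)
    current = 0
    for start in range(som.n_nodes):
        if not mask[start] or labels[start] != -1:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            node = stack.pop()
            for nb in _neighbors(node, som.rows, som.cols, som.toroidal):
                if mask[nb] and labels[nb] == -1:
                    labels[nb] = current
                    stack.append(nb)
        current += 1
    return labels, current
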
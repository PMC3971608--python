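"""Tetranucleotide-signature binning, bin curation, and single-copy-marker
completeness.

Scaffolds >= 5 kb are summarized as 136-dimensional canonical tetranucleotide
frequency vectors (reverse-complement 4-mer pairs collapsed), mapped with an
emergent self-organizing map, and harvested into genome bins from U-matrix
valleys — an automated surrogate for manual ESOM cluster delineation.  Bins
are curated to a consistent scaffold set by GC content, per-sample coverage
profile, and gene taxonomy, and scored for completeness against a suite of
76 single-copy marker genes, which also yields a genome-count estimate for
pooled scaffold sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from ._util import round_half_away
from .io_formats import CoverageTable
from .som import SOMap, bmu_indices, harvest_components, train_som, umatrix

__all__ = [
    "TetraVector",
    "GenomeBin",
    "CuratedBin",
    "tetra_vector",
    "tetra_vectors",
    "canonical_tetramers",
    "train_som",
    "umatrix",
    "harvest_bins",
    "curate_bin",
    "completeness",
    "estimate_genome_count",
    "N_CANONICAL_TETRAMERS",
]

N_CANONICAL_TETRAMERS = 136
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(kmer: str) -> str:
    return "".join(_COMP[b] for b in reversed(kmer))


def canonical_tetramers() -> list[str]:
    """The 136 canonical 4-mers (lexicographically smaller of self/revcomp)."""
    seen = []
    for kmer in ("".join(p) for p in product(_BASES, repeat=4)):
        canon = min(kmer, _revcomp(kmer))
        if canon not in seen:
            seen.append(canon)
    return seen


_CANON_LIST = canonical_tetramers()
_CANON_INDEX = {k: i for i, k in enumerate(_CANON_LIST)}


def _code_to_canon() -> np.ndarray:
    """Map each of the 256 4-mer codes to its canonical class index."""
    out = np.empty(256, dtype=np.int64)
    for code in range(256):
        kmer = "".join(_BASES[(code >> (2 * (3 - j))) & 3] for j in range(4))
        out[code] = _CANON_INDEX[min(kmer, _revcomp(kmer))]
    return out


_CODE_TO_CANON = _code_to_canon()


@dataclass
class TetraVector:
    scaffold_id: str
    freqs: np.ndarray  # (136,), non-negative, sums to 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape != (N_CANONICAL_TETRAMERS,):
            raise ValueError("tetra vector must have 136 entries")
        if (self.freqs < 0).any() or not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("tetra frequencies must be non-negative and sum to 1")


def tetra_vector(sequence: str, scaffold_id: str = "", min_len: int = 5000) -> TetraVector:
    """Canonical tetranucleotide frequency vector of one scaffold.

    Sliding 4-mer windows on one strand; windows containing an ambiguous base
    are skipped; each window counts toward its canonical class.
    """
    if len(sequence) < min_len:
        raise ValueError(f"sequence shorter than min_len={min_len}")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    enc = np.full(arr.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        enc[arr == b] = i
    e = enc.astype(np.int64)
    codes = e[:-3] * 64 + e[1:-2] * 16 + e[2:-1] * 4 + e[3:]
    valid = (enc[:-3] != 255) & (enc[1:-2] != 255) & (enc[2:-1] != 255) & (enc[3:] != 255)
    codes = codes[valid]
    if len(codes) == 0:
        raise ValueError("no unambiguous 4-mer windows in sequence")
    counts = np.bincount(_CODE_TO_CANON[codes], minlength=N_CANONICAL_TETRAMERS).astype(np.float64)
    return TetraVector(scaffold_id=scaffold_id, freqs=counts / counts.sum())


def tetra_vectors(scaffolds, min_len: int = 5000) -> tuple[list[str], np.ndarray]:
    """Tetra vectors for every scaffold of length >= min_len in a SequenceSet."""
    ids, rows = [], []
    for sid, _desc, seq in scaffolds:
        if len(seq) < min_len:
            continue
        ids.append(sid)
        rows.append(tetra_vector(seq, sid, min_len=min_len).freqs)
    return ids, np.vstack(rows) if rows else np.empty((0, N_CANONICAL_TETRAMERS))


# ---------------------------------------------------------------------------
# bins


@dataclass
class GenomeBin:
    bin_id: str
    scaffold_ids: list[str]
    tetra_centroid: np.ndarray | None = None
    gc_mean: float | None = None
    gc_sd: float | None = None
    coverage_profile: pd.DataFrame | None = None
    markers_found: frozenset[str] = frozenset()
    completeness_percent: float | None = None


@dataclass
class CuratedBin(GenomeBin):
    rejected: list[str] = field(default_factory=list)
    iterations: int = 0


def harvest_bins(
    som: SOMap,
    scaffold_ids: list[str],
    vectors: np.ndarray,
    valley_percentile: float = 30.0,
    min_scaffolds: int = 5,
    assign_all: bool = True,
    smooth_passes: int = 2,
) -> list[GenomeBin]:
    """Harvest genome bins from the U-matrix valleys of a trained map.

    Valley nodes (smoothed U below the ``valley_percentile`` threshold) are
    grouped into connected components; scaffolds inherit their BMU's
    component.  Components backing fewer than ``min_scaffolds`` scaffolds are
    dropped.  With ``assign_all``, scaffolds whose BMU sits outside the mask
    (or in a dropped component) are attached to the nearest kept component by
    grid distance; otherwise they stay unbinned.
    """
    labels, n_comp = harvest_components(som, valley_percentile, smooth_passes)
    if n_comp == 0:
        warnings.warn("no U-matrix valley components found; no bins", stacklevel=2)
        return []
    bmus = bmu_indices(som, vectors)
    assigned = labels[bmus].astype(int)
    comp_sizes = {c: int((assigned == c).sum()) for c in range(n_comp)}
    kept = sorted(c for c, n in comp_sizes.items() if n >= min_scaffolds)
    if not kept:
        warnings.warn("no component met the minimum scaffold count", stacklevel=2)
        return []
    keep_set = set(kept)
    orphan = ~np.isin(assigned, kept)
    if assign_all and orphan.any():
        rr = np.arange(som.n_nodes) // som.cols
        cc = np.arange(som.n_nodes) % som.cols
        kept_nodes = np.flatnonzero(np.isin(labels, kept))
        for i in np.flatnonzero(orphan):
            r0, c0 = divmod(int(bmus[i]), som.cols)
            dr = np.abs(rr[kept_nodes] - r0)
            dc = np.abs(cc[kept_nodes] - c0)
            if som.toroidal:
                dr = np.minimum(dr, som.rows - dr)
                dc = np.minimum(dc, som.cols - dc)
            nearest = kept_nodes[int((dr ** 2 + dc ** 2).argmin())]
            assigned[i] = labels[nearest]
    bins = []
    for comp in kept:
        member_idx = np.flatnonzero(assigned == comp)
        if not assign_all and len(member_idx) < min_scaffolds:
            continue
        bins.append(
            GenomeBin(
                bin_id=f"bin{len(bins):03d}",
                scaffold_ids=[scaffold_ids[i] for i in member_idx],
                tetra_centroid=vectors[member_idx].mean(axis=0),
            )
        )
    return bins


def gc_content(seq: str) -> float:
    s = seq.upper()
    atgc = sum(s.count(b) for b in "ACGT")
    return (s.count("G") + s.count("C")) / atgc if atgc else 0.0


def curate_bin(
    gbin: GenomeBin,
    scaffold_gc: dict[str, float],
    coverage: CoverageTable,
    scaffold_taxonomy: pd.DataFrame | None = None,
    gc_z_max: float = 2.0,
    cov_corr_min: float = 0.9,
    taxon: str | None = None,
    vote_min: float = 0.5,
) -> CuratedBin:
    """Iteratively remove outlier scaffolds until a fixed point.

    A scaffold is rejected when its GC z-score against the current bin
    exceeds ``gc_z_max``, when the Pearson correlation of its per-sample
    coverage profile to the bin's median profile falls below
    ``cov_corr_min``, or when its taxonomy vote contradicts the bin's taxon
    at a vote fraction >= ``vote_min``.  Statistics are recomputed after each
    pass; curation is idempotent.
    """
    matrix = coverage.matrix()
    contradicts: set[str] = set()
    if taxon is not None and scaffold_taxonomy is not None:
        for _, row in scaffold_taxonomy.iterrows():
            if (
                row.get("assigned_taxon")
                and row["assigned_taxon"] != taxon
                and row.get("vote_fraction", 0.0) >= vote_min
            ):
                contradicts.add(row["scaffold_id"])
    members = list(gbin.scaffold_ids)
    rejected: list[str] = []
    iterations = 0
    while True:
        iterations += 1
        gcs = np.array([scaffold_gc[s] for s in members])
        mu, sd = gcs.mean(), gcs.std()
        profiles = matrix.reindex(members).fillna(0.0)
        median_profile = profiles.median(axis=0).to_numpy()
        drop = []
        for i, s in enumerate(members):
            if s in contradicts:
                drop.append(s)
                continue
            if sd > 0 and abs(gcs[i] - mu) / sd > gc_z_max:
                drop.append(s)
                continue
            prof = profiles.loc[s].to_numpy()
            if len(prof) >= 2 and prof.std() > 0 and median_profile.std() > 0:
                corr = float(np.corrcoef(prof, median_profile)[0, 1])
                if corr < cov_corr_min:
                    drop.append(s)
        if not drop:
            break
        rejected.extend(drop)
        members = [s for s in members if s not in drop]
        if not members:
            raise ValueError(f"curation rejected every scaffold of {gbin.bin_id}")
    gcs = np.array([scaffold_gc[s] for s in members])
    return CuratedBin(
        bin_id=gbin.bin_id,
        scaffold_ids=members,
        tetra_centroid=gbin.tetra_centroid,
        gc_mean=float(gcs.mean()),
        gc_sd=float(gcs.std()),
        coverage_profile=matrix.reindex(members).fillna(0.0),
        rejected=rejected,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# single-copy markers


def completeness(
    gene_families: list[str], marker_list: list[str],
) -> tuple[int, float, int]:
    """(markers_found, percent, duplicated) for one bin's gene families.

    ``percent`` = 100 x distinct marker families present / len(marker_list);
    ``duplicated`` counts families present more than once (contamination
    signal).
    """
    if len(marker_list) != 76:
        warnings.warn(
            f"marker list has {len(marker_list)} families (expected 76); "
            "using it as the denominator",
            stacklevel=2,
        )
    markers = set(marker_list)
    counts: dict[str, int] = {}
    for fam in gene_families:
        if fam in markers:
            counts[fam] = counts.get(fam, 0) + 1
    found = len(counts)
    duplicated = sum(1 for v in counts.values() if v > 1)
    return found, 100.0 * found / len(marker_list), duplicated


def estimate_genome_count(
    gene_families: list[str], marker_list: list[str],
) -> tuple[float, int]:
    """Estimate how many genomes a pooled scaffold set represents.

    Counts each of the marker families' occurrences in the pool and returns
    the mean across all families plus its half-away-rounded integer.
    """
    counts = {fam: 0 for fam in marker_list}
    for fam in gene_families:
        if fam in counts:
            counts[fam] += 1
    mean = float(np.mean(list(counts.values()))) if marker_list else 0.0
    return mean, round_half_away(mean)
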
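"""Coverage normalization, the organism-abundance estimator, and
rank-abundance profiling.

The abundance model treats the anchor scaffold's read coverage as a proxy
for organism abundance:

    fraction = coverage x predicted_genome_size / dataset_bp

with predicted genome sizes of 3 Mbp in general and 1.5 Mbp for designated
small-genome lineages.  Coverages are made comparable across samples by
scaling each sample to the largest sample's read total.  Per-phylum summary
percentages are integerized half-away-from-zero; cross-depth ratios use
largest-remainder rounding so they sum to exactly 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from ._util import largest_remainder, round_half_away
from .io_formats import CoverageTable

__all__ = [
    "OrganismRecord",
    "RankAbundanceProfile",
    "normalize_coverage",
    "organism_fraction",
    "profile_organisms",
    "rank_profile",
    "pooled_fraction",
    "depth_ratio",
    "detection_floor",
    "SMALL_GENOME_PHYLA",
    "DEFAULT_GENOME_SIZE",
    "SMALL_GENOME_SIZE",
]

DEFAULT_GENOME_SIZE = 3_000_000
SMALL_GENOME_SIZE = 1_500_000
#: Candidate phyla with characteristically reduced genomes (1.5 Mbp).
SMALL_GENOME_PHYLA = frozenset({"OD-1", "OP-11"})


@dataclass
class OrganismRecord:
    """One rpS3-anchored lineage with its abundance vector."""

    lineage_id: str            # anchor scaffold id
    phylum: str
    coverage: dict[str, float]             # raw, per sample
    normalized_coverage: dict[str, float]  # read-total normalized
    fraction: dict[str, float]             # abundance fraction per sample
    predicted_genome_size: int = DEFAULT_GENOME_SIZE
    n_rp_families: int = 16


@dataclass
class RankAbundanceProfile:
    sample_id: str
    table: pd.DataFrame                    # ranked organisms, descending fraction
    phylum_counts: dict[str, int]
    phylum_percent: dict[str, int]

    @property
    def n_organisms(self) -> int:
        return len(self.table)


def normalize_coverage(cov: CoverageTable) -> CoverageTable:
    """Scale each sample's coverages by max(total_reads) / total_reads[sample].

    The deepest-sequenced sample is the reference and keeps its values; any
    reference choice yields identical cross-sample ratios.
    """
    totals = cov.totals
    if (totals["total_reads"] <= 0).any():
        raise ValueError("total_reads must be positive for every sample")
    ref = totals["total_reads"].max()
    factor = {row["sample_id"]: ref / row["total_reads"] for _, row in totals.iterrows()}
    out = cov.cov.copy()
    out["coverage"] = out["coverage"] * out["sample_id"].map(factor)
    return CoverageTable(cov=out, totals=totals.copy())


def organism_fraction(coverage: float, genome_size: float, dataset_bp: float) -> float:
    """Abundance fraction = coverage x genome_size / dataset_bp, clamped to 1."""
    if genome_size <= 0 or dataset_bp <= 0:
        raise ValueError("genome_size and dataset_bp must be positive")
    frac = coverage * genome_size / dataset_bp
    if frac > 1.0:
        warnings.warn(f"organism fraction {frac:.3g} > 1; clamping", stacklevel=2)
        frac = 1.0
    return frac


def detection_floor(
    min_cov: float = 0.2,
    genome_size: float = DEFAULT_GENOME_SIZE,
    dataset_bp: float = 3e9,
) -> float:
    """Smallest detectable abundance fraction given a minimum mappable
    coverage (default 0.2x)."""
    if min_cov <= 0 or genome_size <= 0 or dataset_bp <= 0:
        raise ValueError("all inputs must be positive")
    return min_cov * genome_size / dataset_bp


def profile_organisms(
    lineages: pd.DataFrame,
    cov: CoverageTable,
    dataset_bp: dict[str, float],
    phylum_of: dict[str, str] | None = None,
    small_genome_phyla: frozenset[str] = SMALL_GENOME_PHYLA,
    normalize: bool = False,
) -> list[OrganismRecord]:
    """Build organism records from lineage scaffolds and the coverage table.

    ``lineages`` needs columns ``scaffold_id``, ``phylum`` (or supply
    ``phylum_of``), and optionally ``n_rp_families``.  A lineage's coverage is
    its anchor scaffold's mean coverage in each sample.  Fractions are
    computed from raw coverage and each sample's own dataset size (the exact
    inverse of the coverage model); normalized coverages are carried for
    cross-sample ratio displays.
    """
    norm = normalize_coverage(cov) if normalize else cov
    records = []
    for _, row in lineages.iterrows():
        sid = row["scaffold_id"]
        phylum = row["phylum"] if "phylum" in row and pd.notna(row.get("phylum")) else (phylum_of or {}).get(sid, "unknown")
        gsize = SMALL_GENOME_SIZE if phylum in small_genome_phyla else DEFAULT_GENOME_SIZE
        raw = {s: cov.scaffold_coverage(sid, s) for s in cov.samples()}
        nrm = {s: norm.scaffold_coverage(sid, s) for s in cov.samples()}
        frac = {s: organism_fraction(raw[s], gsize, dataset_bp[s]) for s in cov.samples()}
        records.append(
            OrganismRecord(
                lineage_id=sid, phylum=phylum, coverage=raw,
                normalized_coverage=nrm, fraction=frac,
                predicted_genome_size=gsize,
                n_rp_families=int(row.get("n_rp_families", 16)),
            )
        )
    return records


def rank_profile(
    records: list[OrganismRecord], sample_id: str, min_rp: int = 8,
) -> RankAbundanceProfile:
    """Ranked abundance profile for one sample.

    Organisms with fewer than ``min_rp`` of the 16 ribosomal-protein families
    are excluded; the rest rank by descending fraction (ties by lineage id).
    Per-phylum percentages are round-half-away integers of
    100 x count / n_organisms.
    """
    kept = [r for r in records if r.n_rp_families >= min_rp]
    if not kept:
        raise ValueError("no organisms pass the ribosomal-protein filter")
    df = pd.DataFrame(
        {
            "lineage_id": [r.lineage_id for r in kept],
            "phylum": [r.phylum for r in kept],
            "fraction": [r.fraction[sample_id] for r in kept],
        }
    ).sort_values(["fraction", "lineage_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = range(1, len(df) + 1)
    counts = df["phylum"].value_counts().to_dict()
    n = len(df)
    percents = {p: round_half_away(100.0 * c / n) for p, c in counts.items()}
    return RankAbundanceProfile(
        sample_id=sample_id, table=df.reset_index(drop=True),
        phylum_counts={k: int(v) for k, v in counts.items()},
        phylum_percent=percents,
    )


def pooled_fraction(pairs: list[tuple[int, int]]) -> int:
    """Integer percent of a phylum pooled across samples:
    round_half_away(100 x sum(counts) / sum(n))."""
    if not pairs:
        raise ValueError("at least one (count, n) pair required")
    total_count = sum(c for c, _n in pairs)
    total_n = sum(n for _c, n in pairs)
    if total_n == 0:
        raise ValueError("total organism count is zero")
    return round_half_away(100.0 * total_count / total_n)


def depth_ratio(coverages: list[float]) -> tuple[int, ...]:
    """Cross-depth abundance ratio, integerized by largest remainder to sum
    exactly 100 (ties go to the earlier sample)."""
    if not coverages or all(c == 0 for c in coverages):
        raise ValueError("at least one positive coverage required")
    if any(c < 0 for c in coverages):
        raise ValueError("coverages must be non-negative")
    return largest_remainder(coverages, total=100)
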
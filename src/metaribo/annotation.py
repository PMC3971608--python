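"""Tiered functional annotation and per-scaffold taxonomy voting.

Annotations are ranked into four exclusive tiers, highest first:
reciprocal best matches (bit score >= 300), one-way matches (>= 60),
motif-only evidence, and bare gene predictions (hypothetical proteins).

A scaffold is assigned to a focal taxon when at least 40% of its predicted
genes have a best hit to that taxon; hypothetical genes count in the
denominator by default (configurable).  Threshold comparisons are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import HitTable

__all__ = [
    "AnnotationRecord",
    "ScaffoldTaxonomy",
    "RECIPROCAL_MIN_BITS",
    "ONE_WAY_MIN_BITS",
    "VOTE_THRESHOLD",
    "rank_annotation",
    "annotate_genes",
    "scaffold_vote",
    "vote_all_scaffolds",
    "select_taxon_scaffolds",
]

RECIPROCAL_MIN_BITS = 300.0
ONE_WAY_MIN_BITS = 60.0
VOTE_THRESHOLD = 0.40

TIERS = ("reciprocal", "one_way", "motif", "hypothetical")


@dataclass
class AnnotationRecord:
    gene_id: str
    tier: str
    best_subject: str | None = None
    bit_score: float | None = None
    subject_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "reciprocal" and (self.bit_score is None or self.bit_score < RECIPROCAL_MIN_BITS):
            raise ValueError("reciprocal tier requires bit score >= 300")
        if self.tier == "one_way" and (self.bit_score is None or self.bit_score < ONE_WAY_MIN_BITS):
            raise ValueError("one_way tier requires bit score >= 60")


@dataclass
class ScaffoldTaxonomy:
    scaffold_id: str
    votes: dict[str, int] = field(default_factory=dict)
    n_genes: int = 0
    assigned_taxon: str | None = None
    vote_fraction: float = 0.0
    flag: str | None = None


def _best_by_query(hits: HitTable) -> dict[str, pd.Series]:
    best = hits.best_hits()
    return {row["qseqid"]: row for _, row in best.iterrows()}


def rank_annotation(
    gene_id: str,
    forward: HitTable,
    reciprocal: HitTable,
    motifs: set[str] | None = None,
    taxon_map: dict[str, str] | None = None,
) -> AnnotationRecord:
    """Annotate one gene; see :func:`annotate_genes` for the batch form."""
    table = annotate_genes([gene_id], forward, reciprocal, motifs, taxon_map)
    row = table.iloc[0]
    return AnnotationRecord(
        gene_id=gene_id,
        tier=row["tier"],
        best_subject=row["best_subject"] if pd.notna(row["best_subject"]) else None,
        bit_score=row["bit_score"] if pd.notna(row["bit_score"]) else None,
        subject_taxon=row["subject_taxon"] if pd.notna(row["subject_taxon"]) else None,
    )


def annotate_genes(
    gene_ids: list[str],
    forward: HitTable,
    reciprocal: HitTable,
    motifs: set[str] | None = None,
    taxon_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tiered annotation for a set of genes.

    The first satisfied tier wins: the gene's best forward hit is reciprocal
    at >= 300 bits (the reciprocal table's best hit for that subject points
    back at the gene) -> ``reciprocal``; else a forward hit >= 60 bits ->
    ``one_way``; else motif membership -> ``motif``; else ``hypothetical``.

    The input tables are expected pre-filtered at their tier thresholds
    (300 / 60 bits); filtering is re-applied defensively here.  A gene seen
    only in the reciprocal table triggers a consistency warning and is
    treated as a one-way candidate.
    """
    motifs = motifs or set()
    fwd = forward.filter_bits(ONE_WAY_MIN_BITS)
    rcp = reciprocal.filter_bits(RECIPROCAL_MIN_BITS)
    fwd_best = _best_by_query(fwd)
    rcp_best = _best_by_query(rcp)
    # subjects of reciprocal rows, keyed by the gene they point back to
    rcp_by_gene: dict[str, pd.Series] = {}
    for _q, row in rcp_best.items():
        rcp_by_gene.setdefault(row["sseqid"], row)

    rows = []
    for gid in gene_ids:
        tier, subject, bits, taxon = "hypothetical", None, None, None
        f = fwd_best.get(gid)
        if f is not None:
            subject = f["sseqid"]
            bits = float(f["bitscore"])
            taxon = f.get("staxon")
            back = rcp_best.get(subject)
            if bits >= RECIPROCAL_MIN_BITS and back is not None and back["sseqid"] == gid:
                tier = "reciprocal"
            else:
                tier = "one_way"
        elif gid in rcp_by_gene:
            warnings.warn(
                f"gene {gid} present in reciprocal table but not forward table; "
                "treating as one-way candidate",
                stacklevel=2,
            )
            r = rcp_by_gene[gid]
            tier, subject, bits, taxon = "one_way", r["qseqid"], float(r["bitscore"]), r.get("staxon")
        elif gid in motifs:
            tier = "motif"
        if tier == "one_way" and gid in motifs and bits is None:
            tier = "motif"
        if taxon is None and subject is not None and taxon_map:
            taxon = taxon_map.get(subject)
        rows.append(
            {"gene_id": gid, "tier": tier, "best_subject": subject,
             "bit_score": bits, "subject_taxon": taxon}
        )
    return pd.DataFrame(rows, columns=["gene_id", "tier", "best_subject", "bit_score", "subject_taxon"])


def scaffold_vote(
    annotations: pd.DataFrame,
    scaffold_id: str,
    focal_taxon: str,
    threshold: float = VOTE_THRESHOLD,
    count_hypotheticals: bool = True,
) -> ScaffoldTaxonomy:
    """Taxonomy vote over the genes of one scaffold.

    ``vote_fraction`` = genes whose best-hit taxon equals ``focal_taxon``
    divided by the number of genes considered; the scaffold is assigned when
    the fraction reaches ``threshold`` (inclusive).  With
    ``count_hypotheticals`` (default) unannotated genes stay in the
    denominator.
    """
    if not len(annotations):
        return ScaffoldTaxonomy(scaffold_id=scaffold_id, flag="no_genes")
    pool = annotations if count_hypotheticals else annotations[annotations["subject_taxon"].notna()]
    n = len(pool)
    if n == 0:
        return ScaffoldTaxonomy(scaffold_id=scaffold_id, flag="no_annotated_genes")
    votes = pool["subject_taxon"].dropna().value_counts().to_dict()
    focal = int(votes.get(focal_taxon, 0))
    frac = focal / n
    return ScaffoldTaxonomy(
        scaffold_id=scaffold_id,
        votes={str(k): int(v) for k, v in votes.items()},
        n_genes=n,
        assigned_taxon=focal_taxon if frac >= threshold else None,
        vote_fraction=frac,
    )


def vote_all_scaffolds(
    genes: pd.DataFrame,
    annotations: pd.DataFrame,
    focal_taxon: str,
    threshold: float = VOTE_THRESHOLD,
    count_hypotheticals: bool = True,
) -> pd.DataFrame:
    """Vote every scaffold in ``genes``; returns one row per scaffold."""
    ann = genes.merge(annotations, on="gene_id", how="left")
    rows = []
    for sid, grp in ann.groupby("scaffold_id", sort=True):
        tax = scaffold_vote(grp, sid, focal_taxon, threshold, count_hypotheticals)
        rows.append(
            {"scaffold_id": sid, "n_genes": tax.n_genes,
             "vote_fraction": tax.vote_fraction,
             "assigned_taxon": tax.assigned_taxon, "flag": tax.flag}
        )
    return pd.DataFrame(rows, columns=["scaffold_id", "n_genes", "vote_fraction", "assigned_taxon", "flag"])


def select_taxon_scaffolds(
    taxonomies: pd.DataFrame,
    scaffold_lengths: pd.Series,
    focal_taxon: str,
    min_len: int = 5000,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Scaffolds strictly longer than ``min_len`` that were assigned to
    ``focal_taxon``, plus a count report."""
    t = taxonomies.copy()
    t["length"] = t["scaffold_id"].map(scaffold_lengths)
    selected = t[(t["assigned_taxon"] == focal_taxon) & (t["length"] > min_len)].reset_index(drop=True)
    report = {
        "total_scaffolds": int(len(t)),
        "assigned": int((t["assigned_taxon"] == focal_taxon).sum()),
        "selected": int(len(selected)),
    }
    return selected, report
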
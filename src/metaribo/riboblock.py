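"""rpS3 anchoring and syntenic 16-ribosomal-protein block analysis.

Full-length rpS3 proteins (>= 200 aa, on scaffolds > 5 kb, unique at exact
amino-acid identity) anchor candidate lineages.  Each anchor scaffold is
scored for how many of the 16 ribosomal-protein families it carries
(block_fraction = found/16); lineages retaining at least 8 of the 16 families
pass into the concatenated alignment used for phylogeny and profiling.
Synteny breaks are reported for diagnostics but never filtered on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .align import ConcatAlignment, MultipleAlignment, align_family, concatenate, mask_columns
from .io_formats import HitTable, SequenceSet
from .references import RP16_ORDER, RP_ANCHOR

__all__ = [
    "RP16Definition",
    "RiboBlock",
    "assign_rp_families",
    "find_anchors",
    "score_block",
    "score_blocks",
    "filter_blocks",
    "build_concat_alignment",
    "align_family",
    "mask_columns",
    "concatenate",
]

MIN_SCAFFOLD_LEN = 5000
MIN_ANCHOR_AA = 200
MIN_FAMILIES = 8


@dataclass
class RP16Definition:
    """The 16 ribosomal-protein families in canonical syntenic order."""

    families: tuple[str, ...] = tuple(RP16_ORDER)
    anchor: str = RP_ANCHOR
    reference_alignments: dict[str, MultipleAlignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.families) != 16:
            raise ValueError("exactly 16 families required")
        if self.anchor not in self.families:
            raise ValueError("anchor must be one of the 16 families")


@dataclass
class RiboBlock:
    """A lineage: an rpS3 anchor scaffold and its recovered family block."""

    scaffold_id: str
    anchor_gene_id: str
    anchor_protein: str
    families_found: frozenset[str]
    synteny_breaks: int = 0

    def __post_init__(self) -> None:
        if self.anchor_protein and RP_ANCHOR not in self.families_found:
            raise ValueError("anchor present implies RpS3 in families_found")

    @property
    def block_fraction(self) -> float:
        return len(self.families_found) / 16.0

    @property
    def n_families(self) -> int:
        return len(self.families_found)


def assign_rp_families(
    forward_hits: HitTable,
    rp16: RP16Definition | None = None,
    min_bits: float = 60.0,
) -> pd.DataFrame:
    """Gene -> ribosomal family membership from similarity hits.

    A gene belongs to the family of its best hit (>= ``min_bits``) among the
    16 family references (subject ids ``RP:<family>``); other subjects do not
    confer membership.
    """
    rp16 = rp16 or RP16Definition()
    fam_subjects = {f"RP:{f}": f for f in rp16.families}
    df = forward_hits.filter_bits(min_bits).df.copy()
    # subject ids may carry a source suffix after "|" (database accession style)
    base_subject = df["sseqid"].str.split("|").str[0]
    df = df[base_subject.isin(fam_subjects)]
    df["sseqid"] = base_subject[df.index]
    if not len(df):
        return pd.DataFrame(columns=["gene_id", "family", "bitscore"])
    best = HitTable(df.reset_index(drop=True)).best_hits()
    return pd.DataFrame(
        {
            "gene_id": best["qseqid"],
            "family": best["sseqid"].map(fam_subjects),
            "bitscore": best["bitscore"],
        }
    ).reset_index(drop=True)


def find_anchors(
    genes: pd.DataFrame,
    families: pd.DataFrame,
    proteins: SequenceSet,
    scaffold_lengths: pd.Series,
    min_scaffold_len: int = MIN_SCAFFOLD_LEN,
    min_aa: int = MIN_ANCHOR_AA,
) -> pd.DataFrame:
    """Locate unique full-length rpS3 anchors.

    Keeps rpS3 genes with protein length >= ``min_aa`` on scaffolds strictly
    longer than ``min_scaffold_len``; anchors sharing an identical amino-acid
    sequence collapse to one (first scaffold in sorted order).  Two rpS3 on
    one scaffold keep the longest with a warning.
    """
    fam = families[families["family"] == RP_ANCHOR]
    merged = genes.merge(fam[["gene_id"]], on="gene_id")
    rows = []
    for _, g in merged.iterrows():
        if g["gene_id"] not in proteins:
            continue
        prot = proteins.get(g["gene_id"])
        if len(prot) < min_aa:
            continue
        length = scaffold_lengths.get(g["scaffold_id"], 0)
        if length <= min_scaffold_len:
            continue
        rows.append(
            {"scaffold_id": g["scaffold_id"], "gene_id": g["gene_id"],
             "protein": prot, "protein_len": len(prot)}
        )
    df = pd.DataFrame(rows, columns=["scaffold_id", "gene_id", "protein", "protein_len"])
    if not len(df):
        return df
    # one anchor per scaffold: keep the longest rpS3, warn on extras
    multi = df["scaffold_id"].duplicated(keep=False)
    if multi.any():
        warnings.warn(
            f"multiple rpS3 on scaffold(s) {sorted(df.loc[multi, 'scaffold_id'].unique())}; keeping longest",
            stacklevel=2,
        )
        df = (
            df.sort_values(["scaffold_id", "protein_len"], ascending=[True, False], kind="mergesort")
            .groupby("scaffold_id", sort=False).head(1)
        )
    # uniqueness at exact amino-acid identity
    df = df.sort_values("scaffold_id", kind="mergesort")
    df = df.drop_duplicates(subset="protein", keep="first")
    return df.reset_index(drop=True)


def score_block(
    scaffold_id: str,
    anchor_gene_id: str,
    anchor_protein: str,
    scaffold_genes: pd.DataFrame,
    families: pd.DataFrame,
    rp16: RP16Definition | None = None,
    window: int | None = None,
) -> RiboBlock:
    """Score one anchor scaffold for its recovered ribosomal-protein block.

    families_found are the distinct rp16 families with a gene on the
    scaffold.  A synteny break is counted for each canonically adjacent
    family pair that is present but not adjacent among the scaffold's
    ribosomal-protein genes in position order, or strand-discordant.

    The search space is the whole scaffold; ``window`` (bp, off by default)
    restricts it to genes within that distance of the anchor gene.
    """
    rp16 = rp16 or RP16Definition()
    fam_map = families.set_index("gene_id")["family"].to_dict()
    on_scaffold = scaffold_genes[scaffold_genes["scaffold_id"] == scaffold_id].copy()
    if window is not None:
        anchor_rows = on_scaffold[on_scaffold["gene_id"] == anchor_gene_id]
        if len(anchor_rows):
            a0 = int(anchor_rows["start"].iloc[0])
            a1 = int(anchor_rows["end"].iloc[0])
            on_scaffold = on_scaffold[
                (on_scaffold["end"] >= a0 - window) & (on_scaffold["start"] <= a1 + window)
            ]
    on_scaffold["family"] = on_scaffold["gene_id"].map(fam_map)
    rp_genes = on_scaffold[on_scaffold["family"].isin(rp16.families)].sort_values("start")
    found = frozenset(rp_genes["family"])
    # synteny: walk canonical adjacent pairs that are both present
    pos = {f: (i, row["strand"]) for i, (_, row) in enumerate(rp_genes.iterrows()) for f in [row["family"]]}
    breaks = 0
    canon = [f for f in rp16.families if f in found]
    for f1, f2 in zip(canon, canon[1:]):
        i1, s1 = pos[f1]
        i2, s2 = pos[f2]
        if abs(i2 - i1) != 1 or s1 != s2:
            breaks += 1
    return RiboBlock(
        scaffold_id=scaffold_id,
        anchor_gene_id=anchor_gene_id,
        anchor_protein=anchor_protein,
        families_found=found,
        synteny_breaks=breaks,
    )


def score_blocks(
    anchors: pd.DataFrame,
    genes: pd.DataFrame,
    families: pd.DataFrame,
    rp16: RP16Definition | None = None,
) -> list[RiboBlock]:
    return [
        score_block(a["scaffold_id"], a["gene_id"], a["protein"], genes, families, rp16)
        for _, a in anchors.iterrows()
    ]


def filter_blocks(
    blocks: list[RiboBlock], min_families: int = MIN_FAMILIES,
) -> tuple[list[RiboBlock], dict[str, int]]:
    """Retain blocks with at least ``min_families`` of the 16 families."""
    retained = [b for b in blocks if b.n_families >= min_families]
    return retained, {"total": len(blocks), "retained": len(retained)}


def build_concat_alignment(
    blocks: list[RiboBlock],
    genes: pd.DataFrame,
    families: pd.DataFrame,
    proteins: SequenceSet,
    rp16: RP16Definition | None = None,
    max_gap_frac: float = 0.5,
    min_partitions: int = MIN_FAMILIES,
) -> ConcatAlignment:
    """Per-family align + mask + concatenate for a set of retained blocks.

    Taxon names are the anchor scaffold ids; each family alignment contains
    the family's gene from every block that carries it.
    """
    rp16 = rp16 or RP16Definition()
    fam_map = families.set_index("gene_id")["family"].to_dict()
    scaffold_of_block = {b.scaffold_id for b in blocks}
    per_family: dict[str, MultipleAlignment] = {}
    for fam in rp16.families:
        records = []
        for _, g in genes.iterrows():
            if g["scaffold_id"] not in scaffold_of_block:
                continue
            if fam_map.get(g["gene_id"]) != fam or g["gene_id"] not in proteins:
                continue
            if any(r[0] == g["scaffold_id"] for r in records):
                continue  # one gene per family per lineage
            records.append((g["scaffold_id"], "", proteins.get(g["gene_id"])))
        if not records:
            continue
        aln = align_family(SequenceSet(records=records, alphabet="aa"))
        if len(records) > 1:
            aln, _map = mask_columns(aln, max_gap_frac=max_gap_frac)
        per_family[fam] = aln
    return concatenate(per_family, list(rp16.families), min_partitions=min_partitions)
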
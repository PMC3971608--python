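"""Readers and writers for the plain-text formats used throughout the pipeline.

Everything downstream speaks in terms of three containers:

* :class:`SequenceSet` — ordered FASTA records (nucleotide or amino acid);
* :class:`HitTable` — BLAST outfmt-6 style tabular similarity hits, with an
  optional 13th column carrying the subject's taxon (phylum string);
* :class:`CoverageTable` — per-(scaffold, sample) mean read coverage plus the
  per-sample sequencing totals needed for cross-sample normalization.

Gene calls travel as a pandas DataFrame parsed from a GFF3 subset.
Coordinates are 1-based inclusive; strands are "+"/"-"; protein length of a
gene is (end - start + 1) / 3 - 1 (stop codon excluded).

No science happens here: only parsing, validation, and round-trip fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SequenceSet",
    "HitTable",
    "CoverageTable",
    "read_fasta",
    "write_fasta",
    "read_hits",
    "write_hits",
    "read_gene_table",
    "write_gene_table",
    "read_coverage",
    "write_coverage",
    "protein_length",
]

#: BLAST outfmt 6 column names, in file order; "staxon" is the optional 13th.
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

GENE_COLUMNS = ["scaffold_id", "start", "end", "strand", "gene_id"]


def protein_length(start: int, end: int) -> int:
    """Amino-acid length of a CDS spanning ``start..end`` (1-based inclusive)."""
    return (end - start + 1) // 3 - 1


@dataclass
class SequenceSet:
    """An ordered collection of named sequences with a declared alphabet."""

    records: list[tuple[str, str, str]] = field(default_factory=list)
    alphabet: str = "nt"  # "nt" or "aa"

    def __post_init__(self) -> None:
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"alphabet must be 'nt' or 'aa', got {self.alphabet!r}")
        seen: set[str] = set()
        for rid, _desc, seq in self.records:
            if not rid:
                raise ValueError("empty sequence id")
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if not seq:
                raise ValueError(f"empty sequence for id {rid!r}")

    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def get(self, rid: str) -> str:
        for r, _d, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, rid: str) -> bool:
        return any(r == rid for r, _d, _s in self.records)


def read_fasta(path: str | Path, alphabet: str = "nt") -> SequenceSet:
    """Parse a FASTA file; wrapped lines are joined, order preserved.

    The description is the header text after the first whitespace.  Duplicate
    ids and empty records are hard errors (SequenceSet invariants).
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append((rec.id, desc, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceSet(records=records, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, desc, seq in seqs:
            header = f">{rid} {desc}" if desc else f">{rid}"
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class HitTable:
    """Tabular similarity hits (BLAST outfmt 6 dialect).

    ``df`` keeps file order in the ``_order`` column so that best-hit ties can
    be broken deterministically by input order.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("qseqid", "sseqid", "bitscore"):
            if col not in df.columns:
                raise ValueError(f"hit table missing column {col!r}")
        if len(df):
            if df["bitscore"].isna().any() or (df["bitscore"] < 0).any():
                raise ValueError("bit scores must be finite and non-negative")
            if (df["qseqid"].astype(str) == "").any() or (df["sseqid"].astype(str) == "").any():
                raise ValueError("query/subject ids must be non-empty")
        if "_order" not in df.columns:
            self.df = df.assign(_order=range(len(df)))

    def __len__(self) -> int:
        return len(self.df)

    def filter_bits(self, min_bits: float) -> "HitTable":
        return HitTable(self.df[self.df["bitscore"] >= min_bits].reset_index(drop=True))

    def best_hits(self) -> pd.DataFrame:
        """One row per query: maximum bit score, ties broken by higher percent
        identity, then by input order."""
        df = self.df
        if not len(df):
            return df.copy()
        pid = df["pident"] if "pident" in df.columns else 0.0
        ranked = df.assign(_pid=pid).sort_values(
            ["qseqid", "bitscore", "_pid", "_order"],
            ascending=[True, False, False, True],
            kind="mergesort",
        )
        return ranked.groupby("qseqid", sort=False).head(1).drop(columns="_pid").reset_index(drop=True)


def read_hits(path: str | Path, min_bits: float = 0.0) -> HitTable:
    """Read a 12(+1)-column BLAST tabular file, dropping rows below ``min_bits``.

    A non-numeric bit score is reported with its 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}: line {lineno}: expected >=12 tab-separated columns")
            try:
                bits = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric bit score {parts[11]!r}") from exc
            row = dict(zip(BLAST6_COLUMNS, parts[:12]))
            row["pident"] = float(row["pident"])
            row["length"] = int(row["length"])
            row["mismatch"] = int(row["mismatch"])
            row["gapopen"] = int(row["gapopen"])
            for c in ("qstart", "qend", "sstart", "send"):
                row[c] = int(row[c])
            row["evalue"] = float(row["evalue"])
            row["bitscore"] = bits
            row["staxon"] = parts[12] if len(parts) > 12 else None
            rows.append(row)
    df = pd.DataFrame(rows, columns=BLAST6_COLUMNS + ["staxon"])
    table = HitTable(df)
    return table.filter_bits(min_bits)


def write_hits(hits: HitTable, path: str | Path) -> None:
    df = hits.df.sort_values("_order")
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            cols = [str(row[c]) for c in BLAST6_COLUMNS]
            if row.get("staxon") is not None and not pd.isna(row.get("staxon")):
                cols.append(str(row["staxon"]))
            fh.write("\t".join(cols) + "\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Parse a GFF3-subset gene table into a DataFrame sorted by (scaffold, start).

    Required GFF columns: seqid, start, end, strand, and an ``ID=`` attribute.
    Coordinates are 1-based inclusive; ``end < start`` is a hard error naming
    the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF columns")
            scaffold, _src, _type, start, end, _score, strand, _frame, attrs = parts[:9]
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}: line {lineno}: end ({end_i}) < start ({start_i})")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: strand must be '+' or '-'")
            gene_id = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if not gene_id:
                raise ValueError(f"{path}: line {lineno}: missing ID attribute")
            rows.append((scaffold, start_i, end_i, strand, gene_id))
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return df.sort_values(["scaffold_id", "start"], kind="mergesort").reset_index(drop=True)


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(g["scaffold_id"]), "metaribo", "CDS",
                        str(int(g["start"])), str(int(g["end"])), ".",
                        str(g["strand"]), "0", f"ID={g['gene_id']}",
                    ]
                )
                + "\n"
            )


@dataclass
class CoverageTable:
    """Per-(scaffold, sample) mean coverage with per-sample sequencing totals."""

    cov: pd.DataFrame       # scaffold_id, sample_id, coverage
    totals: pd.DataFrame    # sample_id, total_reads, total_bp

    def __post_init__(self) -> None:
        cov, totals = self.cov, self.totals
        if len(cov):
            if cov.duplicated(["scaffold_id", "sample_id"]).any():
                raise ValueError("duplicate (scaffold, sample) coverage rows")
            if (cov["coverage"] < 0).any():
                raise ValueError("coverage must be non-negative")
            referenced = set(cov["sample_id"])
            known = set(totals["sample_id"])
            if not referenced <= known:
                raise ValueError(f"totals missing for samples: {sorted(referenced - known)}")
        if len(totals):
            if (totals["total_reads"] <= 0).any() or (totals["total_bp"] <= 0).any():
                raise ValueError("per-sample totals must be positive")

    def samples(self) -> list[str]:
        return list(self.totals["sample_id"])

    def matrix(self) -> pd.DataFrame:
        """Scaffold x sample coverage matrix (missing pairs -> 0)."""
        return (
            self.cov.pivot(index="scaffold_id", columns="sample_id", values="coverage")
            .fillna(0.0)
        )

    def scaffold_coverage(self, scaffold_id: str, sample_id: str) -> float:
        sel = self.cov[
            (self.cov["scaffold_id"] == scaffold_id) & (self.cov["sample_id"] == sample_id)
        ]
        return float(sel["coverage"].iloc[0]) if len(sel) else 0.0


def read_coverage(cov_path: str | Path, reads_path: str | Path, bp_path: str | Path) -> CoverageTable:
    """Read the coverage TSV and the two-column per-sample totals TSVs."""
    cov = pd.read_csv(cov_path, sep="\t", dtype={"scaffold_id": str, "sample_id": str})
    reads = pd.read_csv(reads_path, sep="\t", dtype={"sample_id": str})
    bp = pd.read_csv(bp_path, sep="\t", dtype={"sample_id": str})
    totals = reads.merge(bp, on="sample_id")
    return CoverageTable(cov=cov, totals=totals)


def write_coverage(table: CoverageTable, cov_path: str | Path, reads_path: str | Path, bp_path: str | Path) -> None:
    table.cov.to_csv(cov_path, sep="\t", index=False)
    table.totals[["sample_id", "total_reads"]].to_csv(reads_path, sep="\t", index=False)
    table.totals[["sample_id", "total_bp"]].to_csv(bp_path, sep="\t", index=False)
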
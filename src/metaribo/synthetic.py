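"""Synthetic sediment-community generator.

Builds multi-genome communities with exactly the statistical structure the
downstream analyses exploit, so every stage of the pipeline is testable
without external sequence data:

* genome-distinct oligonucleotide signatures — each genome's sequence is
  sampled from an order-3 Markov chain whose transition table is a mixture of
  a fixed global table and a genome-private table, mixed by
  ``signature_strength`` (0 = no compositional signal, 1 = fully private);
* a planted syntenic 16-gene ribosomal-protein operon (rpS3 anchored) and up
  to 76 single-copy marker genes per genome, back-translated with the
  genome's own codon bias so planted genes do not disrupt its signature;
* assembly-style fragmentation into scaffolds with shifted-exponential
  lengths;
* per-sample scaffold coverages derived from a specified abundance matrix by
  the same model the abundance estimator inverts:
  ``coverage = abundance x dataset_bp / predicted_genome_size``;
* BLAST-style forward/reciprocal hit tables emulating a similarity search,
  with a configurable false-positive rate.

Truth tables (scaffold -> genome, genome -> phylum, gene -> family) ride along
so recovery can be scored exactly.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CoverageTable,
    HitTable,
    SequenceSet,
    write_coverage,
    write_fasta,
    write_gene_table,
    write_hits,
)
from .references import (
    AMINO_ACIDS,
    RP16_ORDER,
    marker_reference_proteins,
    mutate_protein,
    rp16_reference_proteins,
)

__all__ = [
    "GenomeSpec",
    "CommunitySpec",
    "Community",
    "FixtureBundle",
    "generate_genome",
    "plant_operon",
    "plant_markers",
    "fragment",
    "simulate_coverage",
    "emit_hits",
    "build_community",
    "build_fixture",
    "lognormal_rank_abundance",
]

_BASES = "ACGT"
_GENOME_SIZE_BP = {"default": 3_000_000, "small": 1_500_000}
MIN_GENOME_LEN = 50_000


# ---------------------------------------------------------------------------
# specs


@dataclass
class GenomeSpec:
    """Recipe for one synthetic genome."""

    genome_id: str
    length: int
    phylum: str
    composition_seed: int
    signature_strength: float = 0.3
    markov_order: int = 3
    genome_size_class: str = "default"   # "default" (3 Mbp) or "small" (1.5 Mbp)
    divergence: float = 0.05             # substitutions/site applied to planted proteins
    plant_rp_operon: bool = True
    drop_rp_families: tuple[str, ...] = ()
    plant_marker_genes: bool = True
    marker_dropout: float = 0.0
    drop_markers: tuple[str, ...] | None = None   # deterministic alternative to dropout
    filler_genes_per_kb: float = 0.0

    def __post_init__(self) -> None:
        if self.length < MIN_GENOME_LEN:
            raise ValueError(f"genome length must be >= {MIN_GENOME_LEN} bp")
        if not 0.0 <= self.signature_strength <= 1.0:
            raise ValueError("signature_strength must be in [0, 1]")
        if self.genome_size_class not in _GENOME_SIZE_BP:
            raise ValueError(f"unknown genome_size_class {self.genome_size_class!r}")

    @property
    def predicted_genome_size(self) -> int:
        """Predicted genome size used by the abundance model (3 Mbp in
        general, 1.5 Mbp for small-genome lineages)."""
        return _GENOME_SIZE_BP[self.genome_size_class]


@dataclass
class CommunitySpec:
    """A set of genomes, samples, and the planted abundance structure."""

    genomes: list[GenomeSpec]
    samples: list[str]
    abundance: pd.DataFrame          # index genome_id, columns sample_id, fractions
    dataset_bp: dict[str, float]     # per-sample total assembled/sequenced bp

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids")
        self.abundance = self.abundance.loc[ids, self.samples].astype(float)
        sums = self.abundance.sum(axis=0)
        if (sums > 1.0 + 1e-9).any():
            bad = sums[sums > 1.0 + 1e-9].index.tolist()
            raise ValueError(f"abundance column(s) sum > 1: {bad}")
        for s in self.samples:
            if self.dataset_bp[s] <= 0:
                raise ValueError("dataset_bp must be positive")

    def genome(self, genome_id: str) -> GenomeSpec:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


def lognormal_rank_abundance(
    n: int, mu: float = 0.0, sigma: float = 1.0, total: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Lognormal(mu, sigma) rank-abundance fractions scaled to sum to ``total``."""
    rng = rng if rng is not None else np.random.default_rng(0)
    raw = rng.lognormal(mu, sigma, size=n)
    return np.sort(raw)[::-1] / raw.sum() * total


# ---------------------------------------------------------------------------
# composition model


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


_GLOBAL_TABLE_CACHE: dict[int, np.ndarray] = {}


def global_transition_table(order: int = 3) -> np.ndarray:
    """The shared order-k transition table (4**k x 4), fixed for the package.

    Drawn once from a mildly concentrated Dirichlet with a hard-coded seed:
    every genome's table is a perturbation of this one, so at
    signature_strength 0 all genomes share a composition.
    """
    if order not in _GLOBAL_TABLE_CACHE:
        rng = np.random.default_rng(714_000 + order)
        _GLOBAL_TABLE_CACHE[order] = rng.dirichlet(np.full(4, 8.0), size=4 ** order)
    return _GLOBAL_TABLE_CACHE[order]


def genome_transition_table(spec: GenomeSpec) -> np.ndarray:
    """Global table mixed with a genome-private Dirichlet table by
    ``signature_strength``."""
    base = global_transition_table(spec.markov_order)
    rng = np.random.default_rng(spec.composition_seed)
    private = rng.dirichlet(np.ones(4), size=4 ** spec.markov_order)
    s = spec.signature_strength
    return (1.0 - s) * base + s * private


def generate_genome(spec: GenomeSpec, seed: int) -> str:
    """Sample ``spec.length`` bases from the genome's order-k Markov chain.

    Deterministic: identical (spec, seed) gives an identical sequence.
    """
    table = genome_transition_table(spec)
    k = spec.markov_order
    n_states = 4 ** k
    cum = np.cumsum(table, axis=1)
    cum_list = [tuple(row) for row in cum]
    rng = np.random.default_rng([seed, spec.composition_seed])
    u = rng.random(spec.length)
    state = int(rng.integers(0, n_states))
    mask = n_states - 1
    out = bytearray(spec.length)
    bases = b"ACGT"
    # seed context written from the initial state
    for j in range(k):
        out[j] = bases[(state >> (2 * (k - 1 - j))) & 3]
    for i in range(k, spec.length):
        c = cum_list[state]
        r = u[i]
        if r < c[0]:
            b = 0
        elif r < c[1]:
            b = 1
        elif r < c[2]:
            b = 2
        else:
            b = 3
        out[i] = bases[b]
        state = ((state << 2) & mask) | b
    return out.decode("ascii")


# ---------------------------------------------------------------------------
# gene planting


def _codon_weights(genome_seq: str) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-amino-acid codon weights taken from the genome's own trimer
    frequencies, so back-translated genes match the host composition."""
    from Bio.Data import CodonTable

    enc = _encode(genome_seq)
    valid = enc != 255
    tri = enc[:-2].astype(np.int32) * 16 + enc[1:-1].astype(np.int32) * 4 + enc[2:].astype(np.int32)
    ok = valid[:-2] & valid[1:-1] & valid[2:]
    counts = np.bincount(tri[ok], minlength=64).astype(float) + 1.0  # pseudocount
    fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
    weights: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in AMINO_ACIDS:
        codons = [c for c, a in fwd.items() if a == aa]
        idx = [
            _BASES.index(c[0]) * 16 + _BASES.index(c[1]) * 4 + _BASES.index(c[2])
            for c in codons
        ]
        w = counts[idx]
        weights[aa] = (codons, w / w.sum())
    return weights


def back_translate(
    protein: str, codon_weights: dict[str, tuple[list[str], np.ndarray]],
    rng: np.random.Generator, stop: str = "TAA",
) -> str:
    parts = []
    for aa in protein:
        codons, probs = codon_weights[aa]
        parts.append(codons[int(rng.choice(len(codons), p=probs))])
    parts.append(stop)
    return "".join(parts)


def _overlaps(a: int, b: int, occupied: list[tuple[int, int]]) -> bool:
    return any(a < e and s < b for s, e in occupied)


def _random_free_position(
    gene_len: int, genome_len: int, occupied: list[tuple[int, int]],
    rng: np.random.Generator,
) -> int | None:
    """Uniform random start among all positions where a gene of ``gene_len``
    fits without touching an occupied interval."""
    merged: list[list[int]] = []
    for a, b in sorted(occupied):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    gaps = []
    prev = 0
    for a, b in merged + [[genome_len, genome_len]]:
        room = a - prev - gene_len
        if room >= 0:
            gaps.append((prev, room + 1))  # (gap start, number of valid starts)
        prev = max(prev, b)
    if not gaps:
        return None
    counts = np.array([g[1] for g in gaps], dtype=float)
    gi = int(rng.choice(len(gaps), p=counts / counts.sum()))
    return gaps[gi][0] + int(rng.integers(0, gaps[gi][1]))


def _insert_gene(
    seq: list, protein: str, position: int, codon_weights, rng,
    occupied: list[tuple[int, int]],
) -> tuple[int, int]:
    """Overwrite the genome at ``position`` (0-based) with the back-translated
    gene; returns 1-based inclusive coordinates."""
    nt = back_translate(protein, codon_weights, rng)
    end = position + len(nt)
    if end > len(seq):
        raise ValueError("gene does not fit at requested position")
    if _overlaps(position, end, occupied):
        raise ValueError(f"planted feature at {position} overlaps an existing feature")
    seq[position:end] = nt
    occupied.append((position, end))
    return position + 1, end


def plant_operon(
    genome_seq: str,
    family_refs: SequenceSet,
    divergence: float,
    position: int,
    seed: int | np.random.Generator,
    gene_prefix: str = "g",
    drop_families: tuple[str, ...] = (),
    spacer: int = 25,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Insert the 16-gene ribosomal block colinearly at ``position``.

    Families appear in the canonical syntenic order on the "+" strand; each
    planted protein is the family reference with Poisson(divergence x length)
    substitutions.  Families in ``drop_families`` are skipped (for block-score
    truth construction).  Returns the modified sequence and gene rows with
    genome coordinates, family labels, and the planted protein.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupied = occupied if occupied is not None else []
    seq = list(genome_seq)
    cw = _codon_weights(genome_seq)
    rows = []
    pos = position
    for fam in RP16_ORDER:
        if fam in drop_families:
            continue
        protein = mutate_protein(family_refs.get(f"RP:{fam}"), divergence, rng)
        start, end = _insert_gene(seq, protein, pos, cw, rng, occupied)
        rows.append(
            {
                "gene_id": f"{gene_prefix}_{fam}",
                "start": start, "end": end, "strand": "+",
                "family": fam, "subject": f"RP:{fam}", "protein": protein,
            }
        )
        pos = end + spacer
    if rows:
        # protect the whole operon span (spacers included) so fragmentation
        # never splits the syntenic block across scaffolds
        occupied.append((position, rows[-1]["end"]))
    return "".join(seq), pd.DataFrame(rows)


def plant_markers(
    genome_seq: str,
    marker_refs: SequenceSet,
    dropout: float = 0.0,
    seed: int | np.random.Generator = 0,
    gene_prefix: str = "g",
    drop_markers: tuple[str, ...] | None = None,
    divergence: float = 0.05,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Plant single-copy marker genes at random non-overlapping positions.

    With ``dropout`` each family is skipped independently with that
    probability; ``drop_markers`` instead names the exact families to omit
    (deterministic completeness truths).  Each family is planted at most once.
    """
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupied = occupied if occupied is not None else []
    seq = list(genome_seq)
    cw = _codon_weights(genome_seq)
    rows = []
    for ref_id, _desc, ref_protein in marker_refs:
        fam = ref_id.split(":", 1)[1]
        if drop_markers is not None:
            if fam in drop_markers or ref_id in drop_markers:
                continue
        elif dropout > 0.0 and rng.random() < dropout:
            continue
        protein = mutate_protein(ref_protein, divergence, rng)
        gene_len = 3 * (len(protein) + 1)
        p = _random_free_position(gene_len, len(seq), occupied, rng)
        if p is None:
            raise ValueError(f"could not place marker {fam}: genome too crowded")
        start, end = _insert_gene(seq, protein, p, cw, rng, occupied)
        rows.append(
            {
                "gene_id": f"{gene_prefix}_{fam}",
                "start": start, "end": end, "strand": "+",
                "family": fam, "subject": ref_id, "protein": protein,
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand", "family", "subject", "protein"])
    return "".join(seq), df


def plant_filler_genes(
    genome_seq: str,
    genes_per_kb: float,
    seed: int | np.random.Generator,
    gene_prefix: str = "g",
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Plant anonymous protein-coding genes so that scaffolds carry votes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupied = occupied if occupied is not None else []
    seq = list(genome_seq)
    cw = _codon_weights(genome_seq)
    n = int(round(genes_per_kb * len(genome_seq) / 1000.0))
    rows = []
    for i in range(n):
        length = int(rng.integers(80, 301))
        protein = "".join(AMINO_ACIDS[j] for j in rng.integers(0, len(AMINO_ACIDS), size=length))
        gene_len = 3 * (length + 1)
        p = _random_free_position(gene_len, len(seq), occupied, rng)
        if p is None:
            break  # filler genes are best-effort
        start, end = _insert_gene(seq, protein, p, cw, rng, occupied)
        rows.append(
            {
                "gene_id": f"{gene_prefix}_f{i:04d}",
                "start": start, "end": end, "strand": "+",
                "family": None, "subject": f"UniRef90_{gene_prefix}_f{i:04d}",
                "protein": protein,
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand", "family", "subject", "protein"])
    return "".join(seq), df


# ---------------------------------------------------------------------------
# fragmentation and coverage


def fragment(
    genome_len: int,
    min_len: int,
    mean_len: float,
    seed: int | np.random.Generator,
    keep_intact: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Tile ``[0, genome_len)`` into scaffolds (0-based half-open intervals).

    Lengths follow min_len + Exponential(mean_len - min_len).  Breakpoints
    that would fall inside a ``keep_intact`` interval (planted operon or
    marker) are pushed to the interval's end, so planted features are never
    split across scaffolds.  Every base is covered exactly once and every
    scaffold is at least ``min_len`` long.
    """
    if min_len < 1000:
        raise ValueError("min_len must be >= 1 kb")
    if mean_len <= min_len:
        raise ValueError("mean_len must exceed min_len")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intervals = sorted(keep_intact or [])
    cuts = [0]
    pos = 0
    while True:
        length = min_len + rng.exponential(mean_len - min_len)
        nxt = pos + int(round(length))
        # push the cut to the end of any protected interval containing it;
        # repeat because intervals may nest (operon span around its genes)
        moved = True
        while moved:
            moved = False
            for a, b in intervals:
                if a < nxt < b:
                    nxt = b
                    moved = True
        if genome_len - nxt < min_len:
            break
        cuts.append(nxt)
        pos = nxt
    cuts.append(genome_len)
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def simulate_coverage(
    community: CommunitySpec,
    scaffold2genome: pd.DataFrame,
    sigma_cov: float = 0.1,
    seed: int | np.random.Generator = 0,
    read_len: int = 150,
) -> CoverageTable:
    """Per-scaffold, per-sample coverage from the planted abundance matrix.

    coverage(g, s) = abundance[g, s] x dataset_bp[s] / predicted_genome_size[g];
    every scaffold of g inherits that value, times mean-one multiplicative
    lognormal noise when sigma_cov > 0.  sigma_cov = 0 is exactly invertible by
    the abundance estimator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for _, sc in scaffold2genome.iterrows():
        g = community.genome(sc["genome_id"])
        for s in community.samples:
            cov = (
                community.abundance.loc[g.genome_id, s]
                * community.dataset_bp[s]
                / g.predicted_genome_size
            )
            if sigma_cov > 0.0 and cov > 0.0:
                cov *= float(np.exp(sigma_cov * rng.standard_normal() - sigma_cov ** 2 / 2.0))
            rows.append((sc["scaffold_id"], s, cov))
    cov_df = pd.DataFrame(rows, columns=["scaffold_id", "sample_id", "coverage"])
    totals = pd.DataFrame(
        {
            "sample_id": community.samples,
            "total_reads": [int(round(community.dataset_bp[s] / read_len)) for s in community.samples],
            "total_bp": [int(community.dataset_bp[s]) for s in community.samples],
        }
    )
    return CoverageTable(cov=cov_df, totals=totals)


# ---------------------------------------------------------------------------
# similarity-search emulation


def emit_hits(
    gene_truth: pd.DataFrame,
    taxon_map: dict[str, str],
    fp_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    bits_true: tuple[float, float] = (310.0, 600.0),
    bits_weak: tuple[float, float] = (61.0, 299.0),
) -> tuple[HitTable, HitTable]:
    """Emulated forward and reciprocal similarity-search tables.

    True genes get a forward hit with bits ~ U(310, 600) and the matching
    reciprocal row; a fraction ``fp_rate`` instead get only a one-way hit with
    bits ~ U(61, 299).  The subject taxon column carries the source genome's
    phylum, mislabeled with probability ``fp_rate``.
    """
    if not 0.0 <= fp_rate < 1.0:
        raise ValueError("fp_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phyla = sorted(set(taxon_map.values()))
    fwd_rows, rcp_rows = [], []
    for _, g in gene_truth.iterrows():
        plen = len(g["protein"])
        taxon = taxon_map[g["genome_id"]]
        if fp_rate > 0.0 and rng.random() < fp_rate and len(phyla) > 1:
            others = [p for p in phyla if p != taxon]
            taxon = others[int(rng.integers(0, len(others)))]
        weak_only = fp_rate > 0.0 and rng.random() < fp_rate
        lo, hi = bits_weak if weak_only else bits_true
        bits = float(rng.uniform(lo, hi))
        pident = float(rng.uniform(40.0, 99.0))
        base = {
            "pident": round(pident, 1), "length": plen,
            "mismatch": int(plen * (100.0 - pident) / 100.0), "gapopen": 0,
            "qstart": 1, "qend": plen, "sstart": 1, "send": plen,
            "evalue": 1e-50, "bitscore": round(bits, 1), "staxon": taxon,
        }
        # subjects are per-source-genome database proteins, so reciprocal
        # best-hit pairs are one-to-one across genomes sharing a family
        subject = f"{g['subject']}|{g['genome_id']}"
        fwd_rows.append({"qseqid": g["gene_id"], "sseqid": subject, **base})
        if not weak_only:
            rcp_rows.append({"qseqid": subject, "sseqid": g["gene_id"], **base})
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore", "staxon"]
    fwd = HitTable(pd.DataFrame(fwd_rows, columns=cols))
    rcp = HitTable(pd.DataFrame(rcp_rows, columns=cols))
    return fwd, rcp


# ---------------------------------------------------------------------------
# end-to-end community assembly


@dataclass
class Community:
    """In-memory synthetic community with truth tables."""

    spec: CommunitySpec
    scaffolds: SequenceSet
    scaffold2genome: pd.DataFrame     # scaffold_id, genome_id, genome_start, genome_end, length
    genes: pd.DataFrame               # scaffold_id, start, end, strand, gene_id
    gene_truth: pd.DataFrame          # gene_id, genome_id, family, subject, protein
    proteins: SequenceSet
    coverage: CoverageTable
    forward_hits: HitTable | None = None
    reciprocal_hits: HitTable | None = None

    @property
    def genome2phylum(self) -> dict[str, str]:
        return {g.genome_id: g.phylum for g in self.spec.genomes}

    def scaffold_lengths(self) -> pd.Series:
        return self.scaffold2genome.set_index("scaffold_id")["length"]


def build_community(
    spec: CommunitySpec,
    seed: int,
    fragment_min_len: int = 5000,
    fragment_mean_len: float = 8000.0,
    sigma_cov: float = 0.1,
    fp_rate: float = 0.0,
    with_hits: bool = True,
    operon_divergence: float | None = None,
) -> Community:
    """Generate genomes, plant genes, fragment, and simulate coverage/hits."""
    rp_refs = rp16_reference_proteins()
    marker_refs = marker_reference_proteins()
    rng = np.random.default_rng([seed, 2013])
    scaffold_records: list[tuple[str, str, str]] = []
    s2g_rows, gene_rows, truth_rows, protein_records = [], [], [], []
    for g in spec.genomes:
        gseed = int(rng.integers(0, 2**31 - 1))
        seq = generate_genome(g, gseed)
        occupied: list[tuple[int, int]] = []
        planted = []
        grng = np.random.default_rng([gseed, 1])
        if g.plant_rp_operon:
            div = g.divergence if operon_divergence is None else operon_divergence
            seq, ops = plant_operon(
                seq, rp_refs, div, position=len(seq) // 3, seed=grng,
                gene_prefix=g.genome_id, drop_families=g.drop_rp_families,
                occupied=occupied,
            )
            planted.append(ops)
        if g.plant_marker_genes:
            seq, mks = plant_markers(
                seq, marker_refs, dropout=g.marker_dropout, seed=grng,
                gene_prefix=g.genome_id, drop_markers=g.drop_markers,
                divergence=g.divergence, occupied=occupied,
            )
            planted.append(mks)
        if g.filler_genes_per_kb > 0.0:
            seq, fill = plant_filler_genes(
                seq, g.filler_genes_per_kb, seed=grng,
                gene_prefix=g.genome_id, occupied=occupied,
            )
            planted.append(fill)
        genes = (
            pd.concat(planted, ignore_index=True)
            if planted
            else pd.DataFrame(columns=["gene_id", "start", "end", "strand", "family", "subject", "protein"])
        )
        pieces = fragment(len(seq), fragment_min_len, fragment_mean_len, grng, keep_intact=occupied)
        for k, (a, b) in enumerate(pieces):
            sid = f"{g.genome_id}_s{k:04d}"
            scaffold_records.append((sid, f"genome={g.genome_id}", seq[a:b]))
            s2g_rows.append(
                {"scaffold_id": sid, "genome_id": g.genome_id,
                 "genome_start": a, "genome_end": b, "length": b - a}
            )
            on_scaffold = genes[(genes["start"] - 1 >= a) & (genes["end"] <= b)]
            for _, gn in on_scaffold.iterrows():
                gene_rows.append(
                    {"scaffold_id": sid, "start": int(gn["start"]) - a,
                     "end": int(gn["end"]) - a, "strand": gn["strand"],
                     "gene_id": gn["gene_id"]}
                )
        for _, gn in genes.iterrows():
            truth_rows.append(
                {"gene_id": gn["gene_id"], "genome_id": g.genome_id,
                 "family": gn["family"], "subject": gn["subject"],
                 "protein": gn["protein"]}
            )
            protein_records.append((gn["gene_id"], f"family={gn['family']}", gn["protein"]))
    scaffolds = SequenceSet(records=scaffold_records, alphabet="nt")
    s2g = pd.DataFrame(s2g_rows)
    genes_df = (
        pd.DataFrame(gene_rows, columns=["scaffold_id", "start", "end", "strand", "gene_id"])
        .sort_values(["scaffold_id", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    gene_truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "genome_id", "family", "subject", "protein"]
    )
    # keep only genes that survived fragmentation in the truth/protein sets
    surviving = set(genes_df["gene_id"])
    gene_truth = gene_truth[gene_truth["gene_id"].isin(surviving)].reset_index(drop=True)
    protein_records = [r for r in protein_records if r[0] in surviving]
    proteins = SequenceSet(records=protein_records, alphabet="aa") if protein_records else SequenceSet(
        records=[("placeholder", "", "M")], alphabet="aa"
    )
    cov_seed = int(rng.integers(0, 2**31 - 1))
    coverage = simulate_coverage(spec, s2g, sigma_cov=sigma_cov, seed=cov_seed)
    fwd = rcp = None
    if with_hits and len(gene_truth):
        hit_seed = int(rng.integers(0, 2**31 - 1))
        fwd, rcp = emit_hits(gene_truth, {g.genome_id: g.phylum for g in spec.genomes},
                             fp_rate=fp_rate, seed=hit_seed)
    return Community(
        spec=spec, scaffolds=scaffolds, scaffold2genome=s2g, genes=genes_df,
        gene_truth=gene_truth, proteins=proteins, coverage=coverage,
        forward_hits=fwd, reciprocal_hits=rcp,
    )


@dataclass
class FixtureBundle:
    """Paths of an on-disk fixture plus the in-memory community."""

    outdir: Path
    community: Community
    paths: dict[str, Path] = field(default_factory=dict)


def build_fixture(config: dict, outdir: str | Path, force: bool = False) -> FixtureBundle:
    """Materialize a community described by a plain config dict onto disk.

    Config keys: ``seed``, ``samples``, ``dataset_bp`` (per sample),
    ``genomes`` (list of GenomeSpec field dicts plus ``abundance`` per
    sample), and optional ``sigma_cov``, ``fp_rate``, ``fragment``
    ({min_len, mean_len}).  A manifest records the seeds used.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(config["seed"])
    samples = list(config["samples"])
    dataset_bp = {s: float(config["dataset_bp"][s]) for s in samples}
    gspecs, abund_rows = [], {}
    for gcfg in config["genomes"]:
        gcfg = dict(gcfg)
        g_abund = gcfg.pop("abundance")
        abund_rows[gcfg["genome_id"]] = [float(g_abund[s]) for s in samples]
        drop_rp = tuple(gcfg.pop("drop_rp_families", ()))
        drop_mk = gcfg.pop("drop_markers", None)
        gspecs.append(
            GenomeSpec(
                **gcfg, drop_rp_families=drop_rp,
                drop_markers=tuple(drop_mk) if drop_mk is not None else None,
            )
        )
    abundance = pd.DataFrame.from_dict(abund_rows, orient="index", columns=samples)
    spec = CommunitySpec(genomes=gspecs, samples=samples, abundance=abundance, dataset_bp=dataset_bp)
    frag = config.get("fragment", {})
    community = build_community(
        spec, seed=seed,
        fragment_min_len=int(frag.get("min_len", 5000)),
        fragment_mean_len=float(frag.get("mean_len", 8000)),
        sigma_cov=float(config.get("sigma_cov", 0.1)),
        fp_rate=float(config.get("fp_rate", 0.0)),
    )

    paths = {
        "scaffolds": outdir / "scaffolds.fasta",
        "genes": outdir / "genes.gff",
        "proteins": outdir / "proteins.faa",
        "forward_hits": outdir / "forward_hits.tsv",
        "reciprocal_hits": outdir / "reciprocal_hits.tsv",
        "coverage": outdir / "coverage.tsv",
        "total_reads": outdir / "total_reads.tsv",
        "total_bp": outdir / "total_bp.tsv",
        "scaffold2genome": outdir / "truth_scaffold2genome.tsv",
        "genome2phylum": outdir / "truth_genome2phylum.tsv",
        "gene2family": outdir / "truth_gene2family.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(community.scaffolds, paths["scaffolds"])
    write_gene_table(community.genes, paths["genes"])
    write_fasta(community.proteins, paths["proteins"])
    if community.forward_hits is not None:
        write_hits(community.forward_hits, paths["forward_hits"])
        write_hits(community.reciprocal_hits, paths["reciprocal_hits"])
    write_coverage(community.coverage, paths["coverage"], paths["total_reads"], paths["total_bp"])
    community.scaffold2genome.to_csv(paths["scaffold2genome"], sep="\t", index=False)
    pd.DataFrame(
        community.genome2phylum.items(), columns=["genome_id", "phylum"]
    ).to_csv(paths["genome2phylum"], sep="\t", index=False)
    community.gene_truth[["gene_id", "genome_id", "family", "subject"]].to_csv(
        paths["gene2family"], sep="\t", index=False
    )
    with open(paths["manifest"], "w") as fh:
        json.dump({"seed": seed, "config": _jsonable(config)}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return FixtureBundle(outdir=outdir, community=community, paths=paths)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
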
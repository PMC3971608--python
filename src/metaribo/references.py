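"""Synthetic reference protein families for the 16-gene ribosomal block and
the 76 single-copy markers.

The pipeline's logic only needs family *identities* and realistic lengths, not
biologically real sequences, so reference proteins are generated once from a
fixed seed.  RpS3 is the anchor family and its reference is kept above the
200 aa full-length filter; the other ribosomal proteins use typical bacterial
lengths.  All references are synthetic stand-ins for the curated family
alignments a production run would supply.
"""

from __future__ import annotations

import numpy as np

from .io_formats import SequenceSet

__all__ = [
    "RP16_ORDER",
    "RP_ANCHOR",
    "N_MARKERS",
    "rp16_reference_proteins",
    "marker_reference_proteins",
    "mutate_protein",
    "AMINO_ACIDS",
]

#: Canonical syntenic order of the 16 ribosomal-protein families; RpS3 anchors
#: lineage detection (it sits inside the block).
RP16_ORDER = [
    "RpL2", "RpL3", "RpL4", "RpL5", "RpL6",
    "RpL14", "RpL15", "RpL16", "RpL18", "RpL22", "RpL24",
    "RpS3", "RpS8", "RpS10", "RpS17", "RpS19",
]
RP_ANCHOR = "RpS3"
N_MARKERS = 76

#: Typical bacterial lengths (aa) per family; RpS3 deliberately > 200 aa.
_RP_LENGTHS = {
    "RpL2": 273, "RpL3": 209, "RpL4": 201, "RpL5": 179, "RpL6": 177,
    "RpL14": 122, "RpL15": 144, "RpL16": 136, "RpL18": 115, "RpL22": 110,
    "RpL24": 104, "RpS3": 218, "RpS8": 132, "RpS10": 102, "RpS17": 87,
    "RpS19": 92,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Roughly bacterial proteome frequencies (order matches AMINO_ACIDS).
_AA_FREQS = np.array([
    0.089, 0.011, 0.054, 0.062, 0.040, 0.074, 0.021, 0.066, 0.053, 0.099,
    0.024, 0.041, 0.044, 0.037, 0.055, 0.058, 0.054, 0.071, 0.013, 0.030,
])
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()

_REFERENCE_SEED = 20130805


def _random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=_AA_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def rp16_reference_proteins(seed: int = _REFERENCE_SEED) -> SequenceSet:
    """Reference protein per ribosomal family, ids ``RP:<family>``."""
    rng = np.random.default_rng(seed)
    records = []
    for fam in RP16_ORDER:
        records.append((f"RP:{fam}", f"{fam} reference", _random_protein(_RP_LENGTHS[fam], rng)))
    return SequenceSet(records=records, alphabet="aa")


def marker_reference_proteins(n: int = N_MARKERS, seed: int = _REFERENCE_SEED + 1) -> SequenceSet:
    """Single-copy marker family references, ids ``SCG:M001`` ... ``SCG:M076``."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, n + 1):
        length = int(rng.integers(90, 251))
        records.append((f"SCG:M{i:03d}", f"marker family M{i:03d}", _random_protein(length, rng)))
    return SequenceSet(records=records, alphabet="aa")


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Apply Poisson(divergence x length) random substitutions to a protein."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    if divergence == 0.0:
        return protein
    n_sub = rng.poisson(divergence * len(protein))
    if n_sub == 0:
        return protein
    seq = list(protein)
    positions = rng.integers(0, len(seq), size=n_sub)
    for pos in positions:
        current = seq[pos]
        choices = [a for a in AMINO_ACIDS if a != current]
        seq[pos] = choices[rng.integers(0, len(choices))]
    return "".join(seq)
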
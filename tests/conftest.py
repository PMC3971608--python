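"""Shared fixtures: small synthetic communities generated at test time."""

from __future__ import annotations

import pandas as pd
import pytest

from metaribo.synthetic import CommunitySpec, GenomeSpec, build_community


def make_spec(
    n_genomes: int = 3,
    length: int = 200_000,
    samples: tuple[str, ...] = ("s4m", "s5m"),
    signature_strength: float = 0.3,
    seed_base: int = 10,
    **genome_kwargs,
) -> CommunitySpec:
    phyla = ["Chloroflexi", "Proteobacteria", "OD-1", "Nitrospirae", "Bacteroidetes"]
    genomes = [
        GenomeSpec(
            genome_id=f"g{i}",
            length=length,
            phylum=phyla[i % len(phyla)],
            composition_seed=seed_base + i,
            signature_strength=signature_strength,
            genome_size_class="small" if phyla[i % len(phyla)] in ("OD-1", "OP-11") else "default",
            **genome_kwargs,
        )
        for i in range(n_genomes)
    ]
    abundance = pd.DataFrame(
        {s: [0.01 * (i + 1) / (j + 1) for i in range(n_genomes)] for j, s in enumerate(samples)},
        index=[g.genome_id for g in genomes],
    )
    dataset_bp = {s: 3e9 + j * 1e9 for j, s in enumerate(samples)}
    return CommunitySpec(genomes=genomes, samples=list(samples), abundance=abundance, dataset_bp=dataset_bp)


@pytest.fixture(scope="session")
def clean_community():
    """3-genome noiseless community with genes, hits, and truth tables."""
    spec = make_spec(filler_genes_per_kb=0.3)
    return build_community(spec, seed=7, sigma_cov=0.0, fp_rate=0.0)


@pytest.fixture(scope="session")
def dropped_family_community():
    """Community whose third genome lacks 3 ribosomal families and 2 markers."""
    spec = make_spec(filler_genes_per_kb=0.2)
    spec.genomes[2].drop_rp_families = ("RpL5", "RpL6", "RpL14")
    spec.genomes[2].drop_markers = ("M001", "M002")
    return build_community(spec, seed=11, sigma_cov=0.0, fp_rate=0.0)
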
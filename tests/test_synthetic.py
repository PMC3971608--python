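"""synthetic community generator: determinism, planted truths, conservation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metaribo.binning import tetra_vector
from metaribo.references import (
    RP16_ORDER,
    marker_reference_proteins,
    rp16_reference_proteins,
)
from metaribo.synthetic import (
    CommunitySpec,
    GenomeSpec,
    build_fixture,
    emit_hits,
    fragment,
    generate_genome,
    plant_markers,
    plant_operon,
    simulate_coverage,
)
from tests.conftest import make_spec


def _spec(gid="g0", length=100_000, strength=0.3, seed=1, **kw):
    return GenomeSpec(genome_id=gid, length=length, phylum="P", composition_seed=seed,
                      signature_strength=strength, **kw)


class TestGenerateGenome:
    def test_deterministic(self):
        s1 = generate_genome(_spec(), 42)
        s2 = generate_genome(_spec(), 42)
        assert s1 == s2 and len(s1) == 100_000

    def test_length_floor(self):
        with pytest.raises(ValueError, match="50"):
            _spec(length=10_000)

    def test_no_signal_at_zero_strength(self):
        # strength 0: between-genome centroid distance comparable to within-genome spread
        fa = [generate_genome(_spec(seed=1, strength=0.0), 1)[i * 10_000:(i + 1) * 10_000] for i in range(10)]
        fb = [generate_genome(_spec(seed=2, strength=0.0), 2)[i * 10_000:(i + 1) * 10_000] for i in range(10)]
        va = np.array([tetra_vector(f).freqs for f in fa])
        vb = np.array([tetra_vector(f).freqs for f in fb])
        between = np.linalg.norm(va.mean(0) - vb.mean(0))
        within = np.linalg.norm(va - va.mean(0), axis=1).mean()
        assert between < 3 * within

    def test_signal_at_strength_03(self):
        # derived oracle: distances computed directly on generated fragments
        fa = [generate_genome(_spec(seed=1), 1)[i * 10_000:(i + 1) * 10_000] for i in range(10)]
        fb = [generate_genome(_spec(seed=2), 2)[i * 10_000:(i + 1) * 10_000] for i in range(10)]
        va = np.array([tetra_vector(f).freqs for f in fa])
        vb = np.array([tetra_vector(f).freqs for f in fb])
        between = np.linalg.norm(va.mean(0) - vb.mean(0))
        within95 = np.percentile(np.linalg.norm(va - va.mean(0), axis=1), 95)
        assert between > within95


class TestPlanting:
    def test_zero_divergence_plants_exact_references(self):
        seq = generate_genome(_spec(), 3)
        refs = rp16_reference_proteins()
        _new, genes = plant_operon(seq, refs, divergence=0.0, position=20_000, seed=1)
        for _, g in genes.iterrows():
            assert g["protein"] == refs.get(f"RP:{g['family']}")

    def test_drop_families_controls_block_truth(self):
        seq = generate_genome(_spec(), 3)
        _new, genes = plant_operon(seq, rp16_reference_proteins(), 0.1, 20_000, seed=1,
                                   drop_families=("RpL2", "RpL3", "RpL4"))
        assert len(genes) == 13
        assert set(genes["family"]) == set(RP16_ORDER) - {"RpL2", "RpL3", "RpL4"}

    def test_planted_order_is_syntenic(self):
        seq = generate_genome(_spec(), 3)
        _new, genes = plant_operon(seq, rp16_reference_proteins(), 0.1, 20_000, seed=1)
        order = {f: i for i, f in enumerate(RP16_ORDER)}
        starts = genes.sort_values("start")["family"].map(order).to_numpy()
        assert (np.diff(starts) > 0).all()

    def test_overlap_error(self):
        seq = generate_genome(_spec(), 3)
        occupied = []
        plant_operon(seq, rp16_reference_proteins(), 0.0, 20_000, seed=1, occupied=occupied)
        with pytest.raises(ValueError, match="overlap"):
            plant_operon(seq, rp16_reference_proteins(), 0.0, 20_000, seed=1, occupied=occupied)

    @pytest.mark.parametrize(
        "dropout,drop,expected",
        [(0.0, None, 76), (1.0, None, 0), (0.0, ("M001", "M002"), 74)],
    )
    def test_marker_counts(self, dropout, drop, expected):
        seq = generate_genome(_spec(length=200_000), 4)
        _new, genes = plant_markers(seq, marker_reference_proteins(), dropout=dropout,
                                    seed=2, drop_markers=drop)
        assert len(genes) == expected


class TestFragment:
    def test_conservation_and_min_len(self):
        rng = np.random.default_rng(0)
        pieces = fragment(300_000, 5000, 8000, rng)
        assert sum(b - a for a, b in pieces) == 300_000
        assert all(b - a >= 5000 for a, b in pieces)
        assert pieces[0][0] == 0 and pieces[-1][1] == 300_000

    def test_keep_intact_never_split(self):
        span = (100_000, 110_000)
        for seed in range(5):
            pieces = fragment(300_000, 5000, 8000, seed, keep_intact=[span])
            holder = [p for p in pieces if p[0] <= span[0] and p[1] >= span[1]]
            assert len(holder) == 1

    def test_n50_matches_monte_carlo(self):
        # oracle: re-fragment many times and compare the analytic-scale N50
        def n50(pieces):
            lens = sorted((b - a for a, b in pieces), reverse=True)
            csum, half = 0, sum(lens) / 2
            for ln in lens:
                csum += ln
                if csum >= half:
                    return ln
            return lens[-1]

        rng = np.random.default_rng(1)
        vals = [n50(fragment(2_000_000, 1000, 4000, rng)) for _ in range(200)]
        mc = float(np.mean(vals))
        obs = n50(fragment(2_000_000, 1000, 4000, np.random.default_rng(99)))
        assert abs(obs - mc) / mc < 0.25


class TestCoverage:
    def test_closed_form(self):
        spec = make_spec(n_genomes=1, samples=("s",))
        spec.abundance.loc["g0", "s"] = 0.01
        spec.dataset_bp["s"] = 3e9
        s2g = pd.DataFrame({"scaffold_id": ["g0_s0"], "genome_id": ["g0"]})
        cov = simulate_coverage(spec, s2g, sigma_cov=0.0)
        assert cov.scaffold_coverage("g0_s0", "s") == pytest.approx(10.0)

    def test_zero_abundance_zero_coverage(self):
        spec = make_spec(n_genomes=2, samples=("s",))
        spec.abundance.loc["g1", "s"] = 0.0
        s2g = pd.DataFrame({"scaffold_id": ["a", "b"], "genome_id": ["g0", "g1"]})
        cov = simulate_coverage(spec, s2g, sigma_cov=0.0)
        assert cov.scaffold_coverage("b", "s") == 0.0

    def test_abundance_over_one_rejected(self):
        spec = make_spec(n_genomes=2, samples=("s",))
        with pytest.raises(ValueError, match="sum > 1"):
            CommunitySpec(
                genomes=spec.genomes, samples=["s"],
                abundance=pd.DataFrame({"s": [0.7, 0.6]}, index=["g0", "g1"]),
                dataset_bp={"s": 1e9},
            )


class TestEmitHits:
    def test_fp_rate_one_rejected(self):
        truth = pd.DataFrame(
            {"gene_id": ["g"], "genome_id": ["g0"], "family": ["RpS3"],
             "subject": ["RP:RpS3"], "protein": ["MKV"]}
        )
        with pytest.raises(ValueError):
            emit_hits(truth, {"g0": "P"}, fp_rate=1.0)

    def test_clean_hits_are_reciprocal_pairs(self):
        truth = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)], "genome_id": ["g0"] * 20,
             "family": [None] * 20, "subject": [f"U{i}" for i in range(20)],
             "protein": ["MKVLA" * 30] * 20}
        )
        fwd, rcp = emit_hits(truth, {"g0": "P"}, fp_rate=0.0, seed=1)
        assert len(fwd) == len(rcp) == 20
        assert (fwd.df["bitscore"] >= 310).all()
        pairs_f = set(zip(fwd.df["qseqid"], fwd.df["sseqid"]))
        pairs_r = set(zip(rcp.df["sseqid"], rcp.df["qseqid"]))
        assert pairs_f == pairs_r


class TestFixtureBundle:
    def test_byte_identical_given_seed(self, tmp_path):
        cfg = {
            "seed": 5, "samples": ["a"], "dataset_bp": {"a": 1e9}, "sigma_cov": 0.0,
            "genomes": [
                {"genome_id": "g0", "length": 60_000, "phylum": "P",
                 "composition_seed": 1, "abundance": {"a": 0.01},
                 "marker_dropout": 0.5},
            ],
        }
        b1 = build_fixture(cfg, tmp_path / "f1")
        b2 = build_fixture(cfg, tmp_path / "f2")
        for key, p1 in b1.paths.items():
            assert p1.read_bytes() == b2.paths[key].read_bytes(), key

    def test_refuses_nonempty_dir(self, tmp_path):
        out = tmp_path / "f"
        out.mkdir()
        (out / "x").write_text("hi")
        cfg = {"seed": 1, "samples": ["a"], "dataset_bp": {"a": 1e9},
               "genomes": [{"genome_id": "g0", "length": 60_000, "phylum": "P",
                            "composition_seed": 1, "abundance": {"a": 0.01}}]}
        with pytest.raises(FileExistsError):
            build_fixture(cfg, out)
        build_fixture(cfg, out, force=True)  # force succeeds

    def test_every_scaffold_traceable(self, clean_community):
        com = clean_community
        s2g = com.scaffold2genome
        assert set(s2g["scaffold_id"]) == set(com.scaffolds.ids())
        assert not s2g["scaffold_id"].duplicated().any()
        # per-genome scaffold lengths sum to genome length
        for g in com.spec.genomes:
            total = s2g[s2g["genome_id"] == g.genome_id]["length"].sum()
            assert total == g.length
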
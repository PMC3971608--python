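"""Tetranucleotide vectors, SOM training, bin harvesting, curation, markers."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from metaribo.binning import (
    canonical_tetramers,
    completeness,
    curate_bin,
    estimate_genome_count,
    GenomeBin,
    harvest_bins,
    tetra_vector,
    tetra_vectors,
)
from metaribo.io_formats import CoverageTable
from metaribo.som import bmu_indices, harvest_components, train_som, umatrix
from metaribo.synthetic import GenomeSpec, generate_genome

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


class TestTetraVector:
    def test_136_canonical_classes(self):
        assert len(canonical_tetramers()) == 136

    def test_poly_a_mass_on_one_class(self):
        v = tetra_vector("A" * 6000)
        assert v.freqs.max() == pytest.approx(1.0)
        assert v.freqs[canonical_tetramers().index("AAAA")] == pytest.approx(1.0)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=6000))
            v1 = tetra_vector(seq)
            v2 = tetra_vector(_revcomp(seq))
            assert np.allclose(v1.freqs, v2.freqs)

    def test_matches_naive_dictionary_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        counts: dict[str, float] = {}
        for i in range(len(seq) - 3):
            kmer = seq[i : i + 4]
            canon = min(kmer, _revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
        total = sum(counts.values())
        expected = np.array([counts.get(k, 0) / total for k in canonical_tetramers()])
        assert np.allclose(tetra_vector(seq).freqs, expected)

    def test_ambiguous_bases_skipped(self):
        rng = np.random.default_rng(9)
        seq = list("".join(rng.choice(list("ACGT"), size=2000)))
        for pos in rng.integers(0, 2000, size=20):
            seq[pos] = "N"
        seq = "".join(seq)
        counts: dict[str, float] = {}
        for i in range(len(seq) - 3):
            kmer = seq[i : i + 4]
            if "N" in kmer:
                continue
            canon = min(kmer, _revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
        total = sum(counts.values())
        expected = np.array([counts.get(k, 0) / total for k in canonical_tetramers()])
        assert np.allclose(tetra_vector(seq, min_len=1000).freqs, expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="min_len"):
            tetra_vector("ACGT" * 100)


def _two_genome_vectors(n_frags=30, frag=6000, strength=0.3, seed=1):
    ids, vecs, truth = [], [], []
    for gi in range(2):
        spec = GenomeSpec(f"g{gi}", n_frags * frag, "P", composition_seed=seed + gi,
                          signature_strength=strength)
        seq = generate_genome(spec, seed + gi)
        for k in range(n_frags):
            ids.append(f"g{gi}_s{k}")
            vecs.append(tetra_vector(seq[k * frag:(k + 1) * frag]).freqs)
            truth.append(f"g{gi}")
    return ids, np.array(vecs), truth


class TestSOM:
    def test_deterministic_given_seed(self):
        _ids, vecs, _t = _two_genome_vectors(n_frags=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = train_som(vecs, rows=10, cols=10, epochs=3, seed=5)
            s2 = train_som(vecs, rows=10, cols=10, epochs=3, seed=5)
        assert np.array_equal(s1.weights, s2.weights)

    def test_quantization_error_decreases(self):
        _ids, vecs, _t = _two_genome_vectors(n_frags=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            som = train_som(vecs, rows=12, cols=12, epochs=8, seed=5)
        log = som.training_log
        assert log[-1]["quantization_error"] <= log[0]["quantization_error"]

    def test_two_genomes_spatially_separated(self):
        """BMU coordinates of the two genomes form separated groups."""
        from sklearn.metrics import silhouette_score

        ids, vecs, truth = _two_genome_vectors(n_frags=30, strength=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            som = train_som(vecs, rows=16, cols=16, epochs=10, seed=5, toroidal=False)
        bmus = bmu_indices(som, vecs)
        coords = np.column_stack([bmus // som.cols, bmus % som.cols]).astype(float)
        assert silhouette_score(coords, truth) > 0

    def test_nan_rejected(self):
        bad = np.full((12, 136), np.nan)
        with pytest.raises(ValueError):
            train_som(bad, rows=10, cols=10, epochs=1)


class TestUMatrix:
    def test_constant_map_all_zeros(self):
        from metaribo.som import SOMap

        som = SOMap(weights=np.ones((100, 4)), rows=10, cols=10)
        assert np.allclose(umatrix(som), 0.0)

    def test_non_negative(self):
        _ids, vecs, _t = _two_genome_vectors(n_frags=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            som = train_som(vecs, rows=10, cols=10, epochs=2, seed=1)
        assert (umatrix(som) >= 0).all()

    def test_matches_brute_force_3x3(self):
        """Hand-computable oracle on a 3x3 planar map."""
        from metaribo.som import SOMap

        rng = np.random.default_rng(0)
        W = rng.random((9, 2))
        som = SOMap(weights=W, rows=3, cols=3, toroidal=False)
        U = umatrix(som)
        for r in range(3):
            for c in range(3):
                dists = []
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr, dc) == (0, 0):
                            continue
                        nr, nc = r + dr, c + dc
                        if 0 <= nr < 3 and 0 <= nc < 3:
                            dists.append(np.linalg.norm(W[r * 3 + c] - W[nr * 3 + nc]))
                assert U[r, c] == pytest.approx(np.mean(dists))


class TestHarvest:
    def test_valley_percentile_zero_gives_no_bins(self):
        ids, vecs, _t = _two_genome_vectors(n_frags=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            som = train_som(vecs, rows=10, cols=10, epochs=3, seed=2)
            bins = harvest_bins(som, ids, vecs, valley_percentile=0.0)
        assert bins == []

    def test_two_genome_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        ids, vecs, truth = _two_genome_vectors(n_frags=40, strength=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            som = train_som(vecs, rows=18, cols=18, epochs=10, seed=4)
        bins = harvest_bins(som, ids, vecs)
        amap = {s: b.bin_id for b in bins for s in b.scaffold_ids}
        ari = adjusted_rand_score(truth, [amap.get(s, "un") for s in ids])
        assert ari >= 0.9

    def test_ari_non_decreasing_in_signature_strength(self):
        from sklearn.metrics import adjusted_rand_score

        means = []
        for strength in (0.0, 0.1, 0.3):
            aris = []
            for seed in range(3):
                ids, vecs, truth = _two_genome_vectors(n_frags=25, strength=strength, seed=10 * seed + 1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    som = train_som(vecs, rows=15, cols=15, epochs=8, seed=seed)
                bins = harvest_bins(som, ids, vecs)
                amap = {s: b.bin_id for b in bins for s in b.scaffold_ids}
                aris.append(adjusted_rand_score(truth, [amap.get(s, "un") for s in ids]))
            means.append(np.mean(aris))
        assert means[0] <= means[1] + 0.05 and means[1] <= means[2] + 0.05


def _cov_table(profiles: dict[str, list[float]], samples=("a", "b", "c")):
    rows = [
        (sid, s, c) for sid, prof in profiles.items() for s, c in zip(samples, prof)
    ]
    totals = [(s, 100, 15000) for s in samples]
    return CoverageTable(
        cov=pd.DataFrame(rows, columns=["scaffold_id", "sample_id", "coverage"]),
        totals=pd.DataFrame(totals, columns=["sample_id", "total_reads", "total_bp"]),
    )


class TestCurate:
    def test_homogeneous_bin_fixed_point(self):
        profiles = {f"s{i}": [10.0, 5.0, 1.0] for i in range(6)}
        gc = {f"s{i}": 0.5 + 0.001 * i for i in range(6)}
        b = GenomeBin(bin_id="b0", scaffold_ids=list(profiles))
        curated = curate_bin(b, gc, _cov_table(profiles))
        assert curated.rejected == []
        assert set(curated.scaffold_ids) == set(profiles)

    def test_contaminant_coverage_profile_rejected(self):
        profiles = {f"s{i}": [10.0 + 0.1 * i, 5.0, 1.0] for i in range(6)}
        profiles["bad"] = [0.1, 8.0, 20.0]  # orthogonal depth profile
        gc = {sid: 0.5 for sid in profiles}
        b = GenomeBin(bin_id="b0", scaffold_ids=list(profiles))
        curated = curate_bin(b, gc, _cov_table(profiles))
        assert curated.rejected == ["bad"]

    def test_gc_outlier_rejected(self):
        profiles = {f"s{i}": [10.0, 5.0, 1.0] for i in range(8)}
        gc = {f"s{i}": 0.50 + 0.002 * i for i in range(8)}
        gc["s7"] = 0.70
        b = GenomeBin(bin_id="b0", scaffold_ids=list(profiles))
        curated = curate_bin(b, gc, _cov_table(profiles))
        assert "s7" in curated.rejected

    def test_idempotent(self):
        profiles = {f"s{i}": [10.0 + i, 5.0, 1.0] for i in range(6)}
        profiles["bad"] = [0.1, 8.0, 20.0]
        gc = {sid: 0.5 for sid in profiles}
        b = GenomeBin(bin_id="b0", scaffold_ids=list(profiles))
        once = curate_bin(b, gc, _cov_table(profiles))
        twice = curate_bin(
            GenomeBin(bin_id="b0", scaffold_ids=once.scaffold_ids), gc, _cov_table(profiles)
        )
        assert twice.scaffold_ids == once.scaffold_ids and twice.rejected == []

    def test_all_rejected_is_error(self):
        profiles = {"s0": [1.0, 2.0, 3.0], "s1": [3.0, 2.0, 1.0], "s2": [1.0, 3.0, 1.0]}
        gc = {"s0": 0.3, "s1": 0.5, "s2": 0.7}
        b = GenomeBin(bin_id="b0", scaffold_ids=list(profiles))
        with pytest.raises(ValueError, match="rejected every scaffold"):
            curate_bin(b, gc, _cov_table(profiles), cov_corr_min=1.1)


MARKERS = [f"M{i:03d}" for i in range(1, 77)]


class TestCompleteness:
    @pytest.mark.parametrize("found,expected_pct", [(74, 97.4), (69, 90.8), (75, 98.7), (0, 0.0)])
    def test_marker_fractions(self, found, expected_pct):
        fams = MARKERS[:found]
        n, pct, dup = completeness(fams, MARKERS)
        assert n == found
        assert pct == pytest.approx(expected_pct, abs=0.05)
        assert pct >= 90.0 or found < 69
        assert dup == 0

    def test_duplicates_flagged(self):
        n, _pct, dup = completeness(MARKERS[:10] + MARKERS[:3], MARKERS)
        assert n == 10 and dup == 3

    def test_invariant_under_order_and_nonmarker_duplication(self):
        fams = MARKERS[:30]
        shuffled = list(reversed(fams)) + ["not_a_marker"] * 50
        assert completeness(fams, MARKERS)[:2] == completeness(shuffled, MARKERS)[:2]

    def test_non76_list_warns(self):
        with pytest.warns(UserWarning, match="expected 76"):
            _n, pct, _d = completeness(["X"], ["X", "Y"])
        assert pct == 50.0

    def test_fixture_dropout_truth(self, dropped_family_community):
        com = dropped_family_community
        fams = com.gene_truth[com.gene_truth["genome_id"] == "g2"]["family"].dropna().tolist()
        n, pct, _d = completeness(fams, MARKERS)
        assert n == 74 and pct == pytest.approx(100 * 74 / 76)


class TestGenomeCount:
    def test_single_complete_genome(self):
        assert estimate_genome_count(MARKERS, MARKERS) == (1.0, 1)

    def test_three_pooled_genomes(self):
        assert estimate_genome_count(MARKERS * 3, MARKERS) == (3.0, 3)

    def test_empty_pool(self):
        assert estimate_genome_count([], MARKERS) == (0.0, 0)

    def test_pooled_fixture(self, clean_community):
        com = clean_community
        fams = com.gene_truth["family"].dropna()
        fams = fams[fams.str.startswith("M")].tolist()
        mean, rounded = estimate_genome_count(fams, MARKERS)
        # 3 genomes, each planting all 76 markers (none lost: markers kept intact)
        assert rounded == 3 and mean == pytest.approx(3.0)
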
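"""Synthetic-data generator: determinism, placement bias, tag and read models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from intsite import (
    BiasModel,
    filter_small,
    make_genome,
    simulate_reads,
    simulate_sites,
    simulate_tags,
)
from intsite.pipeline import Fragment

from conftest import coverage_fraction_bruteforce


class TestMakeGenome:
    def test_deterministic_for_fixed_seed(self):
        a = make_genome(1, 10**6, 10, 5, 5, seed=42)
        b = make_genome(1, 10**6, 10, 5, 5, seed=42)
        assert a[0].chromosomes == b[0].chromosomes
        pd.testing.assert_frame_equal(a[1].df, b[1].df)
        pd.testing.assert_frame_equal(a[2].df, b[2].df)

    def test_seed_changes_coordinates(self):
        a = make_genome(1, 10**6, 10, 0, 0, seed=1)
        b = make_genome(1, 10**6, 10, 0, 0, seed=2)
        assert not a[1].df["tx_start"].equals(b[1].df["tx_start"])

    def test_no_genes_is_valid(self):
        genome, genes, cpg, cnc = make_genome(2, 10**5, 0, 0, 0, seed=0)
        assert len(genes) == 0 and genome.total_length > 0

    def test_annotation_fits_genome(self, small_world):
        genome, genes, cpg, cnc = small_world
        genes.validate_against(genome)
        lengths = genome.lengths
        for track in (cpg, cnc):
            for r in track.df.itertuples(index=False):
                assert 0 <= r.start < r.end <= lengths[r.chrom]

    def test_bad_parameters_name_offender(self):
        with pytest.raises(ValueError, match="n_chrom"):
            make_genome(0, 10**6, 10, 0, 0, seed=0)


class TestBiasModel:
    @pytest.mark.parametrize("kwargs", [
        {"p_tss": 0.7, "p_cpg": 0.5},
        {"p_tss": -0.1},
        {"dip_depth": 1.5},
    ])
    def test_invalid_fractions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BiasModel(**kwargs)


class TestSimulateSites:
    def test_exactly_n_unique_sites_and_determinism(self, small_world):
        genome, genes, cpg, _ = small_world
        a = simulate_sites(genome, genes, cpg, 500, BiasModel.mlv_like(), seed=5)
        b = simulate_sites(genome, genes, cpg, 500, BiasModel.mlv_like(), seed=5)
        assert a.n == 500
        pd.testing.assert_frame_equal(a.df, b.df)
        a.validate_against(genome)

    def test_uniform_tss_fraction_matches_coverage(self, small_world):
        genome, genes, cpg, _ = small_world
        n = 4000
        ds = simulate_sites(genome, genes, cpg, n, BiasModel.uniform(), seed=9)
        from intsite import classify_dataset

        frac = float(np.mean(classify_dataset(ds, genes) == "TSS_proximal"))
        p = coverage_fraction_bruteforce(genome, genes)
        tol = 4 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < tol

    def test_degenerate_kernel_avoids_dip_zone(self, small_world):
        genome, genes, cpg, _ = small_world
        bias = BiasModel(p_tss=1.0, dip_depth=1.0)
        ds = simulate_sites(genome, genes, cpg, 300, bias, seed=3)
        tss = genes.tss
        chroms = genes.df["chrom"].to_numpy()
        for r in ds.df.itertuples(index=False):
            dists = np.abs(r.position - tss[chroms == r.chrom])
            assert dists.min() > 200, "site fell inside the (fully depleted) dip"
            assert dists.min() <= 2500, "site outside every TSS kernel"

    def test_uniform_sites_pass_chi_square_in_most_replicates(self, small_world):
        genome, genes, cpg, _ = small_world
        total = genome.total_length
        bounds = np.cumsum([l for _, l in genome.chromosomes])
        offsets = {name: int(b - l) for (name, l), b in zip(genome.chromosomes, bounds)}
        passed = 0
        for seed in range(100):
            ds = simulate_sites(genome, genes, cpg, 1000, BiasModel.uniform(), seed=seed)
            linear = np.array([offsets[c] + p for c, p in zip(ds.df["chrom"], ds.df["position"])])
            counts, _ = np.histogram(linear, bins=10, range=(0, total))
            if sps.chisquare(counts).pvalue > 0.01:
                passed += 1
        assert passed >= 95

    def test_too_many_sites_rejected(self, toy_genome):
        from intsite.genome import FeatureTrack, GeneAnnotation

        with pytest.raises(ValueError, match="n_sites"):
            simulate_sites(toy_genome, GeneAnnotation(), FeatureTrack("CpG"),
                           10**9, BiasModel.uniform(), seed=0)


class TestSimulateTags:
    def test_uniform_density_closed_form(self, small_world):
        genome, _, _, _ = small_world
        n_tags = 20_000
        track = simulate_tags(genome, [], n_tags, 0.0, 0, seed=1)
        expected_per_bin = n_tags * 50 / genome.total_length
        counts = []
        for chrom, length in genome.chromosomes:
            pos = track.df.loc[track.df["chrom"] == chrom, "position"].to_numpy()
            counts.append(np.histogram(pos, bins=length // 50, range=(0, (length // 50) * 50))[0])
        mean_per_bin = float(np.mean(np.concatenate(counts)))
        assert abs(mean_per_bin - expected_per_bin) < 0.1 * expected_per_bin

    def test_delta_kernel_hits_anchors_exactly(self, small_world):
        genome, genes, _, _ = small_world
        anchors = [(c, int(t)) for c, t in zip(genes.df["chrom"], genes.tss)][:5]
        track = simulate_tags(genome, anchors, 200, 1.0, 0, seed=2)
        anchor_set = set(anchors)
        assert all((r.chrom, r.position) in anchor_set for r in track.df.itertuples(index=False))

    def test_empty_track_and_anchor_validation(self, small_world):
        genome, _, _, _ = small_world
        assert len(simulate_tags(genome, [], 0, 0.0, 100, seed=0)) == 0
        with pytest.raises(ValueError, match="anchor"):
            simulate_tags(genome, [], 100, 0.5, 100, seed=0)


class TestSimulateReads:
    def test_perfect_reads_round_trip_structure(self, seq_world):
        genome, genes, cpg, _ = seq_world
        ds = simulate_sites(genome, genes, cpg, 50, BiasModel.uniform(), seed=8)
        ltr, linker = "TTCTAGTTGACCTTAGGTCACTG", "GATCCCAAGGCATTACCGGT"
        reads = simulate_reads(genome, ds, ltr, linker, fragment_mean=120, fragment_sd=20,
                               fragment_min=30, error_rate=0.0, redundancy=0.0, seed=1)
        assert len(reads) == ds.n  # one perfect read per site
        for read in reads:
            assert read.sequence.startswith(ltr)
            assert read.sequence.endswith(linker)

    def test_redundancy_poisson_mean(self, seq_world):
        genome, genes, cpg, _ = seq_world
        ds = simulate_sites(genome, genes, cpg, 1500, BiasModel.uniform(), seed=10)
        reads = simulate_reads(genome, ds, "TTCTAGTTGACC", "GATCCCAAGGCA",
                               fragment_mean=80, fragment_sd=10, error_rate=0.0,
                               redundancy=4.0, seed=2)
        mean_per_site = len(reads) / ds.n
        assert abs(mean_per_site - 5.0) < 3 * np.sqrt(4.0 / ds.n) + 0.05

    def test_short_fragments_are_later_filtered(self):
        kept, tally = filter_small([Fragment("r1", "ACGT" * 2), Fragment("r2", "ACGT" * 10)], min_len=20)
        assert [f.read_id for f in kept] == ["r2"] and tally["too_short"] == 1
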
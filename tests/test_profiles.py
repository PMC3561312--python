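"""Tag-density aggregation around integration sites."""

import numpy as np
import pandas as pd
import pytest

from intsite import (
    BiasModel,
    SiteDataset,
    TagTrack,
    compare_profiles,
    simulate_sites,
    simulate_tags,
    tag_density_profile,
)


def _sites(records):
    return SiteDataset("s", pd.DataFrame(records, columns=["chrom", "position", "strand"]))


def _tags(records, name="mark"):
    return TagTrack(name, pd.DataFrame(records, columns=["chrom", "position", "strand"]))


class TestTagDensityProfile:
    def test_tags_at_sites_spike_central_bin(self):
        ds = _sites([("chr1", 10_000, "+"), ("chr1", 50_000, "-")])
        tags = _tags([("chr1", 10_000, "+"), ("chr1", 50_000, "+"), ("chr1", 50_000, "-")])
        mat = tag_density_profile(ds, tags, window=5000, bin_size=50)
        central = (0 + 5000) // 50
        assert mat.matrix[:, central].sum() == 3
        assert mat.mean_profile[central] == pytest.approx(1.5)  # tags per site
        assert mat.matrix.sum() == 3

    def test_uniform_tags_flat_closed_form(self, small_world):
        genome, _, _, _ = small_world
        rng = np.random.default_rng(33)
        n_tags = 50_000
        track = simulate_tags(genome, [], n_tags, 0.0, 0, seed=4)
        # sites away from chromosome edges so each window is fully covered
        records = []
        for chrom, length in genome.chromosomes:
            for p in rng.integers(10_000, length - 10_000, size=40):
                records.append((chrom, int(p), "+"))
        mat = tag_density_profile(_sites(records), track, window=5000, bin_size=50)
        rho = n_tags / genome.total_length
        expected = 50 * rho
        assert np.abs(mat.mean_profile - expected).max() < 6 * np.sqrt(expected / mat.matrix.shape[0])

    def test_empty_track_all_zero(self):
        ds = _sites([("chr1", 10_000, "+")])
        mat = tag_density_profile(ds, _tags([]), window=5000, bin_size=50)
        assert mat.matrix.sum() == 0

    def test_mass_conservation_vs_pair_count(self, small_world):
        genome, genes, cpg, _ = small_world
        ds = simulate_sites(genome, genes, cpg, 200, BiasModel.mlv_like(), seed=6)
        track = simulate_tags(genome, [("chr1", 100_000)], 5000, 0.3, 2000, seed=7)
        window = 5000
        mat = tag_density_profile(ds, track, window=window, bin_size=50)
        brute = 0
        for s in ds.df.itertuples(index=False):
            for t in track.df.itertuples(index=False):
                if s.chrom == t.chrom and -window <= t.position - s.position < window:
                    brute += 1
        assert mat.matrix.sum() == brute

    def test_translation_invariance(self):
        shift = 1234
        base_sites = [("chr1", 20_000, "+"), ("chr1", 40_000, "-")]
        base_tags = [("chr1", 19_000, "+"), ("chr1", 41_000, "-"), ("chr1", 22_000, "+")]
        a = tag_density_profile(_sites(base_sites), _tags(base_tags), 5000, 50)
        b = tag_density_profile(
            _sites([(c, p + shift, s) for c, p, s in base_sites]),
            _tags([(c, p + shift, s) for c, p, s in base_tags]),
            5000, 50,
        )
        assert np.array_equal(a.matrix, b.matrix)

    def test_bin_must_divide_window(self):
        ds = _sites([("chr1", 10_000, "+")])
        with pytest.raises(ValueError, match="divide"):
            tag_density_profile(ds, _tags([]), window=5000, bin_size=33)


class TestCompareProfiles:
    def test_identical_profiles_give_zero(self):
        ds = _sites([("chr1", 10_000, "+")])
        tags = _tags([("chr1", 10_100, "+"), ("chr1", 9_000, "-")])
        a = tag_density_profile(ds, tags, 5000, 50)
        diff, mx = compare_profiles(a, a)
        assert mx == 0.0

    def test_scale_invariance_under_tag_duplication(self):
        ds = _sites([("chr1", 10_000, "+")])
        records = [("chr1", 10_100, "+"), ("chr1", 9_000, "-"), ("chr1", 12_000, "+")]
        a = tag_density_profile(ds, _tags(records), 5000, 50)
        b = tag_density_profile(ds, _tags(records + records), 5000, 50)
        _, mx = compare_profiles(a, b)
        assert mx == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self, small_world):
        genome, genes, cpg, _ = small_world
        ds = simulate_sites(genome, genes, cpg, 100, BiasModel.mlv_like(), seed=8)
        t1 = simulate_tags(genome, [("chr1", 200_000)], 3000, 0.5, 1000, seed=9)
        t2 = simulate_tags(genome, [("chr1", 200_000)], 3000, 0.5, 1000, seed=10)
        a = tag_density_profile(ds, t1, 5000, 50)
        b = tag_density_profile(ds, t2, 5000, 50)
        dab, _ = compare_profiles(a, b)
        dba, _ = compare_profiles(b, a)
        assert np.allclose(dab, -dba)

    def test_replicate_simulations_agree_within_bootstrap_envelope(self, small_world):
        genome, genes, cpg, _ = small_world
        ds = simulate_sites(genome, genes, cpg, 400, BiasModel.mlv_like(), seed=11)
        anchors = [(c, int(t)) for c, t in zip(genes.df["chrom"], genes.tss)]
        mats = [
            tag_density_profile(ds, simulate_tags(genome, anchors, 30_000, 0.5, 1000, seed=s), 5000, 50)
            for s in range(12, 20)
        ]
        maxdiffs = [compare_profiles(mats[0], m)[1] for m in mats[1:]]
        envelope = np.percentile(maxdiffs, 99) * 2 + 0.05
        _, mx = compare_profiles(mats[1], mats[2])
        assert mx < envelope

    def test_shape_mismatch_rejected(self):
        ds = _sites([("chr1", 10_000, "+")])
        a = tag_density_profile(ds, _tags([]), 5000, 50)
        b = tag_density_profile(ds, _tags([]), 5000, 100)
        with pytest.raises(ValueError, match="mismatch"):
            compare_profiles(a, b)


def test_promoter_enriched_tags_peak_near_sites(small_world):
    """MLV-like sites + TSS-anchored tags reproduce a centred density peak.

    The true profile is a broad symmetric bump (placement kernel convolved
    with the tag kernel), so the peak is located on the replicate-mean,
    lightly smoothed profile to keep Monte-Carlo noise from dominating
    adjacent near-equal bins.
    """
    genome, genes, cpg, _ = small_world
    anchors = [(c, int(t)) for c, t in zip(genes.df["chrom"], genes.tss)]
    profiles = []
    for s in range(8):
        ds = simulate_sites(genome, genes, cpg, 1500, BiasModel.mlv_like(), seed=100 + s)
        track = simulate_tags(genome, anchors, 100_000, 0.7, 1000, seed=200 + s)
        profiles.append(tag_density_profile(ds, track, window=5000, bin_size=50).mean_profile)
    mean_profile = np.mean(profiles, axis=0)
    smooth = np.convolve(mean_profile, np.ones(21) / 21, mode="same")
    center = len(smooth) // 2
    peak = int(np.argmax(smooth))
    assert abs(peak - center) <= 2
    flank = np.concatenate([smooth[:20], smooth[-20:]]).mean()
    assert smooth[peak] > 2 * flank
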
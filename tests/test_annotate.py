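"""Site classification, Table-1-style summaries and distance profiles."""

import numpy as np
import pandas as pd
import pytest

from intsite import (
    FeatureTrack,
    GeneAnnotation,
    GenomeModel,
    IntegrationSite,
    SiteDataset,
    annotate_dataset,
    classify_dataset,
    classify_site,
    midpoint_distance_profile,
    tss_distance_profile,
    tss_window_coverage_fraction,
)

from conftest import coverage_fraction_bruteforce, gene_rule_oracle


def _dataset(records):
    return SiteDataset("t", pd.DataFrame(records, columns=["chrom", "position", "strand"]))


class TestClassifySite:
    def test_site_exactly_at_tss(self, toy_genes):
        cls, hits = classify_site(IntegrationSite("chr1", 10_000, "+"), toy_genes)
        assert cls == "TSS_proximal"
        assert ("gA", 0) in hits

    def test_inside_gene_beyond_halfwidth_is_intragenic(self, toy_genes):
        # gA spans [10000, 30000) on +; 12,501 is > 2.5 kb from its TSS
        cls, _ = classify_site(IntegrationSite("chr1", 12_501, "+"), toy_genes)
        assert cls == "intragenic"

    def test_tss_proximity_takes_precedence_over_gene_body(self):
        genes = GeneAnnotation(pd.DataFrame({
            "gene_id": ["A", "B"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "+"],
            "tx_start": [0, 22_400],
            "tx_end": [50_000, 60_000],
        }))
        # 20,000 is deep inside A's body but 2,400 bp from B's TSS
        cls, _ = classify_site(IntegrationSite("chr1", 20_000, "+"), genes)
        assert cls == "TSS_proximal"

    def test_matches_brute_force_rule_on_random_cases(self, small_world):
        genome, genes, _, _ = small_world
        rng = np.random.default_rng(77)
        lengths = genome.lengths
        chroms = rng.choice(genome.names, size=2000)
        positions = np.array([rng.integers(0, lengths[c]) for c in chroms])
        ds = _dataset([(c, int(p), "+") for c, p in zip(chroms, positions)])
        fast = classify_dataset(ds, genes)
        oracle = gene_rule_oracle(genes)
        for i, r in enumerate(ds.df.itertuples(index=False)):
            assert fast[i] == oracle(r.chrom, r.position)


class TestAnnotateDataset:
    def test_constructed_all_intergenic(self, toy_genome):
        genes = GeneAnnotation(pd.DataFrame({
            "gene_id": ["g"], "chrom": ["chr1"], "strand": ["+"],
            "tx_start": [10_000], "tx_end": [12_000],
        }))
        cpg = FeatureTrack("CpG", pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [20_500]}))
        cnc = FeatureTrack("CNC", pd.DataFrame({"chrom": ["chr1"], "start": [30_000], "end": [30_200]}))
        ds = _dataset([("chr1", 50_000, "+"), ("chr1", 60_000, "-"), ("chr2", 100, "+")])
        res = annotate_dataset(ds, genes, cpg, cnc)
        assert res.summary["intergenic"] == 1.0
        assert res.summary["cpg"] == 0.0 and res.summary["cnc"] == 0.0

    def test_class_fractions_sum_to_one(self, small_world, mlv_sites):
        genome, genes, cpg, cnc = small_world
        res = annotate_dataset(mlv_sites, genes, cpg, cnc)
        total = res.summary["intergenic"] + res.summary["tss_proximal"] + res.summary["intragenic"]
        assert total == pytest.approx(1.0)
        assert res.summary["total"] == mlv_sites.n

    def test_empty_dataset_rejected(self, small_world):
        genome, genes, cpg, cnc = small_world
        with pytest.raises(ValueError, match="empty"):
            annotate_dataset(SiteDataset("e"), genes, cpg, cnc)

    def test_association_fraction_monotone_in_halfwidth(self, small_world, mlv_sites):
        genome, genes, cpg, cnc = small_world
        fracs = [
            annotate_dataset(mlv_sites, genes, cpg, cnc, assoc_halfwidth=h).summary["cpg"]
            for h in (0, 500, 1000, 5000)
        ]
        assert fracs == sorted(fracs)

    def test_coverage_helper_matches_boolean_mask_oracle(self, small_world):
        genome, genes, _, _ = small_world
        assert tss_window_coverage_fraction(genes, genome) == pytest.approx(
            coverage_fraction_bruteforce(genome, genes), abs=1e-12
        )


class TestTssDistanceProfile:
    def test_single_site_at_tss_all_in_zero_bin(self, toy_genes):
        ds = _dataset([("chr1", 10_000, "+")])
        prof = tss_distance_profile(ds, toy_genes, window=50_000, bin_size=2500)
        zero_bin = np.searchsorted(prof.edges, 0, side="right") - 1
        assert prof.counts.sum() >= 1
        assert prof.percent[zero_bin] > 0
        # the pair with gA sits exactly at distance 0
        assert prof.edges[zero_bin] <= 0 < prof.edges[zero_bin + 1]

    def test_minus_strand_orientation(self):
        genes = GeneAnnotation(pd.DataFrame({
            "gene_id": ["g"], "chrom": ["chr1"], "strand": ["-"],
            "tx_start": [40_000], "tx_end": [60_000],
        }))
        # TSS at 59,999; site at genomic TSS+3,000 is 3,000 bp 5' of the gene
        ds = _dataset([("chr1", 62_999, "+")])
        prof = tss_distance_profile(ds, genes, window=50_000, bin_size=2500)
        d_bin = np.nonzero(prof.counts)[0]
        assert len(d_bin) == 1
        lo, hi = prof.edges[d_bin[0]], prof.edges[d_bin[0] + 1]
        assert lo <= -3000 < hi

    def test_pairs_not_sites_are_counted(self):
        genes = GeneAnnotation(pd.DataFrame({
            "gene_id": ["a", "b"], "chrom": ["chr1", "chr1"], "strand": ["+", "+"],
            "tx_start": [10_000, 11_000], "tx_end": [20_000, 21_000],
        }))
        ds = _dataset([("chr1", 10_500, "+")])
        prof = tss_distance_profile(ds, genes, window=50_000, bin_size=2500)
        assert prof.counts.sum() == 2

    def test_coarse_profile_aggregates_fine_profile(self, small_world, mlv_sites):
        genome, genes, _, _ = small_world
        fine = tss_distance_profile(mlv_sites, genes, window=50_000, bin_size=50)
        coarse = tss_distance_profile(mlv_sites, genes, window=50_000, bin_size=2500)
        assert np.array_equal(fine.counts.reshape(-1, 50).sum(axis=1), coarse.counts)

    def test_percent_sums_to_100(self, small_world, mlv_sites):
        genome, genes, _, _ = small_world
        prof = tss_distance_profile(mlv_sites, genes)
        assert prof.percent.sum() == pytest.approx(100.0)

    def test_zero_pairs_warns_and_returns_zeros(self, toy_genes):
        ds = _dataset([("chr2", 100, "+")])
        with pytest.warns(UserWarning, match="no \\(site, gene\\) pairs"):
            prof = tss_distance_profile(ds, toy_genes)
        assert prof.counts.sum() == 0


class TestMidpointProfile:
    def test_site_at_midpoint_in_central_bin(self):
        track = FeatureTrack("CpG", pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [11_000]}))
        ds = _dataset([("chr1", 10_500, "+")])
        prof = midpoint_distance_profile(ds, track, window=2500, bin_size=50, center_zero=True)
        center = len(prof.counts) // 2
        assert prof.counts[center] == 1 and prof.counts.sum() == 1

    def test_symmetric_sites_give_symmetric_profile(self):
        track = FeatureTrack("CpG", pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [52_000]}))
        mid = 51_000
        ds = _dataset([("chr1", mid - 1000, "+"), ("chr1", mid + 1000, "-")])
        prof = midpoint_distance_profile(ds, track, window=2500, bin_size=50, center_zero=True)
        assert np.array_equal(prof.counts, prof.counts[::-1])
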
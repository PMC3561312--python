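import numpy as np
import pandas as pd
import pytest

from intsite import (
    BiasModel,
    FeatureTrack,
    GeneAnnotation,
    GenomeModel,
    SiteDataset,
    make_genome,
    simulate_sites,
)


@pytest.fixture(scope="session")
def small_world():
    """A 2-chromosome ~2-Mb genome with genes, CpG islands and CNCs."""
    return make_genome(2, 1_000_000, 40, 30, 20, seed=11)


@pytest.fixture(scope="session")
def seq_world():
    """A small genome carrying sequence, for read simulation and mapping."""
    return make_genome(2, 400_000, 10, 0, 0, seed=7, with_sequence=True)


@pytest.fixture(scope="session")
def mlv_sites(small_world):
    genome, genes, cpg, _ = small_world
    return simulate_sites(genome, genes, cpg, 3000, BiasModel.mlv_like(), seed=21, name="mlv_like")


@pytest.fixture()
def toy_genome():
    return GenomeModel([("chr1", 100_000), ("chr2", 50_000)])


@pytest.fixture()
def toy_genes():
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "-"],
                "tx_start": [10_000, 40_000],
                "tx_end": [30_000, 60_000],
            }
        )
    )


def gene_rule_oracle(genes: GeneAnnotation, tss_halfwidth: int = 2500):
    """Literal restatement of the classification rule, scanning every gene.

    Returns a ``classify(chrom, position) -> class`` closure over plain
    Python lists (independent of the vectorised implementation).
    """
    rows = [
        (row["chrom"], int(row["tx_start"]), int(row["tx_end"]), int(t))
        for (_, row), t in zip(genes.df.iterrows(), genes.tss)
    ]

    def classify(chrom: str, position: int) -> str:
        near_tss = False
        inside = False
        for g_chrom, start, end, tss in rows:
            if g_chrom != chrom:
                continue
            if abs(position - tss) <= tss_halfwidth:
                near_tss = True
            if start <= position < end:
                inside = True
        if near_tss:
            return "TSS_proximal"
        if inside:
            return "intragenic"
        return "intergenic"

    return classify


def brute_force_classify(position: int, chrom: str, genes: GeneAnnotation, tss_halfwidth: int = 2500) -> str:
    return gene_rule_oracle(genes, tss_halfwidth)(chrom, position)


def coverage_fraction_bruteforce(genome: GenomeModel, genes: GeneAnnotation, halfwidth: int = 2500) -> float:
    """Boolean-mask oracle for the union coverage of ±halfwidth TSS windows."""
    covered = 0
    tss_all = genes.tss
    for chrom, length in genome.chromosomes:
        mask = np.zeros(length, dtype=bool)
        for i, row in genes.df.iterrows():
            if row["chrom"] != chrom:
                continue
            t = int(tss_all[i])
            mask[max(0, t - halfwidth) : min(length, t + halfwidth + 1)] = True
        covered += int(mask.sum())
    return covered / genome.total_length
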
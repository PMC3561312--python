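"""Synthetic genomes, annotations, biased integration datasets, tag tracks and reads.

The generators emulate the statistical structure the downstream analysis
assumes: a multi-chromosome genome with genes, CpG islands and conserved
non-coding elements; integration datasets placed either uniformly or with an
MLV-like bias (enrichment within ±2.5 kb of transcription start sites with a
dip in the innermost ±0.2 kb, enrichment around CpG-island midpoints,
remainder uniform); ChIP-like tag tracks enriched around chosen anchors; and
raw LM-PCR-style junction reads (LTR tail + genomic flank + linker) with
substitution errors. Every generator is a pure function of its seed and
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import FeatureTrack, GeneAnnotation, GenomeModel, TagTrack
from .sites import SiteDataset

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class BiasModel:
    """Mixture model for integration-site placement.

    ``p_tss`` of sites are drawn from a triangular kernel of half-width
    ``kernel_halfwidth`` around a random gene TSS; ``p_cpg`` from the same
    kernel around a random CpG-island midpoint; the remainder is uniform
    over the genome. Kernel draws landing within ``±dip_halfwidth`` of the
    *nearest* anchor of their kind are thinned by ``dip_depth``,
    reproducing the promoter-proximal dip (with dip_depth = 1 no kernel
    site survives inside the dip zone of any anchor).
    """

    p_tss: float = 0.0
    p_cpg: float = 0.0
    kernel_halfwidth: int = 2500
    dip_halfwidth: int = 200
    dip_depth: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("p_tss", "p_cpg", "dip_depth"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.p_tss + self.p_cpg > 1.0 + 1e-12:
            raise ValueError("p_tss + p_cpg must be <= 1")
        if self.kernel_halfwidth <= 0 or self.dip_halfwidth < 0:
            raise ValueError("kernel widths must be positive")

    @classmethod
    def uniform(cls) -> "BiasModel":
        return cls()

    @classmethod
    def mlv_like(cls) -> "BiasModel":
        """Default MLV-like placement used throughout the synthetic studies."""
        return cls(p_tss=0.25, p_cpg=0.10, kernel_halfwidth=2500, dip_halfwidth=200, dip_depth=0.8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_genome(
    n_chrom: int,
    mean_length: int,
    n_genes: int,
    n_cpg: int = 0,
    n_cnc: int = 0,
    seed: int = 0,
    *,
    cpg_tss_fraction: float = 0.7,
    with_sequence: bool = False,
) -> tuple[GenomeModel, GeneAnnotation, FeatureTrack, FeatureTrack]:
    """Generate a genome with gene, CpG-island and CNC annotation.

    Chromosome lengths vary uniformly in [0.75, 1.25] × ``mean_length``.
    Genes have log-normal lengths (median ≈ 15 kb, clipped to fit), may
    overlap, and sit on either strand with equal probability.
    ``cpg_tss_fraction`` of CpG islands are centred near a TSS (jittered
    ±200 bp), mimicking promoter islands; the rest, and all CNCs, are
    placed uniformly.
    """
    if n_chrom <= 0:
        raise ValueError("n_chrom must be > 0")
    if mean_length <= 0:
        raise ValueError("mean_length must be > 0")
    rng = np.random.default_rng(seed)

    lengths = np.maximum((mean_length * rng.uniform(0.75, 1.25, size=n_chrom)).astype(np.int64), 1000)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_p = lengths / lengths.sum()

    # genes
    gene_records = []
    if n_genes > 0:
        max_fit = int(lengths.max())
        gene_len = np.exp(rng.normal(np.log(15_000), 0.8, size=n_genes)).astype(np.int64)
        gene_len = np.clip(gene_len, 200, max(200, max_fit // 4))
        if gene_len.min() > max_fit:
            raise ValueError("n_genes: genes cannot fit on any chromosome (mean_length too small)")
        chrom_idx = rng.choice(n_chrom, size=n_genes, p=chrom_p)
        strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
        for i in range(n_genes):
            L = int(min(gene_len[i], lengths[chrom_idx[i]] - 1))
            start = int(rng.integers(0, lengths[chrom_idx[i]] - L))
            gene_records.append((f"gene{i + 1}", names[chrom_idx[i]], strands[i], start, start + L))
    genes = GeneAnnotation(pd.DataFrame(gene_records, columns=["gene_id", "chrom", "strand", "tx_start", "tx_end"]))

    # CpG islands: a fraction overlap a TSS (promoter islands)
    cpg_records = []
    if n_cpg > 0:
        if n_genes == 0 and cpg_tss_fraction > 0:
            cpg_tss_fraction = 0.0
        tss = genes.tss if n_genes else np.empty(0, dtype=np.int64)
        widths = rng.integers(200, 2000, size=n_cpg)
        n_at_tss = int(round(n_cpg * cpg_tss_fraction))
        for i in range(n_cpg):
            w = int(widths[i])
            if i < n_at_tss:
                gi = int(rng.integers(0, n_genes))
                chrom = genes.df.at[gi, "chrom"]
                clen = int(dict(zip(names, lengths))[chrom])
                center = int(tss[gi] + rng.integers(-200, 201))
                start = max(0, min(center - w // 2, clen - w - 1))
            else:
                ci = int(rng.choice(n_chrom, p=chrom_p))
                chrom = names[ci]
                clen = int(lengths[ci])
                if clen - w - 1 <= 0:
                    raise ValueError("n_cpg: island width exceeds chromosome length")
                start = int(rng.integers(0, clen - w))
            cpg_records.append((chrom, start, start + w))
    cpg = FeatureTrack("CpG", pd.DataFrame(cpg_records, columns=["chrom", "start", "end"]))

    # CNCs: uniform
    cnc_records = []
    if n_cnc > 0:
        widths = rng.integers(100, 500, size=n_cnc)
        chrom_idx = rng.choice(n_chrom, size=n_cnc, p=chrom_p)
        for i in range(n_cnc):
            w, ci = int(widths[i]), int(chrom_idx[i])
            if lengths[ci] - w <= 0:
                raise ValueError("n_cnc: element width exceeds chromosome length")
            start = int(rng.integers(0, lengths[ci] - w))
            cnc_records.append((names[ci], start, start + w))
    cnc = FeatureTrack("CNC", pd.DataFrame(cnc_records, columns=["chrom", "start", "end"]))

    sequences = {name: _random_sequence(rng, int(L)) for name, L in zip(names, lengths)} if with_sequence else None
    genome = GenomeModel(list(zip(names, (int(L) for L in lengths))), sequences=sequences)
    return genome, genes, cpg, cnc


def _draw_kernel_offsets(rng: np.random.Generator, n: int, bias: BiasModel) -> np.ndarray:
    """Offsets from a triangular kernel on ±halfwidth (dip applied separately)."""
    hw = bias.kernel_halfwidth
    return rng.triangular(-hw, 0, hw, size=n).astype(np.int64)


def _nearest_distance(anchors_by_chrom: dict[str, np.ndarray], chrom: str, pos: int) -> int:
    a = anchors_by_chrom.get(chrom)
    if a is None or len(a) == 0:
        return np.iinfo(np.int64).max
    i = int(np.searchsorted(a, pos))
    best = np.iinfo(np.int64).max
    if i < len(a):
        best = min(best, abs(int(a[i]) - pos))
    if i > 0:
        best = min(best, abs(int(a[i - 1]) - pos))
    return best


def simulate_sites(
    genome: GenomeModel,
    genes: GeneAnnotation,
    cpg: FeatureTrack,
    n_sites: int,
    bias: BiasModel,
    seed: int = 0,
    name: str = "simulated",
) -> SiteDataset:
    """Draw ``n_sites`` unique integration sites from the bias mixture.

    Raises if the bias requests TSS or CpG placement without genes/islands,
    or if ``n_sites`` exceeds the number of available unique positions.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    if n_sites > 2 * genome.total_length:
        raise ValueError("n_sites exceeds available unique (position, strand) pairs")
    if bias.p_tss > 0 and len(genes) == 0:
        raise ValueError("p_tss > 0 requires gene annotation")
    if bias.p_cpg > 0 and len(cpg) == 0:
        raise ValueError("p_cpg > 0 requires CpG islands")
    rng = np.random.default_rng(seed)

    lengths = genome.lengths
    names = genome.names
    chrom_lengths = np.asarray([lengths[c] for c in names], dtype=np.int64)
    chrom_p = chrom_lengths / chrom_lengths.sum()
    tss = genes.tss if len(genes) else np.empty(0, dtype=np.int64)
    gene_chrom = genes.df["chrom"].to_numpy() if len(genes) else np.empty(0, dtype=object)
    mids = cpg.midpoints if len(cpg) else np.empty(0, dtype=np.int64)
    mid_chrom = cpg.df["chrom"].to_numpy() if len(cpg) else np.empty(0, dtype=object)

    def _sorted_by_chrom(values: np.ndarray, chroms: np.ndarray) -> dict[str, np.ndarray]:
        return {c: np.sort(values[chroms == c]) for c in set(chroms)}

    tss_by_chrom = _sorted_by_chrom(tss, gene_chrom) if len(genes) else {}
    mid_by_chrom = _sorted_by_chrom(mids, mid_chrom) if len(cpg) else {}

    seen: set[tuple[str, int, str]] = set()
    chroms_out: list[str] = []
    pos_out: list[int] = []
    strand_out: list[str] = []

    def _emit(chrom: str, pos: int, strand: str) -> None:
        if pos < 0 or pos >= lengths[chrom]:
            return
        key = (chrom, pos, strand)
        if key in seen:
            return
        seen.add(key)
        chroms_out.append(chrom)
        pos_out.append(pos)
        strand_out.append(strand)

    max_rounds = 1000
    for _ in range(max_rounds):
        if len(seen) >= n_sites:
            break
        need = n_sites - len(seen)
        batch = max(2 * need, 64)
        u = rng.random(batch)
        strands = np.where(rng.random(batch) < 0.5, "+", "-")
        from_tss = u < bias.p_tss
        from_cpg = (u >= bias.p_tss) & (u < bias.p_tss + bias.p_cpg)
        n_t, n_c = int(from_tss.sum()), int(from_cpg.sum())
        offs = _draw_kernel_offsets(rng, n_t + n_c, bias)
        ti = rng.integers(0, max(len(tss), 1), size=n_t)
        ci = rng.integers(0, max(len(mids), 1), size=n_c)
        uniform_linear = rng.choice(len(names), size=batch - n_t - n_c, p=chrom_p)
        it_t = iter(range(n_t))
        it_c = iter(range(n_c))
        it_u = iter(uniform_linear)
        for b in range(batch):
            if from_tss[b]:
                j = next(it_t)
                chrom, pos = gene_chrom[ti[j]], int(tss[ti[j]] + offs[j])
                if bias.dip_depth > 0 and _nearest_distance(tss_by_chrom, chrom, pos) <= bias.dip_halfwidth:
                    if rng.random() < bias.dip_depth:
                        continue
                _emit(chrom, pos, strands[b])
            elif from_cpg[b]:
                j = next(it_c)
                chrom, pos = mid_chrom[ci[j]], int(mids[ci[j]] + offs[n_t + j])
                if bias.dip_depth > 0 and _nearest_distance(mid_by_chrom, chrom, pos) <= bias.dip_halfwidth:
                    if rng.random() < bias.dip_depth:
                        continue
                _emit(chrom, pos, strands[b])
            else:
                k = int(next(it_u))
                _emit(names[k], int(rng.integers(0, chrom_lengths[k])), strands[b])
            if len(seen) >= n_sites:
                break
    if len(seen) < n_sites:
        raise ValueError("n_sites: could not place the requested number of unique sites")
    return SiteDataset.from_arrays(name, chroms_out, pos_out, strand_out)


def simulate_tags(
    genome: GenomeModel,
    anchors: list[tuple[str, int]],
    n_tags: int,
    enriched_fraction: float,
    decay_halfwidth: int,
    seed: int = 0,
    name: str = "tags",
) -> TagTrack:
    """ChIP-like point tags: a fraction around anchors, the rest uniform.

    Enriched tags take a Laplace-distributed offset from a random anchor
    (half-density at ``decay_halfwidth``; a half-width of 0 puts them exactly
    on the anchor). The split is deterministic: round(n_tags × fraction)
    tags are enriched.
    """
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must be in [0, 1]")
    if n_tags < 0:
        raise ValueError("n_tags must be >= 0")
    if enriched_fraction > 0 and not anchors:
        raise ValueError("enriched_fraction > 0 requires a non-empty anchor list")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    names = genome.names
    chrom_lengths = np.asarray([lengths[c] for c in names], dtype=np.int64)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    n_enriched = int(round(n_tags * enriched_fraction))
    records: list[tuple[str, int, str]] = []
    while len(records) < n_enriched:
        ai = int(rng.integers(0, len(anchors)))
        chrom, apos = anchors[ai]
        if decay_halfwidth > 0:
            off = int(round(rng.laplace(0.0, decay_halfwidth / np.log(2))))
        else:
            off = 0
        pos = apos + off
        if 0 <= pos < lengths[chrom]:
            records.append((chrom, pos, "+" if rng.random() < 0.5 else "-"))
    for _ in range(n_tags - n_enriched):
        k = int(rng.choice(len(names), p=chrom_p))
        records.append((names[k], int(rng.integers(0, chrom_lengths[k])), "+" if rng.random() < 0.5 else "-"))
    return TagTrack(name, pd.DataFrame(records, columns=["chrom", "position", "strand"]))


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reads(
    genome: GenomeModel,
    sites: SiteDataset,
    ltr_tail: str,
    linker: str,
    fragment_mean: int = 250,
    fragment_sd: int = 60,
    fragment_min: int = 1,
    error_rate: float = 0.0,
    redundancy: float = 0.0,
    seed: int = 0,
) -> list:
    """Emit LM-PCR-style junction reads for every site.

    Each read is ``ltr_tail`` + the genomic flank starting at the site
    position in the site's orientation + ``linker``; each site yields
    1 + Poisson(``redundancy``) reads; substitutions occur per base at
    ``error_rate``. The genomic flank length is drawn from a normal
    distribution (clipped at ``fragment_min`` and at the chromosome edge).
    """
    from .pipeline import ReadRecord

    if genome.sequences is None:
        raise ValueError("genome carries no sequence")
    if not ltr_tail or not linker:
        raise ValueError("ltr_tail and linker must be non-empty")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths

    reads: list[ReadRecord] = []
    for i, r in enumerate(sites.df.itertuples(index=False)):
        if r.chrom not in lengths or not 0 <= r.position < lengths[r.chrom]:
            raise ValueError(f"site {r.chrom}:{r.position} outside sequence bounds")
        n_copies = 1 + int(rng.poisson(redundancy))
        seq = genome.sequence(r.chrom)
        for copy in range(n_copies):
            frag_len = max(fragment_min, int(round(rng.normal(fragment_mean, fragment_sd))))
            if r.strand == "+":
                frag = seq[r.position : r.position + frag_len]
            else:
                lo = max(0, r.position - frag_len + 1)
                frag = reverse_complement(seq[lo : r.position + 1])
            read_seq = ltr_tail + frag + linker
            if error_rate > 0:
                arr = np.frombuffer(read_seq.encode(), dtype=np.uint8).copy()
                hit = rng.random(len(arr)) < error_rate
                if hit.any():
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    idx = {65: 0, 67: 1, 71: 2, 84: 3}
                    vals = np.array([idx.get(int(b), 0) for b in arr[hit]])
                    arr[hit] = _BASES[(vals + shift) % 4]
                read_seq = arr.tobytes().decode("ascii")
            reads.append(ReadRecord(f"site{i}_copy{copy}", read_seq))
    return reads
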
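"""Round-trip LM-PCR-style junction reads back to their integration sites.

Simulates reads of the form LTR tail + genomic flank + linker (with a small
substitution error rate and PCR redundancy), runs the trimming / mapping /
collapsing pipeline, and reports the recovery rate and the per-stage
accounting.
"""

from intsite import BiasModel, make_genome, process_reads, simulate_reads, simulate_sites

genome, genes, cpg, _ = make_genome(1, 2_000_000, 20, 0, 0, seed=11, with_sequence=True)
planted = simulate_sites(genome, genes, cpg, 400, BiasModel.uniform(), seed=12)

LTR = "TTCTAGTTGACCTTAGGTCACTG"
LINKER = "GATCCCAAGGCATTACCGGT"
reads = simulate_reads(
    genome, planted, LTR, LINKER,
    fragment_mean=250, fragment_sd=50, fragment_min=40,
    error_rate=0.005, redundancy=1.0, seed=13,
)

recovered, report = process_reads(genome, reads, LTR, LINKER)
print("pipeline accounting:", report.as_dict())

orig = set(map(tuple, planted.df[["chrom", "position", "strand"]].itertuples(index=False)))
got = set(map(tuple, recovered.df[["chrom", "position", "strand"]].itertuples(index=False)))
print(f"recovered {len(orig & got)}/{len(orig)} planted sites exactly "
      f"({len(orig & got) / len(orig):.1%})")

# Every read lands in exactly one bucket (mapped, duplicate, or a rejection
# reason); at a 0.5% error rate nearly all sites come back at the exact
# junction base and strand.
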
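"""Numerosity-adjusted cluster calling and the published window thresholds.

First reproduces the calibration for the two published dataset sizes on the
2.76e9-bp effective human genome, then calls clusters on two same-bias
synthetic datasets and measures how often their clusters overlap.
"""

from intsite import (
    BiasModel,
    ClusterParams,
    calibrate_window,
    call_clusters,
    make_genome,
    overlap_clusters,
    simulate_sites,
)
from intsite.clustering import DEFAULT_EFFECTIVE_GENOME

# calibration at the published dataset sizes
for n in (32_574, 13_011):
    w = calibrate_window(n, DEFAULT_EFFECTIVE_GENOME, n_min=3, alpha=0.01)
    print(f"n_sites={n:>6d}: 3 integrations within w={w:,} bp (alpha=0.01)")

# synthetic paired datasets: same bias, independent draws
genome, genes, cpg, _ = make_genome(2, 25_000_000, 150, 100, 0, seed=21)
a = simulate_sites(genome, genes, cpg, 3_000, BiasModel.mlv_like(), seed=22, name="A")
b = simulate_sites(genome, genes, cpg, 3_000, BiasModel.mlv_like(), seed=23, name="B")

w = calibrate_window(a.n, genome.total_length)
params = ClusterParams(n_min=3, alpha=0.01, g_eff=genome.total_length, w=w)
ca, cb = call_clusters(a, params), call_clusters(b, params)
print(f"A: {ca.n_clusters} clusters holding {ca.fraction_in_clusters:.1%} of sites")
print(f"B: {cb.n_clusters} clusters holding {cb.fraction_in_clusters:.1%} of sites")

f1, _ = overlap_clusters(ca, cb, min_overlap=1)
f1k, _ = overlap_clusters(ca, cb, min_overlap=1000)
print(f"A clusters overlapping B: {f1:.1%} by >=1 bp, {f1k:.1%} by >=1 kb")

# Because both datasets share one placement bias, their hot spots form at
# the same anchors: most clusters of one dataset overlap a cluster of the
# other, as the paired real datasets do.
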
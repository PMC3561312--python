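# Methods

## Scope and data model

The package analyses retroviral integration-site datasets: named sets of
unique single-base insertion positions with strand, compared against gene
annotation (one transcribed interval per gene, stranded), strandless
feature tracks (CpG islands, conserved non-coding elements) and point tag
tracks (ChIP-seq 5′ positions). All coordinates are 0-based half-open;
files are BED or tab-separated text with a header. The TSS of a minus-strand
gene is the last base of its half-open interval (`tx_end − 1`), the UCSC
txEnd convention. Sites are single base pairs: the duplicated-target-site
biology of retroviral integration (4 bp for MLV) is collapsed to the
junction coordinate, matching how LM-PCR reports one position per provirus.

## Read pipeline

Reads are modelled as `LTR tail + genomic fragment + linker` with
substitution errors. Processing stages:

1. **Trimming.** The LTR tail must match at read position 0 with at most
   `max_mismatch` (default 2) substitutions; otherwise the read is
   rejected (`no_ltr`). The linker is located as the earliest full
   occurrence within the remaining sequence, or a ≥ 6-bp prefix truncated
   at the read end; mismatches up to the same budget are tolerated. The
   6-bp floor prevents spurious trimming by chance matches of very short
   linker remnants; remnants shorter than that remain on the fragment and
   are absorbed by the identity threshold during mapping.
2. **Filtering.** Fragments shorter than `min_len` (default 20 bp) are
   dropped; exact duplicate fragment sequences are removed and counted
   separately (pre-mapping redundancy), since "redundant" can mean either
   identical reads or identical mapped positions — both interpretations
   are applied and reported separately.
3. **Mapping.** A sorted k-mer index (k = 16) over the forward strand of
   every chromosome provides seed hits; seeds are taken at offsets 0, k and
   2k into the fragment (and its reverse complement) so one sequencing
   error cannot hide every seed. Each candidate is scored by ungapped
   full-length identity; only a unique best hit with identity ≥
   `min_identity` (default 0.95) is accepted, ties reject as multimapped.
   Ungapped alignment is the appropriate model because amplicon fragments
   are exact genomic copies plus substitution noise; indels are not
   modelled anywhere in the generator or scorer. The integration
   coordinate is the genomic base of the fragment's first (LTR-proximal)
   base — on the minus strand, the highest coordinate of the aligned
   interval — which makes the zero-error round trip exact.
4. **Collapsing.** Mapped positions on the same chromosome and strand are
   chained by single linkage with gap ≤ `tolerance` (default 3 bp); each
   chain becomes one site at its modal raw position (ties to the smallest),
   with the chain size as read count.

Defaults (`min_len` 20, `min_identity` 0.95, tolerance 3 bp, k 16) are
strict enough that desk-scale genomes (≤ 10⁷ bp of uniform random
sequence) give unique hits for essentially all planted fragments. Every
input read is accounted for exactly once across the accepted and rejected
buckets.

## Annotation

Classification applies, with precedence: TSS-proximal when
|site − TSS| ≤ 2,500 bp for *any* gene; else intragenic when inside any
gene's transcribed interval (not exon-resolved); else intergenic. Class
fractions are computed per unique site. Feature association counts a site
whose distance to the nearest interval (0 if inside) is ≤ 1,000 bp,
implemented as membership in the ±1,000-bp-padded interval union — hence
association fractions are monotone in the half-width.

Distance profiles count **pairs**, not sites: a site near several TSSs
contributes once per TSS (one entry per (site, gene) pair with |signed
distance| ≤ window, the distance oriented by gene strand). Two binning
conventions are provided because they serve different purposes and cannot
coincide: edge-aligned bins (edges at multiples of the bin width from
−window; the default) make a 2,500-bp profile an exact aggregation of the
50-bp profile; zero-centred bins (the bin containing 0 spans ±bin/2; used
for the 50-bp zoom over ±2,500 bp) place the promoter dip symmetrically
around the origin. Midpoint profiles for strandless features use the
unoriented genomic distance to `floor((start+end)/2)`.

## Tag-density profiles

Tags are points; each tag at offset `tag − site` in [−5,000, +5,000)
contributes to one 50-bp bin (200 bins over the 10-kb window), so the
matrix total equals the number of in-window (site, tag) pairs and the
profile is translation-invariant. Profiles are orientation-agnostic
(genomic left-to-right, no strand flipping of rows) and no fragment-length
extension is applied to tags. Profile comparison divides each mean profile
by its own overall mean density before differencing, making the distance
invariant to sequencing depth.

## Cluster calibration and calling

Under the uniform null, N sites on an effective genome of G bp are
modelled as a homogeneous Poisson process of rate λ = N/G. The *clump
probability* — that a given site is followed downstream by at least
n_min − 1 further sites within w — is P[Poisson(λw) ≥ n_min − 1]. The
calibrated window is the largest integer w keeping this below α; for
n_min = 3 it solves 1 − e^(−μ)(1+μ) = α at μ* (≈ 0.148555 for α = 0.01)
with w = ⌊μ*·G/N⌋. This per-site criterion was chosen because it is the
simple model consistent with windows inversely proportional to dataset
size, the scaling the published thresholds obey; a genome-wide
expected-cluster criterion would scale as N^(−3/2) and does not. The
packaged effective genome size, 2.76 × 10⁹ bp, is a calibration constant
for the mappable human genome (back-solved consistently from both
published (N, w) pairs) and is always an explicit input, never inferred
from data.

The Monte-Carlo calibration draws ≥ 200 uniform datasets on [0, G) and
bisects on integer w until the empirical clump frequency brackets α; it
agrees with the analytic solution within a few percent and guards the
model. `false_cluster_rate` re-estimates the clump frequency at a given w
as a validation harness.

Calling scans position-sorted sites per chromosome (strand ignored): every
run of n_min consecutive sites spanning ≤ w seeds a cluster, overlapping
seeds chain into maximal clusters, and the cluster span is [first site,
last site] (stored half-open, no flanking padding). Overlap between
cluster sets is the fraction of one set's clusters overlapping any cluster
of the other by at least `min_overlap` bp (half-open interval arithmetic);
the quantity is directional.

## Fisher comparisons

The two-sided Fisher exact test conditions on the margins of the 2×2
table and sums the hypergeometric point probabilities of all tables no
more likely than the observed one (point-probability rule, the convention
of mainstream statistical software; the underlying convention for
"two-sided" is otherwise ambiguous). Probabilities are computed with
log-gamma arithmetic and summed with log-sum-exp; a relative slack of
1e−7 absorbs floating-point ties, p is clamped to exactly 1 when every
table is included and kept strictly positive (≥ 5e−324) for extreme
tables. Random controls are plain uniform placements with random strand; a
matching of controls to additional covariates (e.g. restriction-fragment
structure) is left to the caller via the extractor hook. No
multiple-testing correction is applied.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
and only that:

- **Genome/annotation**: chromosome lengths uniform in [0.75, 1.25] ×
  mean; log-normal gene lengths (median ≈ 15 kb) placed uniformly,
  overlaps allowed, strands equiprobable; 70% of CpG islands centred near
  a TSS (±200 bp jitter) mimicking promoter islands, the rest uniform;
  CNCs uniform. Sequence, when requested, is i.i.d. uniform ACGT.
- **Sites**: a mixture — with probability `p_tss` a triangular kernel of
  half-width 2,500 bp around a random TSS, with `p_cpg` the same kernel
  around a random CpG midpoint, the rest uniform. Kernel draws landing
  within ±200 bp of the *nearest* anchor of their kind are thinned by
  `dip_depth`, producing the promoter-proximal dip as an aggregate
  property. The MLV-like default (`p_tss` 0.25, `p_cpg` 0.10, dip depth
  0.8) was fixed once to land the class fractions in the regime the real
  vector datasets show (≈ 20–35% TSS-proximal and ≈ 12–18% CpG-associated
  on the synthetic genomes, against a few percent for uniform controls).
- **Tags**: a deterministic `round(n × enriched_fraction)` split between
  anchor-kernel tags (Laplace offsets, half-density at `decay_halfwidth`;
  half-width 0 degenerates to a point mass on the anchor) and uniform
  background.
- **Reads**: per site, 1 + Poisson(redundancy) copies of LTR tail +
  genomic flank (normal length, clipped at the chromosome edge) + linker,
  with i.i.d. substitution errors.

Every generator is a pure function of its seed and parameters. What the
synthetic data does **not** emulate: platform-specific error profiles
(e.g. pyrosequencing homopolymer errors), restriction-site fragmentation,
sequence-dependent mappability, chromatin-driven covariance between
features, or heterogeneous per-locus targeting intensity beyond the
anchor mixture. Passing tests therefore demonstrate the correctness of
the computations and the calibration under the stated placement models,
not fidelity to any particular biological dataset.

## Problem sizes and numerical choices

The test and validation suites run at desk scale, chosen as the smallest
sizes at which the statistical checks are well powered: ~2-Mb genomes
with tens of genes for unit tests; a 10⁷-bp sequence-bearing genome with
2,000 planted sites for the pipeline round trip; 10⁴ random cases for the
classification oracle; 500 uniform replicates at N = 32,574 on
G = 2.76 × 10⁹ for calibration validity; 500 null replicates of 10⁴-site
dataset pairs for the type-I-error check; and exhaustive enumeration of
all 2×2 tables with total ≤ 60 (symmetry-reduced; row/column-swap
invariance is asserted separately) for the Fisher test. Monte-Carlo
assertions use 3-standard-error or 99%+ binomial bounds. Floor rounding
is used for calibrated windows, ties in redundancy collapse go to the
smallest position, and all interval arithmetic is half-open.

## Known limitations

- Gapped or spliced alignment is not supported; reads with indels will
  fail the identity threshold rather than map approximately.
- The uniform null for cluster calibration ignores mappability structure
  within the effective genome; G_eff absorbs it only globally.
- The random control is not matched for restriction-fragment covariates.
- Tag profiles treat tags as points; fragment extension, if desired, must
  be applied upstream.
- Exon-level annotation and transcription-factor-binding-site tracks are
  out of scope.
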
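"""Site classification against genes and feature tracks, and distance profiles.

Classification rule (applied with precedence, every site gets exactly one
class): a site is *TSS-proximal* when it lies within ±``tss_halfwidth``
(default 2,500 bp) of the TSS of any gene; otherwise *intragenic* when it
falls inside any gene's transcribed interval; *intergenic* in all other
cases. Association with CpG islands or conserved non-coding elements counts
a site whose distance to the nearest interval (0 if inside) is at most
``assoc_halfwidth`` (default 1,000 bp).

Distance profiles count (site, gene) or (site, feature) *pairs* — one site
near several TSSs contributes once per TSS — binned by signed distance,
oriented by gene strand for TSS profiles and left unoriented for strandless
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import FeatureTrack, GeneAnnotation, merge_intervals
from .sites import IntegrationSite, SiteDataset

CLASSES = ("TSS_proximal", "intragenic", "intergenic")


def _by_chrom_sorted(values: np.ndarray, chroms: np.ndarray) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom in pd.unique(chroms):
        out[chrom] = np.sort(values[chroms == chrom])
    return out


def _merged_by_chrom(df: pd.DataFrame, start_col: str, end_col: str, pad: int = 0) -> dict[str, np.ndarray]:
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        iv = np.stack([
            grp[start_col].to_numpy(dtype=np.int64) - pad,
            grp[end_col].to_numpy(dtype=np.int64) + pad,
        ], axis=1)
        out[chrom] = merge_intervals(iv)
    return out


def _in_intervals(pos: np.ndarray, merged: np.ndarray) -> np.ndarray:
    if len(merged) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < merged[idx[ok], 1]
    return res


def _near_sorted(pos: np.ndarray, anchors: np.ndarray, halfwidth: int) -> np.ndarray:
    """True where some anchor lies within ±halfwidth of the position."""
    if len(anchors) == 0:
        return np.zeros(len(pos), dtype=bool)
    lo = np.searchsorted(anchors, pos - halfwidth, side="left")
    hi = np.searchsorted(anchors, pos + halfwidth, side="right")
    return hi > lo


def classify_dataset(dataset: SiteDataset, genes: GeneAnnotation, tss_halfwidth: int = 2500) -> np.ndarray:
    """Vectorised class per site (array of strings aligned to ``dataset.df``)."""
    tss_by_chrom = _by_chrom_sorted(genes.tss, genes.df["chrom"].to_numpy()) if len(genes) else {}
    bodies = _merged_by_chrom(genes.df, "tx_start", "tx_end") if len(genes) else {}
    classes = np.full(dataset.n, "intergenic", dtype=object)
    for chrom, grp in dataset.df.groupby("chrom", sort=False):
        pos = grp["position"].to_numpy(dtype=np.int64)
        idx = grp.index.to_numpy()
        near_tss = _near_sorted(pos, tss_by_chrom.get(chrom, np.empty(0, dtype=np.int64)), tss_halfwidth)
        inside = _in_intervals(pos, bodies.get(chrom, np.empty((0, 2), dtype=np.int64)))
        classes[idx[near_tss]] = "TSS_proximal"
        classes[idx[~near_tss & inside]] = "intragenic"
    return classes


def classify_site(
    site: IntegrationSite,
    genes: GeneAnnotation,
    tss_halfwidth: int = 2500,
    target_window: int = 50000,
) -> tuple[str, list[tuple[str, int]]]:
    """Class of a single site plus its targeted genes.

    Returns ``(class, hits)`` where hits lists ``(gene_id, signed TSS
    distance)`` for every gene whose TSS lies within ±``target_window``,
    the distance oriented by gene strand (positive = downstream of the TSS).
    """
    cls = "intergenic"
    hits: list[tuple[str, int]] = []
    if len(genes):
        sub = genes.df[genes.df["chrom"] == site.chrom]
        tss = genes.tss[sub.index.to_numpy()]
        sign = genes.strand_sign[sub.index.to_numpy()]
        d_signed = (site.position - tss) * sign
        if len(sub) and (np.abs(site.position - tss) <= tss_halfwidth).any():
            cls = "TSS_proximal"
        elif len(sub) and (
            (sub["tx_start"].to_numpy() <= site.position) & (site.position < sub["tx_end"].to_numpy())
        ).any():
            cls = "intragenic"
        for gid, d in zip(sub["gene_id"], d_signed):
            if abs(int(d)) <= target_window:
                hits.append((gid, int(d)))
    return cls, hits


@dataclass
class AnnotationResult:
    """Per-site classes and a Table-1-style summary for one dataset."""

    dataset_name: str
    classes: np.ndarray
    summary: dict[str, float]
    tss_halfwidth: int
    assoc_halfwidth: int

    def as_row(self) -> dict[str, float]:
        return {"dataset": self.dataset_name, **self.summary}


def annotate_dataset(
    dataset: SiteDataset,
    genes: GeneAnnotation,
    cpg: FeatureTrack,
    cnc: FeatureTrack,
    tss_halfwidth: int = 2500,
    assoc_halfwidth: int = 1000,
) -> AnnotationResult:
    """Classify every site and summarise class and feature-association fractions."""
    if dataset.n == 0:
        raise ValueError("cannot annotate an empty dataset")
    classes = classify_dataset(dataset, genes, tss_halfwidth=tss_halfwidth)
    assoc = {}
    for track in (cpg, cnc):
        padded = _merged_by_chrom(track.df, "start", "end", pad=assoc_halfwidth) if len(track) else {}
        flags = np.zeros(dataset.n, dtype=bool)
        for chrom, grp in dataset.df.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy(dtype=np.int64)
            flags[grp.index.to_numpy()] = _in_intervals(pos, padded.get(chrom, np.empty((0, 2), dtype=np.int64)))
        assoc[track.name] = flags
    n = dataset.n
    summary = {
        "intergenic": float(np.mean(classes == "intergenic")),
        "tss_proximal": float(np.mean(classes == "TSS_proximal")),
        "intragenic": float(np.mean(classes == "intragenic")),
        "cpg": float(np.mean(assoc[cpg.name])),
        "cnc": float(np.mean(assoc[cnc.name])),
        "total": n,
    }
    return AnnotationResult(dataset.name, classes, summary, tss_halfwidth, assoc_halfwidth)


@dataclass
class ProfileMatrix:
    """Binned pair counts around an anchor set.

    ``edges`` are half-open bin boundaries in bp offset from the anchor;
    ``counts`` is one value per bin. ``percent`` normalises counts to sum
    to 100 over the window.
    """

    anchor_kind: str
    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("counts/edges length mismatch")

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    @property
    def percent(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return 100.0 * self.counts / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset_lo": self.edges[:-1],
            "offset_hi": self.edges[1:],
            "count": self.counts,
            "percent": self.percent,
        })


def _profile_edges(window: int, bin_size: int, center_zero: bool) -> np.ndarray:
    if center_zero:
        centers = np.arange(-window, window + bin_size, bin_size, dtype=np.int64)
        return np.concatenate([centers - bin_size // 2, [centers[-1] + (bin_size - bin_size // 2)]])
    if (2 * window) % bin_size != 0:
        raise ValueError("bin size must divide 2×window")
    return np.arange(-window, window + bin_size, bin_size, dtype=np.int64)


def _pair_distances(
    dataset: SiteDataset,
    anchors: np.ndarray,
    anchor_chroms: np.ndarray,
    signs: np.ndarray,
    window: int,
) -> np.ndarray:
    """Signed distances of all (site, anchor) pairs with |d| ≤ window."""
    site_pos = {
        chrom: np.sort(grp["position"].to_numpy(dtype=np.int64))
        for chrom, grp in dataset.df.groupby("chrom", sort=False)
    }
    chunks = []
    for a, chrom, sign in zip(anchors, anchor_chroms, signs):
        pos = site_pos.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, a - window, side="left")
        hi = np.searchsorted(pos, a + window, side="right")
        if hi > lo:
            chunks.append((pos[lo:hi] - a) * sign)
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks)


def tss_distance_profile(
    dataset: SiteDataset,
    genes: GeneAnnotation,
    window: int = 50000,
    bin_size: int = 2500,
    center_zero: bool = False,
) -> ProfileMatrix:
    """Distribution of site–TSS distances over all (site, gene) pairs.

    Distances are oriented by gene strand: positive offsets are downstream
    of the TSS. With ``center_zero`` the bin containing 0 spans
    [−bin/2, +bin/2) (used for the 50-bp zoom so the promoter dip straddles
    the origin); otherwise bins are edge-aligned at multiples of
    ``bin_size`` from −window, which makes coarse profiles exact
    aggregations of fine ones.
    """
    edges = _profile_edges(window, bin_size, center_zero)
    d = _pair_distances(dataset, genes.tss, genes.df["chrom"].to_numpy(), genes.strand_sign, window)
    if len(d) == 0:
        warnings.warn("no (site, gene) pairs within the window; profile is all zero")
    counts, _ = np.histogram(d, bins=edges)
    return ProfileMatrix("TSS", edges, counts.astype(np.int64))


def midpoint_distance_profile(
    dataset: SiteDataset,
    track: FeatureTrack,
    window: int = 50000,
    bin_size: int = 2500,
    center_zero: bool = False,
) -> ProfileMatrix:
    """Distribution of site–midpoint distances for a strandless feature track."""
    edges = _profile_edges(window, bin_size, center_zero)
    mids = track.midpoints
    signs = np.ones(len(mids), dtype=np.int64)
    d = _pair_distances(dataset, mids, track.df["chrom"].to_numpy(), signs, window)
    if len(d) == 0:
        warnings.warn("no (site, feature) pairs within the window; profile is all zero")
    counts, _ = np.histogram(d, bins=edges)
    return ProfileMatrix(f"{track.name}_mid", edges, counts.astype(np.int64))


def tss_window_coverage_fraction(
    genes: GeneAnnotation,
    genome,
    tss_halfwidth: int = 2500,
) -> float:
    """Fraction of the genome covered by the union of ±halfwidth TSS windows.

    This is the expected TSS-proximal fraction of uniformly placed sites,
    used as the closed-form check on random controls.
    """
    from .genome import interval_union_length

    lengths = genome.lengths
    covered = 0
    tss = genes.tss
    chroms = genes.df["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        t = tss[chroms == chrom]
        iv = np.stack([
            np.maximum(t - tss_halfwidth, 0),
            np.minimum(t + tss_halfwidth + 1, lengths[chrom]),
        ], axis=1)
        covered += interval_union_length(iv)
    return covered / genome.total_length
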
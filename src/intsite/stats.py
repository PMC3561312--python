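"""Random controls and pairwise dataset comparison via Fisher's exact test.

The two-sided Fisher test is implemented directly: conditioning on the
margins of the 2×2 table, the first cell follows a hypergeometric
distribution; the two-sided p-value sums the point probabilities of every
table (same margins) whose probability does not exceed that of the observed
table — the convention of mainstream statistical software. Point
probabilities are computed with log-gamma arithmetic so counts in the 10⁴
range do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .genome import GenomeModel
from .sites import SiteDataset


def random_control(genome: GenomeModel, n_sites: int, seed: int = 0, name: str = "random") -> SiteDataset:
    """Uniformly placed control sites with random strand (unique, seeded)."""
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.asarray([genome.lengths[c] for c in names], dtype=np.int64)
    total = lengths.sum()
    if n_sites > 2 * total:
        raise ValueError("n_sites exceeds available unique (position, strand) pairs")
    bounds = np.cumsum(lengths)
    starts = bounds - lengths
    # draw (position, strand) keys until n_sites unique ones accumulate
    unique_keys = np.empty(0, dtype=np.int64)
    while len(unique_keys) < n_sites:
        draw = rng.integers(0, 2 * total, size=max(2 * (n_sites - len(unique_keys)), 64))
        unique_keys = np.unique(np.concatenate([unique_keys, draw]))
    chosen = unique_keys[rng.permutation(len(unique_keys))[:n_sites]]
    linear = chosen // 2
    strand_bits = chosen % 2
    ci = np.searchsorted(bounds, linear, side="right")
    return SiteDataset.from_arrays(
        name,
        [names[i] for i in ci],
        linear - starts[ci],
        np.where(strand_bits == 1, "+", "-"),
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = dataset 1 in/not in category, (c, d) = dataset 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    n = r1 + r2
    return (
        gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
        + gammaln(r2 + 1) - gammaln(c1 - a + 1) - gammaln(r2 - c1 + a + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (point-probability method).

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more likely than the observed
    one (a small relative slack absorbs floating-point ties).
    """
    r1, r2, c1, c2 = table.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate margins: every margin must be positive")
    a_lo = max(0, c1 - r2)
    a_hi = min(r1, c1)
    a_all = np.arange(a_lo, a_hi + 1)
    logp = _log_hypergeom_pmf(a_all.astype(float), r1, r2, c1)
    log_obs = _log_hypergeom_pmf(np.asarray([float(table.a)]), r1, r2, c1)[0]
    include = logp <= log_obs + 1e-7
    if include.all():
        return 1.0
    p = float(np.exp(logsumexp(logp[include])))
    # extreme tables can underflow double precision; keep p strictly positive
    return min(max(p, 5e-324), 1.0)


@dataclass
class CategoryComparison:
    table: ContingencyTable2x2
    fraction_a: float
    fraction_b: float
    p_value: float

    def as_dict(self) -> dict:
        t = self.table
        return {
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "fraction_a": self.fraction_a,
            "fraction_b": self.fraction_b,
            "p_value": self.p_value,
        }


def compare_category(
    dataset_a: SiteDataset,
    dataset_b: SiteDataset,
    in_category: Callable[[SiteDataset], np.ndarray],
) -> CategoryComparison:
    """Fisher comparison of a per-site category between two datasets.

    ``in_category`` maps a dataset to a boolean mask over its sites (built
    from one shared annotation, so both datasets are judged under identical
    tracks and parameters). Returns the 2×2 table, per-dataset fractions
    and the two-sided p-value.
    """
    mask_a = np.asarray(in_category(dataset_a), dtype=bool)
    mask_b = np.asarray(in_category(dataset_b), dtype=bool)
    if len(mask_a) != dataset_a.n or len(mask_b) != dataset_b.n:
        raise ValueError("category mask length does not match dataset size")
    a, b = int(mask_a.sum()), int((~mask_a).sum())
    c, d = int(mask_b.sum()), int((~mask_b).sum())
    table = ContingencyTable2x2(a, b, c, d)
    return CategoryComparison(table, a / dataset_a.n, c / dataset_b.n, fisher_two_sided(table))


def class_extractor(genes, class_name: str, tss_halfwidth: int = 2500) -> Callable[[SiteDataset], np.ndarray]:
    """Membership mask for one annotation class (TSS_proximal/intragenic/intergenic)."""
    from .annotate import classify_dataset

    def extract(dataset: SiteDataset) -> np.ndarray:
        return classify_dataset(dataset, genes, tss_halfwidth=tss_halfwidth) == class_name

    return extract


def feature_association_extractor(track, assoc_halfwidth: int = 1000) -> Callable[[SiteDataset], np.ndarray]:
    """Membership mask: site within ±halfwidth of (or inside) any track interval."""
    from .annotate import _in_intervals, _merged_by_chrom

    def extract(dataset: SiteDataset) -> np.ndarray:
        padded = _merged_by_chrom(track.df, "start", "end", pad=assoc_halfwidth) if len(track) else {}
        flags = np.zeros(dataset.n, dtype=bool)
        for chrom, grp in dataset.df.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy(dtype=np.int64)
            flags[grp.index.to_numpy()] = _in_intervals(
                pos, padded.get(chrom, np.empty((0, 2), dtype=np.int64))
            )
        return flags

    return extract


def cluster_membership_extractor(make_params: Callable[[SiteDataset], "object"]) -> Callable[[SiteDataset], np.ndarray]:
    """Membership mask: site inside a cluster called on its own dataset.

    ``make_params`` builds ClusterParams (typically with a freshly
    calibrated window) for the dataset being tested, mirroring the
    numerosity adjustment of the published analysis.
    """
    from .clustering import call_clusters

    def extract(dataset: SiteDataset) -> np.ndarray:
        clusters = call_clusters(dataset, make_params(dataset))
        flags = np.zeros(dataset.n, dtype=bool)
        for c in clusters.clusters:
            flags[list(c.site_index)] = True
        return flags

    return extract
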
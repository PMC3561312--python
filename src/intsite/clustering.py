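"""Numerosity-adjusted integration-cluster calling and cluster overlap.

A cluster (hot spot) is a run of at least ``n_min`` sites spanning no more
than a window ``w``, where ``w`` is calibrated so that, under uniform
placement of the dataset's ``n_sites`` over an effective genome of
``G_eff`` bp, the probability that a given site is followed by at least
``n_min − 1`` further sites within ``w`` downstream (the *clump
probability*) stays below ``alpha``. Modelling the uniform sites as a
homogeneous Poisson process of rate λ = n_sites / G_eff, the clump
probability is P[Poisson(λw) ≥ n_min − 1]; for n_min = 3 and alpha = 0.01
this solves 1 − e^(−μ)(1 + μ) = 0.01 at μ* ≈ 0.148555 and
w = floor(μ*·G_eff / n_sites). The calibrated window is therefore inversely
proportional to dataset size — larger datasets need tighter windows for the
same false-cluster rate.

``DEFAULT_EFFECTIVE_GENOME`` (2.76 × 10⁹ bp) is the package's calibration
constant for the mappable human genome; it is a required, documented input
rather than something inferred from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .sites import SiteDataset

DEFAULT_EFFECTIVE_GENOME = 2_760_000_000


@dataclass
class ClusterParams:
    """Calibration parameters for cluster calling."""

    n_min: int = 3
    alpha: float = 0.01
    g_eff: int = DEFAULT_EFFECTIVE_GENOME
    w: int = 0  # calibrated window, bp

    def __post_init__(self) -> None:
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.w < 0:
            raise ValueError("w must be >= 0")


@dataclass(frozen=True)
class Cluster:
    chrom: str
    start: int  # first site position
    end: int  # last site position + 1 (half-open)
    site_count: int
    site_index: tuple[int, ...] = ()


@dataclass
class ClusterSet:
    params: ClusterParams
    clusters: list[Cluster] = field(default_factory=list)
    n_dataset_sites: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def sites_in_clusters(self) -> int:
        return sum(c.site_count for c in self.clusters)

    @property
    def fraction_in_clusters(self) -> float:
        if self.n_dataset_sites == 0:
            return 0.0
        return self.sites_in_clusters / self.n_dataset_sites

    def summary(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "sites_in_clusters": self.sites_in_clusters,
            "fraction_in_clusters": self.fraction_in_clusters,
            "w": self.params.w,
            "n_min": self.params.n_min,
            "alpha": self.params.alpha,
            "g_eff": self.params.g_eff,
        }


def clump_mu(n_min: int, alpha: float) -> float:
    """Solve P[Poisson(μ) ≥ n_min − 1] = alpha for μ."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    f = lambda mu: stats.poisson.sf(n_min - 2, mu) - alpha
    return float(optimize.brentq(f, 1e-12, 1e3, xtol=1e-12, rtol=1e-14))


def _clump_frequency(positions: np.ndarray, w: int, n_min: int) -> float:
    """Observed fraction of sites with ≥ n_min − 1 further sites ≤ w downstream."""
    pos = np.sort(positions)
    downstream = np.searchsorted(pos, pos + w, side="right") - np.arange(1, len(pos) + 1)
    return float(np.mean(downstream >= n_min - 1))


def calibrate_window(
    n_sites: int,
    g_eff: int = DEFAULT_EFFECTIVE_GENOME,
    n_min: int = 3,
    alpha: float = 0.01,
    method: str = "analytic",
    seed: int | None = None,
    n_reps: int = 200,
) -> int:
    """Largest window w keeping the per-site clump probability below alpha.

    ``analytic`` solves the Poisson model in closed form (w = floor(μ*·G/N)).
    ``montecarlo`` draws ``n_reps`` uniform datasets of ``n_sites`` on
    [0, g_eff) and bisects on integer w until the empirical clump frequency
    brackets alpha; both methods agree to within a few percent.
    """
    if n_sites < n_min:
        raise ValueError("n_sites must be >= n_min")
    if method == "analytic":
        mu = clump_mu(n_min, alpha)
        return int(np.floor(mu * g_eff / n_sites))
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        if n_reps < 50:
            raise ValueError("montecarlo calibration needs n_reps >= 50")
        reps = [np.sort(rng.integers(0, g_eff, size=n_sites)) for _ in range(n_reps)]

        def freq(w: int) -> float:
            return float(np.mean([_clump_frequency(p, w, n_min) for p in reps]))

        lo, hi = 1, 2
        for _ in range(64):
            if freq(hi) >= alpha:
                break
            lo, hi = hi, hi * 2
        else:
            raise RuntimeError("montecarlo calibration did not converge")
        # invariant: freq(lo) < alpha <= freq(hi); freq is monotone in w
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if freq(mid) < alpha:
                lo = mid
            else:
                hi = mid
        return lo
    raise ValueError(f"unknown calibration method {method!r}")


def _call_positions(pos: np.ndarray, w: int, n_min: int) -> list[tuple[int, int]]:
    """Maximal clusters over sorted positions: index ranges [i, j] inclusive."""
    n = len(pos)
    seeds = [
        (i, i + n_min - 1)
        for i in range(n - n_min + 1)
        if pos[i + n_min - 1] - pos[i] <= w
    ]
    merged: list[list[int]] = []
    for s, e in seeds:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_clusters(dataset: SiteDataset, params: ClusterParams) -> ClusterSet:
    """Call maximal clusters per chromosome (strand ignored).

    Every run of ``n_min`` consecutive position-sorted sites spanning at
    most ``w`` bp seeds a cluster; overlapping seeds chain into maximal
    clusters whose span is [first site, last site] (stored half-open).
    """
    out = ClusterSet(params, [], dataset.n)
    for chrom, grp in dataset.df.groupby("chrom", sort=True):
        order = np.argsort(grp["position"].to_numpy(), kind="stable")
        pos = grp["position"].to_numpy(dtype=np.int64)[order]
        idx = grp.index.to_numpy()[order]
        for s, e in _call_positions(pos, params.w, params.n_min):
            out.clusters.append(
                Cluster(chrom, int(pos[s]), int(pos[e]) + 1, e - s + 1, tuple(int(i) for i in idx[s : e + 1]))
            )
    return out


def overlap_clusters(
    a: ClusterSet,
    b: ClusterSet,
    min_overlap: int = 1,
) -> tuple[float, list[tuple[int, int, int]]]:
    """Fraction of a's clusters overlapping ≥1 cluster of b by ≥ min_overlap bp.

    Overlap of half-open spans is max(0, min(e1, e2) − max(s1, s2)).
    Returns the fraction plus matched (a index, b index, overlap bp) pairs.
    Not symmetric in (a, b).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, c in enumerate(b.clusters):
        b_by_chrom.setdefault(c.chrom, []).append((c.start, c.end, j))
    pairs: list[tuple[int, int, int]] = []
    hit = np.zeros(len(a.clusters), dtype=bool)
    for i, c in enumerate(a.clusters):
        for s, e, j in b_by_chrom.get(c.chrom, ()):
            ov = min(c.end, e) - max(c.start, s)
            if ov >= min_overlap:
                pairs.append((i, j, int(ov)))
                hit[i] = True
    fraction = float(hit.mean()) if len(a.clusters) else 0.0
    return fraction, pairs


def false_cluster_rate(
    n_sites: int,
    g_eff: int,
    params: ClusterParams,
    n_reps: int = 100,
    seed: int | None = None,
) -> dict:
    """Clump frequency and cluster counts under uniform placement.

    Validation harness for the calibration: with ``params.w`` set by
    :func:`calibrate_window`, the mean per-site clump frequency should sit
    within Monte-Carlo error of ``params.alpha``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.empty(n_reps)
    n_clusters = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        pos = np.sort(rng.integers(0, g_eff, size=n_sites))
        freqs[r] = _clump_frequency(pos, params.w, params.n_min)
        n_clusters[r] = len(_call_positions(pos, params.w, params.n_min))
    mean = float(freqs.mean())
    se = float(freqs.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
    return {
        "mean_clump_frequency": mean,
        "se_clump_frequency": se,
        "per_replicate_frequency": freqs,
        "per_replicate_cluster_count": n_clusters,
    }
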
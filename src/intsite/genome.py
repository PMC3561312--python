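"""Core genomic containers: genome model, gene annotation, feature and tag tracks.

All coordinates are 0-based, half-open ([start, end)), matching BED. The TSS
of a gene is ``tx_start`` on the + strand and ``tx_end - 1`` on the − strand
(the last base of the half-open interval, i.e. the UCSC txEnd convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tx_start", "tx_end"]
FEATURE_COLUMNS = ["chrom", "start", "end"]
TAG_COLUMNS = ["chrom", "position", "strand"]


@dataclass
class GenomeModel:
    """Chromosome names/lengths, an effective (mappable) size, optional sequence.

    Parameters
    ----------
    chromosomes
        Ordered list of ``(name, length)`` pairs, lengths in bp.
    effective_size
        Mappable genome length used as the support of the uniform null in
        cluster calibration. Defaults to the sum of chromosome lengths.
    sequences
        Optional per-chromosome nucleotide strings; required only by read
        simulation and mapping.
    """

    chromosomes: list[tuple[str, int]]
    effective_size: int | None = None
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.effective_size is None:
            self.effective_size = self.total_length
        if self.effective_size > self.total_length:
            raise ValueError("effective_size exceeds total genome length")
        if self.sequences is not None:
            for name, length in self.chromosomes:
                seq = self.sequences.get(name)
                if seq is not None and len(seq) != length:
                    raise ValueError(f"sequence length mismatch for {name!r}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return int(sum(length for _, length in self.chromosomes))

    def linear_offsets(self) -> dict[str, int]:
        """Start offset of each chromosome in the concatenated coordinate."""
        offsets, cum = {}, 0
        for name, length in self.chromosomes:
            offsets[name] = cum
            cum += length
        return offsets

    def from_linear(self, linear: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map concatenated-genome positions to (chrom index, position)."""
        bounds = np.cumsum([length for _, length in self.chromosomes])
        idx = np.searchsorted(bounds, linear, side="right")
        starts = bounds - np.asarray([length for _, length in self.chromosomes])
        return idx, np.asarray(linear) - starts[idx]

    def sequence(self, chrom: str) -> str:
        if self.sequences is None or chrom not in self.sequences:
            raise ValueError(f"genome carries no sequence for {chrom!r}")
        return self.sequences[chrom]


@dataclass
class GeneAnnotation:
    """Gene records with strand-aware TSS derivation.

    ``df`` holds columns gene_id, chrom, strand, tx_start, tx_end
    (0-based half-open). The TSS is tx_start for + genes and tx_end − 1
    for − genes.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df
        missing = set(GENE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if len(df):
            if not df["strand"].isin(STRANDS).all():
                bad = df.loc[~df["strand"].isin(STRANDS), "strand"].iloc[0]
                raise ValueError(f"unknown strand symbol {bad!r}")
            if (df["tx_start"] >= df["tx_end"]).any():
                raise ValueError("gene with tx_start >= tx_end")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tss(self) -> np.ndarray:
        """Per-gene TSS position (tx_start on +, tx_end − 1 on −)."""
        s = self.df["tx_start"].to_numpy(dtype=np.int64, copy=True)
        minus = (self.df["strand"] == "-").to_numpy()
        s[minus] = self.df["tx_end"].to_numpy(dtype=np.int64)[minus] - 1
        return s

    @property
    def strand_sign(self) -> np.ndarray:
        """+1 for + genes, −1 for − genes (orients signed TSS distances)."""
        return np.where(self.df["strand"].to_numpy() == "+", 1, -1).astype(np.int64)

    def validate_against(self, genome: GenomeModel) -> None:
        lengths = genome.lengths
        for _, row in self.df.iterrows():
            if row["chrom"] not in lengths:
                raise ValueError(f"gene {row['gene_id']!r} on unknown chromosome {row['chrom']!r}")
            if row["tx_end"] > lengths[row["chrom"]]:
                raise ValueError(f"gene {row['gene_id']!r} extends past chromosome end")


@dataclass
class FeatureTrack:
    """Strandless genomic intervals (CpG islands, conserved non-coding sequences).

    Midpoints are ``floor((start + end) / 2)``. Normalised tracks are sorted
    by (chrom, start).
    """

    name: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FEATURE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df
        missing = set(FEATURE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("feature interval with end <= start")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def midpoints(self) -> np.ndarray:
        s = self.df["start"].to_numpy(dtype=np.int64)
        e = self.df["end"].to_numpy(dtype=np.int64)
        return (s + e) // 2


@dataclass
class TagTrack:
    """Point tags (ChIP-seq 5′ positions) with strand."""

    name: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TAG_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df
        missing = set(TAG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"tag table missing columns: {sorted(missing)}")
        if len(df) and not df["strand"].isin(STRANDS).all():
            raise ValueError("unknown strand symbol in tag track")
        self.df = df.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate_against(self, genome: GenomeModel) -> None:
        lengths = genome.lengths
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"tag on unknown chromosome {chrom!r}")
            if (grp["position"] < 0).any() or (grp["position"] >= lengths[chrom]).any():
                raise ValueError(f"tag position out of bounds on {chrom!r}")


def interval_union_length(intervals: np.ndarray) -> int:
    """Total length covered by a set of half-open intervals (n × 2 array)."""
    if len(intervals) == 0:
        return 0
    iv = intervals[np.argsort(intervals[:, 0], kind="stable")]
    total, cur_s, cur_e = 0, iv[0, 0], iv[0, 1]
    for s, e in iv[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return int(total + cur_e - cur_s)


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of half-open intervals as a sorted, disjoint (m × 2) array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = intervals[np.argsort(intervals[:, 0], kind="stable")]
    out = [[iv[0, 0], iv[0, 1]]]
    for s, e in iv[1:]:
        if s > out[-1][1]:
            out.append([s, e])
        else:
            out[-1][1] = max(out[-1][1], e)
    return np.asarray(out, dtype=np.int64)
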
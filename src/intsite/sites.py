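"""Integration-site containers.

An integration site is the single genomic base adjacent to the vector's
3′ LTR (the junction base recovered by ligation-mediated PCR), with the
strand of the proviral orientation. A dataset is a named, deduplicated,
sorted collection of such sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel, STRANDS

SITE_COLUMNS = ["chrom", "position", "strand", "read_count"]


@dataclass(frozen=True)
class IntegrationSite:
    chrom: str
    position: int
    strand: str
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class SiteDataset:
    """Named set of unique (chrom, position, strand) integration sites.

    Duplicate records are collapsed on construction with their read counts
    summed; the table is sorted by (chrom, position, strand). ``n`` is the
    number of unique sites.
    """

    name: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SITE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "read_count" not in df.columns:
            df["read_count"] = 1
        missing = set(SITE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        df = df[SITE_COLUMNS]
        if len(df):
            if not df["strand"].isin(STRANDS).all():
                bad = df.loc[~df["strand"].isin(STRANDS), "strand"].iloc[0]
                raise ValueError(f"unknown strand symbol {bad!r}")
            if (df["read_count"] < 1).any():
                raise ValueError("read_count must be >= 1")
            df = (
                df.groupby(["chrom", "position", "strand"], as_index=False, sort=True)
                ["read_count"].sum()
            )
            df = df.sort_values(["chrom", "position", "strand"], kind="stable")
        df["position"] = df["position"].astype(np.int64) if len(df) else df.get("position", pd.Series(dtype=np.int64))
        df["read_count"] = df["read_count"].astype(np.int64) if len(df) else df.get("read_count", pd.Series(dtype=np.int64))
        self.df = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        """Number of unique sites."""
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def sites(self) -> list[IntegrationSite]:
        return [
            IntegrationSite(r.chrom, int(r.position), r.strand, int(r.read_count))
            for r in self.df.itertuples(index=False)
        ]

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted position arrays keyed by chromosome (strand ignored)."""
        return {
            chrom: np.sort(grp["position"].to_numpy(dtype=np.int64))
            for chrom, grp in self.df.groupby("chrom", sort=True)
        }

    def validate_against(self, genome: GenomeModel) -> None:
        lengths = genome.lengths
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"site on unknown chromosome {chrom!r}")
            if (grp["position"] < 0).any() or (grp["position"] >= lengths[chrom]).any():
                raise ValueError(f"site position out of bounds on {chrom!r}")

    @classmethod
    def from_arrays(
        cls,
        name: str,
        chrom: np.ndarray | list,
        position: np.ndarray | list,
        strand: np.ndarray | list,
        read_count: np.ndarray | list | None = None,
    ) -> "SiteDataset":
        data = {"chrom": chrom, "position": position, "strand": strand}
        if read_count is not None:
            data["read_count"] = read_count
        return cls(name, pd.DataFrame(data))
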
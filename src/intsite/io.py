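"""Readers and writers for the formats the pipeline touches.

BED records are 0-based half-open; site TSV files are tab-separated with a
header line, ``#`` comment lines ignored, positions 0-based. Readers reject
malformed input (with the offending line number) rather than repairing it;
every writer produces files its own reader accepts identically after
normalization.

Chromosome names are matched exactly; :func:`normalize_chrom_names` can
strip or add a ``chr`` prefix when two sources disagree.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import FeatureTrack, GeneAnnotation, GenomeModel, STRANDS, TagTrack
from .sites import SiteDataset

SITE_TSV_HEADER = ["chrom", "position", "strand", "read_count"]


class FormatError(ValueError):
    """Malformed record in an input file."""


def _rows(path: str | os.PathLike) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            yield lineno, line.split("\t")


def _check_strand(symbol: str, path, lineno: int) -> str:
    if symbol not in STRANDS:
        raise FormatError(f"{path}:{lineno}: unknown strand symbol {symbol!r}")
    return symbol


# ---------------------------------------------------------------------------
# integration sites

def read_sites(path: str | os.PathLike, format: str = "tsv", name: str | None = None) -> SiteDataset:
    """Read a site dataset from TSV or BED.

    TSV columns: chrom, position, strand[, read_count] (header required).
    BED6: the site position is the 0-based ``start`` field, read count is
    taken from the score column when integral. Duplicate (chrom, position,
    strand) records are collapsed with read counts summed.
    """
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    records: list[tuple[str, int, str, int]] = []
    if format == "tsv":
        header: list[str] | None = None
        for lineno, fields in _rows(path):
            if header is None:
                header = fields
                missing = {"chrom", "position", "strand"} - set(header)
                if missing:
                    raise FormatError(f"{path}:{lineno}: header missing {sorted(missing)}")
                continue
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            row = dict(zip(header, fields))
            try:
                pos = int(row["position"])
                count = int(row.get("read_count", 1))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            records.append((row["chrom"], pos, _check_strand(row["strand"], path, lineno), count))
    elif format == "bed":
        for lineno, fields in _rows(path):
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: site BED needs 6 columns")
            try:
                start = int(fields[1])
                score = fields[4]
                count = int(score) if score not in (".", "") else 1
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            records.append((fields[0], start, _check_strand(fields[5], path, lineno), max(count, 1)))
    else:
        raise ValueError(f"unknown site format {format!r}")
    df = pd.DataFrame(records, columns=SITE_TSV_HEADER)
    return SiteDataset(name, df)


def write_sites(dataset: SiteDataset, path: str | os.PathLike, format: str = "tsv") -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(SITE_TSV_HEADER) + "\n")
            for r in dataset.df.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.position}\t{r.strand}\t{r.read_count}\n")
    elif format == "bed":
        with open(path, "w") as fh:
            for i, r in enumerate(dataset.df.itertuples(index=False)):
                fh.write(f"{r.chrom}\t{r.position}\t{r.position + 1}\t{dataset.name}_{i}\t{r.read_count}\t{r.strand}\n")
    else:
        raise ValueError(f"unknown site format {format!r}")


# ---------------------------------------------------------------------------
# genes and tracks

def read_genes(path: str | os.PathLike) -> GeneAnnotation:
    """Read gene records from BED6 (one interval per gene, name = gene_id)."""
    records = []
    for lineno, fields in _rows(path):
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: gene BED needs 6 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if end <= start:
            raise FormatError(f"{path}:{lineno}: interval end <= start")
        records.append((fields[3], fields[0], _check_strand(fields[5], path, lineno), start, end))
    return GeneAnnotation(pd.DataFrame(records, columns=["gene_id", "chrom", "strand", "tx_start", "tx_end"]))


def write_genes(genes: GeneAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in genes.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.tx_start}\t{r.tx_end}\t{r.gene_id}\t0\t{r.strand}\n")


def read_features(path: str | os.PathLike, name: str | None = None) -> FeatureTrack:
    """Read a strandless interval track (CpG islands, CNCs) from BED3+."""
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    records = []
    for lineno, fields in _rows(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if end <= start:
            raise FormatError(f"{path}:{lineno}: interval end <= start")
        records.append((fields[0], start, end))
    return FeatureTrack(name, pd.DataFrame(records, columns=["chrom", "start", "end"]))


def write_features(track: FeatureTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in track.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_tags(path: str | os.PathLike, name: str | None = None) -> TagTrack:
    """Read a tag track (BED6 of 1-bp tag positions, or BED3 → + strand)."""
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    records = []
    for lineno, fields in _rows(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        try:
            start = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        strand = _check_strand(fields[5], path, lineno) if len(fields) >= 6 else "+"
        records.append((fields[0], start, strand))
    return TagTrack(name, pd.DataFrame(records, columns=["chrom", "position", "strand"]))


def write_tags(track: TagTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(track.df.itertuples(index=False)):
            fh.write(f"{r.chrom}\t{r.position}\t{r.position + 1}\t{track.name}_{i}\t0\t{r.strand}\n")


def write_clusters(clusters, path: str | os.PathLike) -> None:
    """Write a ClusterSet as BED: interval = cluster span, score = site count."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters.clusters):
            if c.end <= c.start:
                raise ValueError("cluster interval end <= start")
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tcluster_{i}\t{c.site_count}\t.\n")


def read_clusters_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cluster BED back as a plain table (chrom, start, end, site_count)."""
    records = []
    for lineno, fields in _rows(path):
        if len(fields) < 5:
            raise FormatError(f"{path}:{lineno}: cluster BED needs >= 5 columns")
        try:
            records.append((fields[0], int(fields[1]), int(fields[2]), int(fields[4])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(records, columns=["chrom", "start", "end", "site_count"])


# ---------------------------------------------------------------------------
# sequences

def write_genome_fasta(genome: GenomeModel, path: str | os.PathLike) -> None:
    if genome.sequences is None:
        raise ValueError("genome carries no sequence")
    records = [SeqRecord(Seq(genome.sequence(name)), id=name, description="") for name in genome.names]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | os.PathLike, effective_size: int | None = None) -> GenomeModel:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    chroms = [(name, len(seq)) for name, seq in seqs.items()]
    return GenomeModel(chroms, effective_size=effective_size, sequences=seqs)


def write_reads_fasta(reads, path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: str | os.PathLike, format: str = "fasta"):
    from .pipeline import ReadRecord

    return [ReadRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), format)]


# ---------------------------------------------------------------------------
# utilities

def normalize_chrom_names(df: pd.DataFrame, column: str = "chrom", prefix: str = "chr", add: bool = True) -> pd.DataFrame:
    """Strip or add a chromosome-name prefix (exact matching elsewhere)."""
    out = df.copy()
    if add:
        out[column] = [c if c.startswith(prefix) else prefix + c for c in out[column]]
    else:
        out[column] = [c[len(prefix):] if c.startswith(prefix) else c for c in out[column]]
    return out
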
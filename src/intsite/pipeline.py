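"""From raw vector–genome junction reads to unique integration sites.

Stages: (1) trim the LTR tail (must match at the read start) and the linker;
(2) drop fragments below a minimum length and exact duplicate fragments;
(3) map each fragment to the genome by k-mer seeding plus ungapped extension,
keeping only unique best hits above an identity floor; (4) collapse mapped
positions within a small tolerance into unique sites. The run report
accounts for every input read exactly once.

Mapping is intentionally self-contained (sorted k-mer index over both
strands, no gaps): reads are amplicons copied from the genome, so ungapped
identity is the right model and there is no external aligner to configure.
The integration coordinate is the genomic base of the fragment's first
(LTR-proximal) base; on the − strand that is the highest coordinate of the
aligned interval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel
from .sites import SiteDataset

_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
    _ENCODE[ord(chr(b).lower())] = i

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ReadRecord:
    """A raw junction read."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"read {self.read_id!r} has non-ACGTN characters")


@dataclass(frozen=True)
class Fragment:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class MappedFragment:
    read_id: str
    chrom: str
    position: int  # junction (LTR-proximal) base
    strand: str
    identity: float
    n_best_hits: int


@dataclass
class Rejection:
    read_id: str
    reason: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_junction(
    read: ReadRecord,
    ltr_tail: str,
    linker: str,
    max_mismatch: int = 2,
    min_linker_match: int = 6,
) -> Fragment | Rejection:
    """Extract the genomic fragment between the LTR tail and the linker.

    The LTR tail must match at read position 0 with at most ``max_mismatch``
    substitutions; otherwise the read is rejected with reason ``no_ltr``.
    The linker is located as the earliest occurrence (full, or truncated at
    the read end with at least ``min_linker_match`` matched bases) with at
    most ``max_mismatch`` substitutions; absent linkers leave the fragment
    running to the read end. An empty fragment rejects with
    ``empty_after_trim``.
    """
    if len(ltr_tail) < 8:
        raise ValueError("ltr_tail must be at least 8 bp")
    seq = read.sequence
    if len(seq) < len(ltr_tail) or _hamming(seq[: len(ltr_tail)], ltr_tail) > max_mismatch:
        return Rejection(read.read_id, "no_ltr")
    rest = seq[len(ltr_tail):]

    cut = len(rest)
    exact = rest.find(linker)
    if exact >= 0:
        cut = exact
    else:
        min_match = min(min_linker_match, len(linker))
        rest_arr = np.frombuffer(rest.encode(), dtype=np.uint8)
        link_arr = np.frombuffer(linker.encode(), dtype=np.uint8)
        for i in range(len(rest) - min_match + 1):
            m = min(len(linker), len(rest) - i)
            if m < len(linker) and i + m != len(rest):
                continue  # truncation only at the read end
            if int(np.count_nonzero(rest_arr[i : i + m] != link_arr[:m])) <= max_mismatch:
                cut = i
                break
    fragment = rest[:cut]
    if not fragment:
        return Rejection(read.read_id, "empty_after_trim")
    return Fragment(read.read_id, fragment)


def filter_small(fragments: list[Fragment], min_len: int = 20) -> tuple[list[Fragment], Counter]:
    """Drop fragments shorter than ``min_len``; tally removals."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    tally: Counter = Counter()
    kept = []
    for f in fragments:
        if len(f.sequence) < min_len:
            tally["too_short"] += 1
        else:
            kept.append(f)
    return kept, tally


def dedupe_fragments(fragments: list[Fragment]) -> tuple[list[Fragment], int]:
    """Remove exact duplicate fragment sequences (pre-mapping redundancy)."""
    seen: set[str] = set()
    kept, dropped = [], 0
    for f in fragments:
        if f.sequence in seen:
            dropped += 1
        else:
            seen.add(f.sequence)
            kept.append(f)
    return kept, dropped


class GenomeIndex:
    """Sorted k-mer index over the forward strand of every chromosome."""

    def __init__(self, genome: GenomeModel, k: int = 16):
        if genome.sequences is None:
            raise ValueError("genome carries no sequence")
        if not 4 <= k <= 31:
            raise ValueError("k must be in [4, 31]")
        self.genome = genome
        self.k = k
        codes_all, chrom_idx_all, pos_all = [], [], []
        self._encoded: dict[str, np.ndarray] = {}
        for ci, name in enumerate(genome.names):
            enc = _encode(genome.sequence(name))
            self._encoded[name] = enc
            n = len(enc)
            if n < k:
                continue
            valid = enc < 4
            kmers = np.zeros(n - k + 1, dtype=np.uint64)
            ok = np.ones(n - k + 1, dtype=bool)
            for j in range(k):
                kmers = kmers * np.uint64(4) + enc[j : n - k + 1 + j].astype(np.uint64)
                ok &= valid[j : n - k + 1 + j]
            pos = np.nonzero(ok)[0]
            codes_all.append(kmers[pos])
            chrom_idx_all.append(np.full(len(pos), ci, dtype=np.int32))
            pos_all.append(pos.astype(np.int64))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.uint64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._chrom_idx = (np.concatenate(chrom_idx_all) if chrom_idx_all else np.empty(0, dtype=np.int32))[order]
        self._pos = (np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64))[order]

    def seed_hits(self, seed_codes: np.ndarray) -> list[tuple[int, int]]:
        """All (chrom index, position) pairs whose k-mer equals any seed code."""
        hits = []
        for code in seed_codes:
            lo = int(np.searchsorted(self._codes, code, side="left"))
            hi = int(np.searchsorted(self._codes, code, side="right"))
            for j in range(lo, hi):
                hits.append((int(self._chrom_idx[j]), int(self._pos[j])))
        return hits

    def encoded(self, chrom: str) -> np.ndarray:
        return self._encoded[chrom]


def _kmer_code(enc: np.ndarray, k: int) -> int | None:
    if len(enc) < k or (enc[:k] >= 4).any():
        return None
    code = 0
    for v in enc[:k]:
        code = code * 4 + int(v)
    return code


def map_fragment(
    index: GenomeIndex,
    fragment: Fragment,
    min_identity: float = 0.95,
    seed_offsets: tuple[int, ...] = (0, 1, 2),
) -> MappedFragment | Rejection:
    """Place a fragment by seeded ungapped alignment on both strands.

    Seeds of ``k`` exact bases are taken at ``seed_offsets`` multiples of k
    into the fragment (so a single sequencing error cannot hide every seed);
    each seed hit is extended over the full fragment length counting
    matches. Accepts only a unique best hit with identity ≥ ``min_identity``;
    ties reject as ``multimapped``, no qualifying hit as ``unmapped``.
    """
    k = index.k
    genome = index.genome
    L = len(fragment.sequence)
    if L < k:
        return Rejection(fragment.read_id, "unmapped")

    candidates: dict[tuple[int, int, str], float] = {}
    for strand, seq in (("+", fragment.sequence), ("-", _revcomp(fragment.sequence))):
        enc = _encode(seq)
        for mult in seed_offsets:
            off = mult * k
            if off + k > L:
                break
            code = _kmer_code(enc[off:], k)
            if code is None:
                continue
            for ci, p in index.seed_hits(np.asarray([code], dtype=np.uint64)):
                start = p - off
                key = (ci, start, strand)
                if key in candidates:
                    continue
                chrom = genome.names[ci]
                ref = index.encoded(chrom)
                if start < 0 or start + L > len(ref):
                    continue
                matches = int(np.count_nonzero(ref[start : start + L] == enc))
                candidates[key] = matches / L

    best = [(key, ident) for key, ident in candidates.items() if ident >= min_identity]
    if not best:
        return Rejection(fragment.read_id, "unmapped")
    top = max(ident for _, ident in best)
    winners = [key for key, ident in best if ident >= top - 1e-12]
    if len(winners) > 1:
        return Rejection(fragment.read_id, "multimapped")
    ci, start, strand = winners[0]
    position = start if strand == "+" else start + L - 1
    return MappedFragment(fragment.read_id, genome.names[ci], position, strand, top, 1)


def collapse_redundant(
    mapped: list[MappedFragment],
    tolerance: int = 3,
    name: str = "sites",
) -> SiteDataset:
    """Merge mapped positions on the same chrom+strand within ``tolerance``.

    Positions are chained by single linkage (consecutive gap ≤ tolerance);
    each chain becomes one site at its modal raw position (tie → smallest),
    with ``read_count`` = number of fragments merged.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    groups: dict[tuple[str, str], list[int]] = {}
    for m in mapped:
        groups.setdefault((m.chrom, m.strand), []).append(m.position)
    chroms, positions, strands, counts = [], [], [], []
    for (chrom, strand), pos_list in groups.items():
        pos = np.sort(np.asarray(pos_list, dtype=np.int64))
        breaks = np.nonzero(np.diff(pos) > tolerance)[0] + 1
        for chunk in np.split(pos, breaks):
            vals, cnts = np.unique(chunk, return_counts=True)
            modal = int(vals[np.argmax(cnts)])  # np.argmax takes the first (smallest) on ties
            chroms.append(chrom)
            positions.append(modal)
            strands.append(strand)
            counts.append(len(chunk))
    return SiteDataset.from_arrays(name, chroms, positions, strands, counts)


@dataclass
class PipelineReport:
    total_reads: int = 0
    rejections: Counter = field(default_factory=Counter)
    duplicate_fragments: int = 0
    mapped: int = 0
    unique_sites: int = 0

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "rejections": dict(self.rejections),
            "duplicate_fragments": self.duplicate_fragments,
            "mapped": self.mapped,
            "unique_sites": self.unique_sites,
        }

    def accounted(self) -> int:
        """Every read lands in exactly one bucket."""
        return self.mapped + self.duplicate_fragments + sum(self.rejections.values())


def process_reads(
    genome: GenomeModel,
    reads: list[ReadRecord],
    ltr_tail: str,
    linker: str,
    min_len: int = 20,
    min_identity: float = 0.95,
    tolerance: int = 3,
    max_mismatch: int = 2,
    k: int = 16,
    dataset_name: str = "sites",
    index: GenomeIndex | None = None,
) -> tuple[SiteDataset, PipelineReport]:
    """Run the full pipeline: trim → length filter → dedupe → map → collapse."""
    report = PipelineReport(total_reads=len(reads))
    fragments = []
    for read in reads:
        result = trim_junction(read, ltr_tail, linker, max_mismatch=max_mismatch)
        if isinstance(result, Rejection):
            report.rejections[result.reason] += 1
        else:
            fragments.append(result)
    fragments, small_tally = filter_small(fragments, min_len=min_len)
    report.rejections.update(small_tally)
    fragments, n_dup = dedupe_fragments(fragments)
    report.duplicate_fragments = n_dup

    if index is None:
        index = GenomeIndex(genome, k=k)
    mapped = []
    for frag in fragments:
        result = map_fragment(index, frag, min_identity=min_identity)
        if isinstance(result, Rejection):
            report.rejections[result.reason] += 1
        else:
            mapped.append(result)
    report.mapped = len(mapped)
    dataset = collapse_redundant(mapped, tolerance=tolerance, name=dataset_name)
    report.unique_sites = dataset.n
    return dataset, report
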
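"""Coordinate system, interval engine and annotation containers.

Everything downstream works on 0-based half-open intervals (BED convention)
over a fixed chromosome-size table, and on a regular grid of 500-bp bins
anchored at coordinate 0.  A bin is identified by its ``(chrom, start)`` pair;
set algebra on DMR calls is plain Python set algebra on those pairs, while
nucleotide-level overlap questions go through :class:`IntervalSet`, a small
per-chromosome sorted-array engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

logger = logging.getLogger(__name__)

BIN_SIZE = 500

BinKey = Tuple[str, int]  # (chrom, start); width is always BIN_SIZE


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional payload."""

    chrom: str
    start: int
    end: int
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}; "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Bin:
    """A grid-aligned 500-bp window."""

    chrom: str
    start: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start % BIN_SIZE != 0:
            raise ValueError(f"bin start {self.start} is not a multiple of {BIN_SIZE}")

    @property
    def end(self) -> int:
        return self.start + BIN_SIZE

    @property
    def key(self) -> BinKey:
        return (self.chrom, self.start)

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """One transcript record: TSS is strand-aware (+ -> body.start, - -> body.end)."""

    gene_id: str
    chrom: str
    strand: str
    body: GenomicInterval
    aliases: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end


@dataclass(frozen=True)
class TECopy:
    interval: GenomicInterval
    subfamily: str
    family: str
    te_class: str


@dataclass
class ProbeSet:
    """Per-chromosome sorted probe coordinates with ids, for one array platform."""

    platform: str
    positions: Dict[str, np.ndarray]      # chrom -> sorted int positions
    probe_ids: Dict[str, np.ndarray]      # chrom -> ids aligned with positions

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for chrom, ids in self.probe_ids.items():
            order = np.argsort(self.positions[chrom], kind="stable")
            self.positions[chrom] = np.asarray(self.positions[chrom])[order]
            self.probe_ids[chrom] = np.asarray(ids)[order]
            for pid in self.probe_ids[chrom]:
                if pid in seen:
                    raise ValueError(f"duplicate probe id {pid!r} on platform {self.platform}")
                seen.add(pid)

    @property
    def n_probes(self) -> int:
        return sum(len(v) for v in self.positions.values())


# ---------------------------------------------------------------------------
# interval-set engine
# ---------------------------------------------------------------------------

class IntervalSet:
    """An immutable set of genomic intervals stored as merged sorted arrays.

    Construction merges overlapping/abutting intervals per chromosome, so
    every nucleotide is represented at most once; all bp accounting
    (``total_bp``, ``overlap_bp``) is therefore union semantics.
    """

    __slots__ = ("_data",)

    def __init__(self, data: Mapping[str, np.ndarray]):
        self._data = {c: a for c, a in data.items() if len(a)}

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            raw.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return cls({c: _merge(np.array(v, dtype=np.int64)) for c, v in raw.items()})

    @classmethod
    def from_arrays(cls, data: Mapping[str, np.ndarray]) -> "IntervalSet":
        return cls({c: _merge(np.asarray(a, dtype=np.int64).reshape(-1, 2))
                    for c, a in data.items()})

    @classmethod
    def from_bins(cls, bins: Iterable[BinKey]) -> "IntervalSet":
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start in bins:
            raw.setdefault(chrom, []).append((start, start + BIN_SIZE))
        return cls({c: _merge(np.array(v, dtype=np.int64)) for c, v in raw.items()})

    @property
    def chroms(self) -> List[str]:
        return sorted(self._data)

    def arrays(self) -> Dict[str, np.ndarray]:
        return dict(self._data)

    def intervals(self) -> List[GenomicInterval]:
        out = []
        for chrom in self.chroms:
            for s, e in self._data[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out

    @property
    def total_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __bool__(self) -> bool:
        return bool(self._data)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom in set(self._data) & set(other._data):
            pieces = _intersect_sorted(self._data[chrom], other._data[chrom])
            if len(pieces):
                out[chrom] = pieces
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom in set(self._data) | set(other._data):
            parts = [a for a in (self._data.get(chrom), other._data.get(chrom)) if a is not None]
            out[chrom] = _merge(np.vstack(parts))
        return IntervalSet(out)

    def overlap_bp(self, other: "IntervalSet") -> int:
        return self.intersect(other).total_bp

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps this set by >= 1 bp."""
        arr = self._data.get(chrom)
        if arr is None:
            return False
        i = np.searchsorted(arr[:, 1], start, side="right")
        return i < len(arr) and arr[i, 0] < end

    def overlap_bp_interval(self, chrom: str, start: int, end: int) -> int:
        arr = self._data.get(chrom)
        if arr is None:
            return 0
        lo = np.searchsorted(arr[:, 1], start, side="right")
        hi = np.searchsorted(arr[:, 0], end, side="left")
        if lo >= hi:
            return 0
        seg = arr[lo:hi]
        return int(np.sum(np.minimum(seg[:, 1], end) - np.maximum(seg[:, 0], start)))


def _merge(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping or abutting [start, end) rows into disjoint sorted rows."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    starts, ends = arr[:, 0], arr[:, 1]
    running_max = np.maximum.accumulate(ends)
    new_block = np.ones(len(arr), dtype=bool)
    new_block[1:] = starts[1:] > running_max[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    out = np.empty((n_blocks, 2), dtype=np.int64)
    out[:, 0] = starts[new_block]
    out[:, 1] = np.maximum.reduceat(ends, np.flatnonzero(new_block))
    return out


def _intersect_sorted(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: List[Tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def overlap_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Total nucleotides in the intersection of two interval sets.

    Each set is unioned internally first, so multiply-covered nucleotides
    count once.
    """
    return a.overlap_bp(b)


# ---------------------------------------------------------------------------
# segmentation / annotation containers
# ---------------------------------------------------------------------------

ROADMAP_18_STATES = (
    "1_TssA", "2_TssFlnk", "3_TssFlnkU", "4_TssFlnkD", "5_Tx", "6_TxWk",
    "7_EnhG1", "8_EnhG2", "9_EnhA1", "10_EnhA2", "11_EnhWk", "12_ZNF/Rpts",
    "13_Het", "14_TssBiv", "15_EnhBiv", "16_ReprPC", "17_ReprPCWk", "18_Quies",
)
ROADMAP_15_STATES = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk", "6_EnhG", "7_Enh",
    "8_ZNF/Rpts", "9_Het", "10_TssBiv", "11_BivFlnk", "12_EnhBiv", "13_ReprPC",
    "14_ReprPCWk", "15_Quies",
)
STATE_VOCABULARIES = {"18-state": ROADMAP_18_STATES, "15-state": ROADMAP_15_STATES}

# state groups referenced by the regulatory and TE cascades (18-state model)
TSS_STATES_18 = ("1_TssA", "2_TssFlnk", "3_TssFlnkU", "4_TssFlnkD")
ACTIVE_ENHANCER_STATES_18 = ("9_EnhA1", "10_EnhA2")


@dataclass
class SegmentationStack:
    """Chromatin-state interval labelings for a set of reference epigenomes."""

    model: str
    epigenomes: Dict[str, List[Tuple[GenomicInterval, str]]]
    state_vocabulary: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.state_vocabulary:
            self.state_vocabulary = STATE_VOCABULARIES[self.model]
        vocab = set(self.state_vocabulary)
        for eid, segs in self.epigenomes.items():
            segs.sort(key=lambda t: (t[0].chrom, t[0].start))
            prev: Dict[str, int] = {}
            for iv, state in segs:
                if state not in vocab:
                    raise ValueError(
                        f"epigenome {eid}: state {state!r} not in {self.model} vocabulary"
                    )
                if iv.start < prev.get(iv.chrom, 0):
                    raise ValueError(f"epigenome {eid}: overlapping segments on {iv.chrom}")
                prev[iv.chrom] = iv.end

    @property
    def epigenome_ids(self) -> List[str]:
        return sorted(self.epigenomes)

    def state_intervals(self, epigenome_id: str, states: Sequence[str]) -> IntervalSet:
        wanted = set(states)
        return IntervalSet.from_intervals(
            iv for iv, s in self.epigenomes[epigenome_id] if s in wanted
        )

    def state_union(self, states: Sequence[str]) -> IntervalSet:
        """Union over all epigenomes of the given states (>=1-epigenome rule)."""
        wanted = set(states)
        return IntervalSet.from_intervals(
            iv
            for segs in self.epigenomes.values()
            for iv, s in segs
            if s in wanted
        )


@dataclass
class GenomeAnnotation:
    """All static annotation inputs of one analysis run."""

    chrom_sizes: Dict[str, int]
    genes: List[GeneModel] = field(default_factory=list)
    cpg_islands: Optional[IntervalSet] = None
    cpg_positions: Dict[str, np.ndarray] = field(default_factory=dict)
    blacklist_bins: Set[BinKey] = field(default_factory=set)
    enhancer_catalogs: Dict[str, IntervalSet] = field(default_factory=dict)
    te_table: List[TECopy] = field(default_factory=list)
    probe_manifests: Dict[str, ProbeSet] = field(default_factory=dict)

    def validate(self) -> None:
        def _check(iv: GenomicInterval) -> None:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > size:
                raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds length {size}")

        for g in self.genes:
            _check(g.body)
        for t in self.te_table:
            _check(t.interval)
        if self.cpg_islands is not None:
            for iv in self.cpg_islands.intervals():
                _check(iv)
        for cat in self.enhancer_catalogs.values():
            for iv in cat.intervals():
                _check(iv)
        for chrom, pos in self.cpg_positions.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r} in CpG positions")
            if len(pos) and (pos[-1] >= self.chrom_sizes[chrom] or pos[0] < 0):
                raise ValueError(f"CpG position out of bounds on {chrom}")


# ---------------------------------------------------------------------------
# bin grid and background universe
# ---------------------------------------------------------------------------

@dataclass
class SignalPresence:
    """Per sample, the set of bins carrying >= 1 MeDIP and/or MRE read."""

    samples: Dict[str, Set[BinKey]]

    def __post_init__(self) -> None:
        for sid, bins in self.samples.items():
            for chrom, start in bins:
                if start % BIN_SIZE != 0:
                    raise ValueError(f"sample {sid}: bin start {start} off grid")

    def any_signal(self) -> Set[BinKey]:
        out: Set[BinKey] = set()
        for bins in self.samples.values():
            out |= bins
        return out


@dataclass
class BackgroundSet:
    """The eligible-bin universe: the N of every enrichment and overlap test."""

    bins: Tuple[BinKey, ...]
    excluded_chroms: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.bins = tuple(sorted(set(self.bins)))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def total_bp(self) -> int:
        return self.n_bins * BIN_SIZE

    @property
    def bin_set(self) -> Set[BinKey]:
        return set(self.bins)

    def interval_set(self) -> IntervalSet:
        return IntervalSet.from_bins(self.bins)


def build_bin_grid(chrom_sizes: Mapping[str, int]) -> List[Bin]:
    """Full 500-bp bin grid: [0,500), [500,1000), ... per chromosome.

    A trailing partial window is dropped so every bin has identical width.
    """
    if not chrom_sizes:
        raise ValueError("empty chromosome-size table")
    out: List[Bin] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        out.extend(Bin(chrom, s) for s in range(0, (size // BIN_SIZE) * BIN_SIZE, BIN_SIZE))
    return out


def build_background(
    grid: Sequence[Bin],
    cpg_positions: Mapping[str, np.ndarray],
    blacklist_bins: Set[BinKey],
    presence: SignalPresence,
    excluded_chroms: Iterable[str] = (),
    n_end_bins: int = 1,
) -> BackgroundSet:
    """Filter the grid down to the eligible background universe.

    A bin is kept iff it is not among the first/last ``n_end_bins`` full bins
    of its chromosome, is not blacklisted, contains >= 1 CpG, carries MeDIP
    and/or MRE signal in >= 1 sample, and is not on an excluded chromosome.
    """
    if not grid:
        raise ValueError("empty bin grid")
    excluded = set(excluded_chroms)
    signal = presence.any_signal()

    by_chrom: Dict[str, List[Bin]] = {}
    for b in grid:
        by_chrom.setdefault(b.chrom, []).append(b)

    kept: List[BinKey] = []
    for chrom, bins in by_chrom.items():
        if chrom in excluded:
            continue
        bins = sorted(bins, key=lambda b: b.start)
        interior = bins[n_end_bins: len(bins) - n_end_bins] if n_end_bins else bins
        pos = np.asarray(cpg_positions.get(chrom, ()), dtype=np.int64)
        for b in interior:
            if b.key in blacklist_bins or b.key not in signal:
                continue
            lo = np.searchsorted(pos, b.start, side="left")
            hi = np.searchsorted(pos, b.end, side="left")
            if hi > lo:
                kept.append(b.key)
    logger.info("background: kept %d of %d grid bins", len(kept), len(grid))
    return BackgroundSet(bins=tuple(kept), excluded_chroms=frozenset(excluded))
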
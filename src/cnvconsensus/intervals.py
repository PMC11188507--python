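"""Genomic interval model and exact length-based set algebra.

All coordinates are 0-based, half-open (BED convention). An
:class:`IntervalSet` is always kept normalized — sorted by
``(chrom, start)`` with overlapping or abutting intervals merged — so
every length computed from it is an exact count of distinct bases.
This module is the unit of account for the whole package: consensus
scores, validation rates and precision/recall are all per-base length
ratios computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "ExclusionMask",
    "normalize",
    "intersect_length",
    "jaccard",
    "partition_multi",
    "subtract",
    "restrict_to_annotation",
    "read_bed",
    "write_bed",
    "harmonize_chrom",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge a start-sorted (n, 2) array; abutting intervals coalesce."""
    if len(arr) <= 1:
        return arr
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s <= cur_e:  # overlap or abut
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


class IntervalSet:
    """A normalized collection of genomic intervals.

    Internally a mapping ``chrom -> (n, 2) int64 array`` of disjoint,
    sorted, non-abutting spans. Construct via :func:`normalize` or
    :meth:`from_intervals`; the raw constructor trusts its input.
    """

    __slots__ = ("_chroms",)

    def __init__(self, chroms: Dict[str, np.ndarray] | None = None):
        self._chroms: Dict[str, np.ndarray] = chroms or {}

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        chroms = {}
        for chrom in sorted(by_chrom):
            arr = np.asarray(sorted(by_chrom[chrom]), dtype=np.int64)
            chroms[chrom] = _merge_sorted(arr)
        return cls(chroms)

    # -- basic protocol -------------------------------------------------
    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._chroms)

    def arrays(self, chrom: str) -> np.ndarray:
        return self._chroms.get(chrom, np.empty((0, 2), dtype=np.int64))

    def intervals(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c in self.chromosomes
            for s, e in self._chroms[c]
        ]

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals())

    def __len__(self) -> int:
        return sum(len(a) for a in self._chroms.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    @property
    def total_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._chroms.values() if len(a))
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        mine = {c: a for c, a in self._chroms.items() if len(a)}
        theirs = {c: a for c, a in other._chroms.items() if len(a)}
        if set(mine) != set(theirs):
            return False
        return all(np.array_equal(mine[c], theirs[c]) for c in mine)

    def __hash__(self) -> int:  # content hash for caching in tests
        return hash(tuple((c, a.tobytes()) for c, a in sorted(self._chroms.items())))

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({len(self)} intervals, {self.total_length} bp)"

    # -- set algebra ----------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        chroms = {}
        for c in sorted(set(self._chroms) | set(other._chroms)):
            both = np.concatenate([self.arrays(c), other.arrays(c)])
            if len(both) == 0:
                continue
            both = both[np.lexsort((both[:, 1], both[:, 0]))]
            merged = _merge_sorted(both)
            if len(merged):
                chroms[c] = merged
        return IntervalSet(chroms)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        chroms = {}
        for c in sorted(set(self._chroms) & set(other._chroms)):
            a, b = self.arrays(c), other.arrays(c)
            out = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((s, e))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if out:
                chroms[c] = np.asarray(out, dtype=np.int64)
        return IntervalSet(chroms)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        chroms = {}
        for c in self.chromosomes:
            a, b = self.arrays(c), other.arrays(c)
            if len(b) == 0:
                if len(a):
                    chroms[c] = a.copy()
                continue
            out = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        out.append((cur, b[k, 0]))
                    cur = max(cur, b[k, 1])
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    out.append((cur, e))
            if out:
                chroms[c] = np.asarray(out, dtype=np.int64)
        return IntervalSet(chroms)


@dataclass
class ExclusionMask:
    """Regions removed from all accounting (e.g. lost arms, assembly gaps).

    For a hyper-diploid tumor line like HCC1395 this typically holds the
    fully lost chr6p / chr16q arms, chrX, and gap (centromere/telomere)
    regions where short-read CNV calls are unreliable.
    """

    regions: IntervalSet = field(default_factory=IntervalSet)
    label: str = ""

    @classmethod
    def empty(cls) -> "ExclusionMask":
        return cls(IntervalSet(), "empty")


# ---------------------------------------------------------------------------
# module-level operations


def normalize(intervals: Iterable[GenomicInterval]) -> IntervalSet:
    """Sort, merge overlapping/abutting intervals; exact same base coverage."""
    return IntervalSet.from_intervals(intervals)


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    """Number of bases covered by both sets."""
    return a.intersect(b).total_length


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Intersection length over union length.

    Returns NaN when both sets are empty (0/0 is undefined, not zero).
    """
    inter = intersect_length(a, b)
    uni = a.union(b).total_length
    if uni == 0:
        return math.nan
    return inter / uni


def subtract(a: IntervalSet, mask: ExclusionMask | IntervalSet) -> IntervalSet:
    """Remove masked bases from *a*."""
    regions = mask.regions if isinstance(mask, ExclusionMask) else mask
    return a.subtract(regions)


def restrict_to_annotation(a: IntervalSet, track: IntervalSet) -> IntervalSet:
    """Keep only the part of *a* inside an annotation track (genes, exons)."""
    return a.intersect(track)


def partition_multi(
    sets: Sequence[IntervalSet],
) -> List[Tuple[GenomicInterval, Tuple[bool, ...]]]:
    """Partition the union of many sets into disjoint support-annotated pieces.

    Every base covered by at least one input appears in exactly one output
    interval, whose boolean support vector marks which inputs cover it.
    Adjacent pieces with identical support are merged, so the output is the
    minimal disjoint refinement. Support vectors are never all-false.
    """
    if len(sets) == 0:
        raise ValueError("partition_multi requires at least one input set")
    all_chroms = sorted({c for s in sets for c in s.chromosomes})
    out: List[Tuple[GenomicInterval, Tuple[bool, ...]]] = []
    for chrom in all_chroms:
        arrs = [s.arrays(chrom) for s in sets]
        bounds = np.unique(np.concatenate([a.ravel() for a in arrs if len(a)]))
        if len(bounds) < 2:
            continue
        starts = bounds[:-1]
        # membership per elementary interval [bounds[i], bounds[i+1])
        support = np.zeros((len(starts), len(sets)), dtype=bool)
        for k, a in enumerate(arrs):
            if len(a) == 0:
                continue
            idx = np.searchsorted(a[:, 0], starts, side="right") - 1
            ok = idx >= 0
            ok[ok] &= a[idx[ok], 1] > starts[ok]
            support[:, k] = ok
        covered = support.any(axis=1)
        # run-length merge of contiguous equal-support covered pieces
        run_start = None
        run_vec = None
        for i in range(len(starts)):
            if not covered[i]:
                if run_start is not None:
                    out.append(
                        (GenomicInterval(chrom, int(run_start), int(bounds[i])),
                         tuple(bool(x) for x in run_vec))
                    )
                    run_start = None
                continue
            vec = support[i]
            if run_start is None:
                run_start, run_vec = starts[i], vec
            elif not np.array_equal(vec, run_vec):
                out.append(
                    (GenomicInterval(chrom, int(run_start), int(starts[i])),
                     tuple(bool(x) for x in run_vec))
                )
                run_start, run_vec = starts[i], vec
        if run_start is not None:
            out.append(
                (GenomicInterval(chrom, int(run_start), int(bounds[-1])),
                 tuple(bool(x) for x in run_vec))
            )
    return out


# ---------------------------------------------------------------------------
# BED I/O and chromosome-name harmonization


def harmonize_chrom(name: str, style: str = "keep") -> str:
    """Normalize chromosome naming: ``style`` is 'keep', 'chr' or 'bare'."""
    if style == "keep":
        return name
    bare = name[3:] if name.lower().startswith("chr") else name
    if style == "bare":
        return bare
    if style == "chr":
        return f"chr{bare}"
    raise ValueError(f"unknown chromosome style {style!r}")


def read_bed(path, chrom_style: str = "keep") -> IntervalSet:
    """Read a BED3+ file (tab-separated, 0-based half-open) into a set."""
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(
                    harmonize_chrom(parts[0], chrom_style), int(parts[1]), int(parts[2])
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            ivs.append(iv)
    return normalize(ivs)


def write_bed(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
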
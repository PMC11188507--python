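"""Orthogonal-technology validation and benchmark assembly.

Consensus intervals from sequencing are confirmed against independent
technologies (SNP arrays, optical genome mapping). Validation is per-base:
a benchmark region can be partially validated, and all rates are length
ratios. The benchmark keeps strong-evidence intervals unconditionally and
medium/weak intervals only where at least two technologies confirm the
same CNV type; gain/loss conflicts are resolved and overlapping
breakpoints trimmed using orthogonal support.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .callsets import CallSet, CNVCall, CNVType, Cohort
from .intervals import (
    ExclusionMask,
    GenomicInterval,
    IntervalSet,
    intersect_length,
    normalize,
)
from .scoring import Confidence, ScoredInterval

__all__ = [
    "OrthogonalCallSet",
    "BenchmarkInterval",
    "BenchmarkSet",
    "validated_length",
    "validation_table",
    "cluster_nonredundant",
    "resolve_conflicts",
    "trim_breakpoints",
    "assemble_benchmark",
]

logger = logging.getLogger(__name__)

MB = 1e6


@dataclass
class OrthogonalCallSet:
    """CNV calls from one non-NGS technology (array, optical mapping)."""

    technology: str
    calls: List[CNVCall] = field(default_factory=list)

    def typed_regions(self, cnv_type: CNVType) -> IntervalSet:
        return normalize(c.interval for c in self.calls if c.cnv_type == cnv_type)


@dataclass(frozen=True)
class BenchmarkInterval:
    interval: GenomicInterval
    cnv_type: CNVType
    confidence: Confidence
    median_cn: float
    technologies: Tuple[str, ...] = ()


@dataclass
class BenchmarkSet:
    """The final high-confidence gain/loss/LOH regions."""

    intervals: List[BenchmarkInterval] = field(default_factory=list)

    def typed_regions(self, cnv_type: CNVType) -> IntervalSet:
        return normalize(
            b.interval for b in self.intervals if b.cnv_type == cnv_type
        )

    def of_type(self, cnv_type: CNVType) -> List[BenchmarkInterval]:
        return [b for b in self.intervals if b.cnv_type == cnv_type]

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": b.interval.chrom,
                "start": b.interval.start,
                "end": b.interval.end,
                "type": str(b.cnv_type),
                "confidence": str(b.confidence),
                "median_cn": b.median_cn,
                "technologies": ",".join(b.technologies),
            }
            for b in sorted(self.intervals, key=lambda b: (b.interval, b.cnv_type))
        ]
        return pd.DataFrame(rows)


def validated_length(
    intervals: IntervalSet, tech: OrthogonalCallSet, cnv_type: CNVType
) -> int:
    """Bases of *intervals* covered by same-type calls of one technology."""
    return intersect_length(intervals, tech.typed_regions(cnv_type))


def _ge2_region(tech_regions: Sequence[IntervalSet]) -> IntervalSet:
    """Union of pairwise intersections: bases covered by >= 2 technologies."""
    acc = IntervalSet()
    for i in range(len(tech_regions)):
        for j in range(i + 1, len(tech_regions)):
            acc = acc.union(tech_regions[i].intersect(tech_regions[j]))
    return acc


def _ge1_region(tech_regions: Sequence[IntervalSet]) -> IntervalSet:
    acc = IntervalSet()
    for r in tech_regions:
        acc = acc.union(r)
    return acc


def validation_table(
    scored: Sequence[ScoredInterval],
    techs: Sequence[OrthogonalCallSet],
) -> pd.DataFrame:
    """Per (type, confidence) validation accounting in Mb.

    Columns: collapsed NGS length, per-technology validated length, length
    (and %) validated by >= 1 and by >= 2 technologies. Percentages are
    validated length / collapsed length x 100.
    """
    if not techs:
        raise ValueError("at least one orthogonal technology required")
    rows = []
    types = sorted({s.cnv_type for s in scored}, key=lambda t: t.value)
    order = [Confidence.STRONG, Confidence.MEDIUM, Confidence.WEAK, Confidence.NEUTRAL]
    for cnv_type in types:
        tech_regions = [t.typed_regions(cnv_type) for t in techs]
        union1 = _ge1_region(tech_regions)
        union2 = _ge2_region(tech_regions)
        for conf in order:
            region = normalize(
                s.interval
                for s in scored
                if s.cnv_type == cnv_type and s.confidence == conf
            )
            if region.is_empty:
                continue
            collapsed = region.total_length
            ge1 = intersect_length(region, union1)
            ge2 = intersect_length(region, union2)
            row = {
                "type": str(cnv_type),
                "confidence": str(conf),
                "collapsed_mb": collapsed / MB,
            }
            for t, tr in zip(techs, tech_regions):
                row[f"{t.technology}_mb"] = intersect_length(region, tr) / MB
            row["ge1_mb"] = ge1 / MB
            row["ge1_pct"] = 100.0 * ge1 / collapsed
            row["ge2_mb"] = ge2 / MB
            row["ge2_pct"] = 100.0 * ge2 / collapsed
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Non-redundant clustering of replicate calls


def cluster_nonredundant(
    calls: Sequence[CNVCall],
    proximity: int = 10_000,
    similarity: float = 0.5,
) -> List[CNVCall]:
    """Merge same-type calls that are near-duplicates across replicates.

    Two calls of the same type link when both breakpoints lie within
    ``proximity`` bp and their lengths agree to better than ``similarity``
    (min/max length ratio strictly greater). Single-linkage clusters are
    replaced by one representative with median start, end and copy number.
    Idempotent on its own output.
    """
    calls = list(calls)
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def link(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        a = calls[i]
        for j in range(i + 1, n):
            b = calls[j]
            if a.cnv_type != b.cnv_type or a.interval.chrom != b.interval.chrom:
                continue
            if abs(a.interval.start - b.interval.start) > proximity:
                continue
            if abs(a.interval.end - b.interval.end) > proximity:
                continue
            la, lb = a.interval.length, b.interval.length
            if min(la, lb) / max(la, lb) > similarity:
                link(i, j)

    clusters: Dict[int, List[CNVCall]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(calls[i])

    out: List[CNVCall] = []
    for members in clusters.values():
        if len(members) == 1:
            out.append(members[0])
            continue
        start = int(statistics.median(m.interval.start for m in members))
        end = int(statistics.median(m.interval.end for m in members))
        cn = statistics.median(m.total_cn for m in members)
        rep = members[0]
        out.append(
            CNVCall(
                GenomicInterval(rep.interval.chrom, start, end),
                cn,
                loh=rep.loh,
                cnv_type=rep.cnv_type,
            )
        )
    out.sort(key=lambda c: (c.interval, c.cnv_type))
    return out


# ---------------------------------------------------------------------------
# Conflict resolution and breakpoint trimming


def _clip_scored(
    scored: Sequence[ScoredInterval], keep: IntervalSet
) -> List[ScoredInterval]:
    """Intersect each scored interval with *keep*, splitting as needed and
    preserving scores/confidence."""
    out = []
    for s in scored:
        piece = normalize([s.interval]).intersect(keep)
        for iv in piece:
            out.append(
                ScoredInterval(
                    interval=iv,
                    cnv_type=s.cnv_type,
                    per_caller_cumulative=s.per_caller_cumulative,
                    per_caller_converted=s.per_caller_converted,
                    total_score=s.total_score,
                    confidence=s.confidence,
                )
            )
    return out


def resolve_conflicts(
    scored_gain: Sequence[ScoredInterval],
    scored_loss: Sequence[ScoredInterval],
    techs: Sequence[OrthogonalCallSet],
) -> Tuple[List[ScoredInterval], List[ScoredInterval], pd.DataFrame]:
    """Remove gain (loss) bases contradicted by orthogonal evidence.

    A base called gain is removed where at least one technology calls it a
    loss and no technology calls it a gain; symmetric for loss. Regions
    with any same-type orthogonal support are retained even under
    opposite-type evidence. Removals are per-base and logged.
    """
    tech_gain = _ge1_region([t.typed_regions(CNVType.GAIN) for t in techs])
    tech_loss = _ge1_region([t.typed_regions(CNVType.LOSS) for t in techs])

    gain_region = normalize(s.interval for s in scored_gain)
    loss_region = normalize(s.interval for s in scored_loss)

    gain_removed = gain_region.intersect(tech_loss).subtract(tech_gain)
    loss_removed = loss_region.intersect(tech_gain).subtract(tech_loss)

    kept_gain = _clip_scored(scored_gain, gain_region.subtract(gain_removed))
    kept_loss = _clip_scored(scored_loss, loss_region.subtract(loss_removed))

    log_rows = []
    for cnv_type, removed in ((CNVType.GAIN, gain_removed), (CNVType.LOSS, loss_removed)):
        for iv in removed:
            log_rows.append(
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "type": str(cnv_type),
                    "reason": "opposite-type orthogonal evidence, no same-type support",
                }
            )
    return kept_gain, kept_loss, pd.DataFrame(log_rows)


def trim_breakpoints(
    gain: Sequence[ScoredInterval],
    loss: Sequence[ScoredInterval],
    techs: Sequence[OrthogonalCallSet],
) -> Tuple[List[ScoredInterval], List[ScoredInterval], pd.DataFrame]:
    """Trim overlapping gain/loss ends using orthogonal support.

    Where a gain interval and a loss interval overlap, the end whose type
    has orthogonal support over the overlap keeps its coordinate and the
    other is trimmed back to abut it. If both or neither end is supported,
    the overlap is split at its midpoint (logged). Afterwards gain and loss
    regions are disjoint.
    """
    tech_gain = _ge1_region([t.typed_regions(CNVType.GAIN) for t in techs])
    tech_loss = _ge1_region([t.typed_regions(CNVType.LOSS) for t in techs])

    gain_region = normalize(s.interval for s in gain)
    loss_region = normalize(s.interval for s in loss)
    overlaps = gain_region.intersect(loss_region)

    gain_cut = IntervalSet()  # bases to remove from gain
    loss_cut = IntervalSet()
    log_rows = []
    for o in overlaps:
        oset = normalize([o])
        g_support = intersect_length(oset, tech_gain) > 0
        l_support = intersect_length(oset, tech_loss) > 0
        if g_support and not l_support:
            loss_cut = loss_cut.union(oset)
            resolution = "gain end supported; loss trimmed"
        elif l_support and not g_support:
            gain_cut = gain_cut.union(oset)
            resolution = "loss end supported; gain trimmed"
        else:
            mid = (o.start + o.end) // 2
            # split at midpoint: gain keeps the side nearer its own body
            g_left = intersect_length(
                normalize([GenomicInterval(o.chrom, max(0, o.start - 1), o.start)])
                if o.start > 0 else IntervalSet(),
                gain_region,
            ) > 0
            if mid == o.start or mid == o.end:
                # 1-bp overlap: give it to gain deterministically
                loss_cut = loss_cut.union(oset)
            elif g_left:
                gain_cut = gain_cut.union(normalize([GenomicInterval(o.chrom, mid, o.end)]))
                loss_cut = loss_cut.union(normalize([GenomicInterval(o.chrom, o.start, mid)]))
            else:
                gain_cut = gain_cut.union(normalize([GenomicInterval(o.chrom, o.start, mid)]))
                loss_cut = loss_cut.union(normalize([GenomicInterval(o.chrom, mid, o.end)]))
            resolution = (
                "both ends supported; split at midpoint"
                if g_support
                else "neither end supported; split at midpoint"
            )
        log_rows.append(
            {
                "chrom": o.chrom,
                "start": o.start,
                "end": o.end,
                "resolution": resolution,
            }
        )
    kept_gain = _clip_scored(gain, gain_region.subtract(gain_cut))
    kept_loss = _clip_scored(loss, loss_region.subtract(loss_cut))
    return kept_gain, kept_loss, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# Benchmark assembly


class _MedianCNIndex:
    """Per (type, chrom) start-sorted cohort calls for fast median lookup."""

    _DEFAULTS = {CNVType.GAIN: 3.0, CNVType.LOSS: 1.0, CNVType.LOH: 2.0}

    def __init__(self, cohort: Optional[Cohort]):
        self._idx: Dict[Tuple[CNVType, str], Tuple] = {}
        if cohort is None:
            return
        buckets: Dict[Tuple[CNVType, str], List[Tuple[int, int, float]]] = {}
        for cs in cohort.callsets:
            for c in cs.calls:
                buckets.setdefault((c.cnv_type, c.interval.chrom), []).append(
                    (c.interval.start, c.interval.end, c.total_cn)
                )
        import numpy as np

        for key, rows in buckets.items():
            rows.sort()
            arr = np.asarray(rows, dtype=float)
            self._idx[key] = (arr[:, 0], arr[:, 1], arr[:, 2])

    def median_cn(self, iv: GenomicInterval, cnv_type: CNVType) -> float:
        entry = self._idx.get((cnv_type, iv.chrom))
        if entry is None:
            return self._DEFAULTS[cnv_type]
        starts, ends, cns = entry
        hit = (starts < iv.end) & (ends > iv.start)
        if not hit.any():
            return self._DEFAULTS[cnv_type]
        return float(statistics.median(cns[hit]))


def _supporting_techs(
    iv: GenomicInterval,
    tech_regions: Sequence[Tuple[str, IntervalSet]],
) -> Tuple[str, ...]:
    iset = normalize([iv])
    return tuple(
        name for name, region in tech_regions if intersect_length(iset, region) > 0
    )


def assemble_benchmark(
    scored_by_type: Dict[CNVType, Sequence[ScoredInterval]],
    techs: Sequence[OrthogonalCallSet],
    cohort: Optional[Cohort] = None,
) -> BenchmarkSet:
    """Compose the final benchmark from scored intervals and orthogonal calls.

    Strong intervals are kept unconditionally; medium/weak intervals are
    kept only on bases validated by >= 2 technologies of the same type
    (splitting at support boundaries); neutral and unsupported intervals
    are dropped. Gain/loss conflicts are then resolved and overlapping
    breakpoints trimmed. Each benchmark interval carries the median copy
    number across all same-type cohort calls overlapping it.
    """
    filtered: Dict[CNVType, List[ScoredInterval]] = {}
    for cnv_type, scored in scored_by_type.items():
        ge2 = _ge2_region([t.typed_regions(cnv_type) for t in techs]) if techs else IntervalSet()
        keep: List[ScoredInterval] = []
        for s in scored:
            if s.confidence == Confidence.STRONG:
                keep.append(s)
            elif s.confidence in (Confidence.MEDIUM, Confidence.WEAK):
                keep.extend(_clip_scored([s], ge2))
            # NEUTRAL / NONE dropped
        filtered[cnv_type] = keep

    gain = filtered.get(CNVType.GAIN, [])
    loss = filtered.get(CNVType.LOSS, [])
    if techs and (gain or loss):
        gain, loss, _removed = resolve_conflicts(gain, loss, techs)
        gain, loss, _trimmed = trim_breakpoints(gain, loss, techs)
    filtered[CNVType.GAIN] = list(gain)
    filtered[CNVType.LOSS] = list(loss)

    cn_index = _MedianCNIndex(cohort)
    intervals: List[BenchmarkInterval] = []
    for cnv_type, kept in filtered.items():
        tech_regions = [(t.technology, t.typed_regions(cnv_type)) for t in techs]
        for s in kept:
            intervals.append(
                BenchmarkInterval(
                    interval=s.interval,
                    cnv_type=cnv_type,
                    confidence=s.confidence,
                    median_cn=cn_index.median_cn(s.interval, cnv_type),
                    technologies=_supporting_techs(s.interval, tech_regions),
                )
            )
    intervals.sort(key=lambda b: (b.interval, b.cnv_type))
    return BenchmarkSet(intervals=intervals)
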
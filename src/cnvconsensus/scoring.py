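"""Replicate-group consensus scoring of disjoint CNV intervals.

The cohort design has 21 WGS replicates per caller, spread over sequencing
centers. Replicates are partitioned into five groups per caller (three
3-replicate center groups, one 9-replicate group whose raw count is divided
by 3, and one group of three single-replicate centers), so each group
contributes 0-3 and each caller's cumulative group score lies in [0, 15].
The cumulative score converts to a per-caller score of 0-3
(0-3 -> 0, 4-6 -> 1, 7-9 -> 2, 10-15 -> 3); summing converted scores across
callers gives a total score from which a four-level confidence label is
assigned. Gain/loss intervals use the six-caller scale (11-18 strong,
8-10 medium, 4-7 weak, 1-3 neutral); LOH uses a five-caller scale
(> 8 strong, 6-8 medium, 4-5 weak, <= 3 neutral) because one caller never
reports LOH.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .callsets import CallSet, CNVType, Cohort
from .intervals import ExclusionMask, GenomicInterval, IntervalSet, partition_multi, subtract

__all__ = [
    "Confidence",
    "GroupingScheme",
    "ScoredInterval",
    "build_support_matrix",
    "caller_cumulative_score",
    "convert_cumulative",
    "assign_confidence_gain_loss",
    "assign_confidence_loh",
    "score_cohort",
]

logger = logging.getLogger(__name__)


class Confidence(str, enum.Enum):
    STRONG = "STRONG"
    MEDIUM = "MEDIUM"
    WEAK = "WEAK"
    NEUTRAL = "NEUTRAL"
    NONE = "NONE"

    def __str__(self) -> str:
        return self.value

    @property
    def rank(self) -> int:
        return {"NONE": 0, "NEUTRAL": 1, "WEAK": 2, "MEDIUM": 3, "STRONG": 4}[self.value]


@dataclass
class GroupingScheme:
    """Assignment of (center, replicate) to score groups with divisors.

    ``group_of`` maps each replicate to a group id; ``divisor_of`` gives the
    normalization divisor per group (the 9-replicate group uses 3, all
    others 1, so every group contributes at most 3).
    """

    group_of: Dict[Tuple[str, str], str]
    divisor_of: Dict[str, float]

    def __post_init__(self) -> None:
        for gid, div in self.divisor_of.items():
            if div < 1:
                raise ValueError(f"group {gid!r} divisor {div} < 1")
        missing = {g for g in self.group_of.values()} - set(self.divisor_of)
        if missing:
            raise ValueError(f"groups without divisor: {sorted(missing)}")

    @property
    def replicates(self) -> List[Tuple[str, str]]:
        return list(self.group_of)

    @property
    def max_cumulative(self) -> float:
        counts: Dict[str, int] = {}
        for gid in self.group_of.values():
            counts[gid] = counts.get(gid, 0) + 1
        return sum(counts[g] / self.divisor_of[g] for g in counts)

    @classmethod
    def default(cls) -> "GroupingScheme":
        """The study layout: FD/IL/NV 3 reps each, NS 9 reps (divided by 3),
        and EA/LL/NC one rep each pooled into a fifth group. Max score 15."""
        group_of: Dict[Tuple[str, str], str] = {}
        for center, n, gid in (
            ("FD", 3, "G1"), ("IL", 3, "G2"), ("NV", 3, "G3"), ("NS", 9, "G4"),
        ):
            for i in range(1, n + 1):
                group_of[(center, str(i))] = gid
        for center in ("EA", "LL", "NC"):
            group_of[(center, "1")] = "G5"
        divisor_of = {"G1": 1.0, "G2": 1.0, "G3": 1.0, "G4": 3.0, "G5": 1.0}
        return cls(group_of, divisor_of)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"center": c, "replicate": r, "group": g, "divisor": self.divisor_of[g]}
            for (c, r), g in self.group_of.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df) -> "GroupingScheme":
        group_of = {
            (str(r.center), str(r.replicate)): str(r.group) for r in df.itertuples()
        }
        divisor_of = {str(r.group): float(r.divisor) for r in df.itertuples()}
        return cls(group_of, divisor_of)


@dataclass
class ScoredInterval:
    """A disjoint consensus interval with per-caller and total scores."""

    interval: GenomicInterval
    cnv_type: CNVType
    per_caller_cumulative: Dict[str, float]
    per_caller_converted: Dict[str, int]
    total_score: int
    confidence: Confidence

    @property
    def length(self) -> int:
        return self.interval.length


def caller_cumulative_score(
    support: Mapping[Tuple[str, str], bool], scheme: GroupingScheme
) -> float:
    """Cumulative group score for one caller from its replicate support.

    Each group contributes (number of supporting replicates) / divisor;
    contributions sum across groups. With the default scheme the result
    lies in [0, 15].
    """
    counts: Dict[str, int] = {}
    for rep, supported in support.items():
        if rep not in scheme.group_of:
            raise ValueError(f"replicate {rep!r} not in grouping scheme")
        if supported:
            gid = scheme.group_of[rep]
            counts[gid] = counts.get(gid, 0) + 1
    return sum(n / scheme.divisor_of[g] for g, n in counts.items())


def convert_cumulative(score: float, max_score: float = 15.0) -> int:
    """Convert a cumulative group score to the 0-3 per-caller scale.

    Integer anchor points: 0-3 -> 0, 4-6 -> 1, 7-9 -> 2, 10-15 -> 3;
    fractional scores fall in the half-open bins (3,6], (6,9], (9,15].
    """
    if not (0 <= score <= max_score + 1e-9):
        raise ValueError(f"cumulative score {score} outside [0, {max_score}]")
    if score <= 3:
        return 0
    if score <= 6:
        return 1
    if score <= 9:
        return 2
    return 3


def assign_confidence_gain_loss(total_score: float) -> Confidence:
    """Six-caller scale: 11-18 strong, 8-10 medium, 4-7 weak, 1-3 neutral,
    0 (no support at all) maps to NONE."""
    if not (0 <= total_score <= 18):
        raise ValueError(f"total score {total_score} outside [0, 18]")
    if total_score == 0:
        return Confidence.NONE
    if total_score >= 11:
        return Confidence.STRONG
    if total_score >= 8:
        return Confidence.MEDIUM
    if total_score >= 4:
        return Confidence.WEAK
    return Confidence.NEUTRAL


def assign_confidence_loh(total_score: float) -> Confidence:
    """Five-caller LOH scale: strong strictly above 8, medium 6-8, weak 4-5,
    neutral 1-3, NONE at 0.

    The published scale leaves 8 and 3 unassigned (strong is "> 8", medium
    "6-7", neutral "< 3"); both gaps close downward here, preserving the
    strict inequality for strong.
    """
    if not (0 <= total_score <= 15):
        raise ValueError(f"total score {total_score} outside [0, 15]")
    if total_score == 0:
        return Confidence.NONE
    if total_score > 8:
        return Confidence.STRONG
    if total_score >= 6:
        return Confidence.MEDIUM
    if total_score > 3:
        return Confidence.WEAK
    return Confidence.NEUTRAL


def build_support_matrix(
    cohort: Cohort,
    cnv_type: CNVType,
    mask: Optional[ExclusionMask] = None,
) -> Tuple[List[Tuple[str, str, str]], List[Tuple[GenomicInterval, Tuple[bool, ...]]]]:
    """Disjoint intervals with per-call-set support for one CNV type.

    Returns the ordered call-set keys ``(caller, center, replicate)`` and
    the partition of the union of all (masked) typed regions. Empty when no
    call set has calls of the requested type.
    """
    keys = [(cs.caller, cs.center, cs.replicate) for cs in cohort.callsets]
    region_sets = []
    for cs in cohort.callsets:
        regions = cs.typed_regions(cnv_type)
        if mask is not None:
            regions = subtract(regions, mask)
        region_sets.append(regions)
    if all(r.is_empty for r in region_sets):
        return keys, []
    return keys, partition_multi(region_sets)


def _confidence_for(cnv_type: CNVType, total: int, n_callers: int) -> Confidence:
    if cnv_type == CNVType.LOH:
        return assign_confidence_loh(total)
    return assign_confidence_gain_loss(total)


def score_cohort(
    cohort: Cohort,
    cnv_type: CNVType,
    mask: Optional[ExclusionMask] = None,
) -> List[ScoredInterval]:
    """Score a cohort's calls of one type into disjoint confidence-labelled
    intervals.

    Pipeline: mask each call set's typed regions, partition the union into
    disjoint intervals with support vectors, aggregate replicate support
    into per-caller cumulative group scores, convert each to 0-3, sum
    across callers, and assign confidence (six-caller scale for gain/loss,
    five-caller LOH scale). Callers with no call of the requested type in
    any replicate are dropped from that type's scale (e.g. a caller that
    never reports LOH).
    """
    if cnv_type not in (CNVType.GAIN, CNVType.LOSS, CNVType.LOH):
        raise ValueError(f"cannot score type {cnv_type}")
    scheme = cohort.grouping if cohort.grouping is not None else GroupingScheme.default()
    callers = [
        c for c in cohort.callers
        if any(cs.has_type(cnv_type) for cs in cohort.by_caller(c))
    ]
    dropped = set(cohort.callers) - set(callers)
    if dropped:
        logger.warning(
            "callers with no %s calls dropped from the %s scale: %s",
            cnv_type, cnv_type, sorted(dropped),
        )
    sub = Cohort(
        [cs for cs in cohort.callsets if cs.caller in callers], grouping=scheme
    )
    if not sub.callsets:
        return []
    keys, matrix = build_support_matrix(sub, cnv_type, mask)
    out: List[ScoredInterval] = []
    for interval, vec in matrix:
        cumulative: Dict[str, float] = {}
        converted: Dict[str, int] = {}
        for caller in callers:
            support = {
                (center, rep): vec[i]
                for i, (cal, center, rep) in enumerate(keys)
                if cal == caller
            }
            cum = caller_cumulative_score(support, scheme)
            cumulative[caller] = cum
            converted[caller] = convert_cumulative(cum, scheme.max_cumulative)
        total = int(sum(converted.values()))
        out.append(
            ScoredInterval(
                interval=interval,
                cnv_type=cnv_type,
                per_caller_cumulative=cumulative,
                per_caller_converted=converted,
                total_score=total,
                confidence=_confidence_for(cnv_type, total, len(callers)),
            )
        )
    return out


def scored_to_frame(scored: Sequence[ScoredInterval]):
    """Tabular view: chrom, start, end, type, per-caller scores, total,
    confidence."""
    import pandas as pd

    callers = sorted({c for s in scored for c in s.per_caller_converted})
    rows = []
    for s in scored:
        row = {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "type": str(s.cnv_type),
        }
        for c in callers:
            row[f"score_{c}"] = s.per_caller_converted.get(c, 0)
        row["total_score"] = s.total_score
        row["confidence"] = str(s.confidence)
        rows.append(row)
    return pd.DataFrame(rows)
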
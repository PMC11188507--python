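"""Concordance and accuracy metrics.

All metrics are length-based: precision is the fraction of the query's
CNV-affected bases that lie inside the truth regions, recall the fraction
of truth bases recovered, F1 their harmonic mean. Pairwise reproducibility
between call sets uses the Jaccard index of typed regions, optionally
restricted to gene or exon annotation. The ploidy estimator is the
length-weighted mean total copy number over called segments, and the
re-centering shift converts an estimated ploidy into the log2 offset that
moves the copy-neutral level to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .callsets import CallSet, CNVType
from .intervals import (
    ExclusionMask,
    IntervalSet,
    intersect_length,
    jaccard,
    restrict_to_annotation,
    subtract,
)
from .validation import BenchmarkSet

__all__ = [
    "EvalMetrics",
    "PloidyEstimate",
    "precision_recall_f1",
    "pairwise_jaccard",
    "estimate_ploidy",
    "recenter_shift",
]


@dataclass(frozen=True)
class EvalMetrics:
    """Length-based precision/recall/F1; NaN marks an undefined ratio
    (empty query or empty truth), never silently zero."""

    precision: float
    recall: float
    f1: float
    query_length: int
    truth_length: int
    overlap_length: int


@dataclass(frozen=True)
class PloidyEstimate:
    ploidy: float
    covered_length: int


def _typed_regions(side: Union[CallSet, BenchmarkSet, IntervalSet], cnv_type) -> IntervalSet:
    if isinstance(side, IntervalSet):
        return side
    return side.typed_regions(cnv_type)


def precision_recall_f1(
    query: Union[CallSet, IntervalSet],
    truth: Union[BenchmarkSet, IntervalSet],
    cnv_type: CNVType,
    mask: Optional[ExclusionMask] = None,
) -> EvalMetrics:
    """Evaluate one CNV type of a query call set against a truth set.

    Both sides are masked identically before length accounting. An empty
    query yields NaN precision, an empty truth NaN recall; F1 is NaN
    whenever either component is, and 0 when P + R = 0.
    """
    q = _typed_regions(query, cnv_type)
    t = _typed_regions(truth, cnv_type)
    if mask is not None:
        q = subtract(q, mask)
        t = subtract(t, mask)
    overlap = intersect_length(q, t)
    ql, tl = q.total_length, t.total_length
    precision = overlap / ql if ql else math.nan
    recall = overlap / tl if tl else math.nan
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalMetrics(precision, recall, f1, ql, tl, overlap)


def pairwise_jaccard(
    callsets: Sequence[CallSet],
    cnv_type: CNVType,
    level: str = "segment",
    annotation: Optional[IntervalSet] = None,
    mask: Optional[ExclusionMask] = None,
) -> pd.DataFrame:
    """Symmetric Jaccard matrix of typed regions across call sets.

    ``level`` is 'segment' (whole-genome regions) or 'gene'/'exon', in
    which case regions are first restricted to the annotation track.
    Row/column labels are ``caller/center/replicate``.
    """
    if level not in ("segment", "gene", "exon"):
        raise ValueError(f"unknown level {level!r}")
    if level != "segment" and annotation is None:
        raise ValueError(f"{level}-level concordance requires an annotation track")
    regions = []
    labels = []
    for cs in callsets:
        r = cs.typed_regions(cnv_type)
        if mask is not None:
            r = subtract(r, mask)
        if level != "segment":
            r = restrict_to_annotation(r, annotation)
        regions.append(r)
        labels.append(f"{cs.caller}/{cs.center}/{cs.replicate}")
    n = len(regions)
    mat = np.ones((n, n))
    for i in range(n):
        mat[i, i] = 1.0 if not regions[i].is_empty else math.nan
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard(regions[i], regions[j])
    return pd.DataFrame(mat, index=labels, columns=labels)


def estimate_ploidy(callset: CallSet) -> PloidyEstimate:
    """Length-weighted average total copy number over called segments.

    Each segment contributes length x copy number to the numerator and
    length to the denominator (the total genome length covered by calls).
    """
    num = 0.0
    den = 0
    for c in callset.calls:
        num += c.interval.length * c.total_cn
        den += c.interval.length
    if den == 0:
        raise ValueError("cannot estimate ploidy: no called bases")
    return PloidyEstimate(ploidy=num / den, covered_length=den)


def recenter_shift(ploidy: float) -> float:
    """Log2 shift that re-centers log-ratio calls for a non-diploid genome.

    Equals log2(2 / ploidy): the copy-neutral level of a genome with the
    given overall ploidy, expressed on the log2-ratio scale that assumes
    diploidy (e.g. ploidy 2.85 -> -0.51).
    """
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    return math.log2(2.0 / ploidy)
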
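"""CNV call-set model, copy-number typing, and segment/VCF I/O.

A *call set* is the collection of CNV segments one caller reported on one
replicate sample. Calls are typed GAIN / LOSS / LOH / NEUTRAL from total
copy number against the diploid baseline of 2: gain above 2, loss below 2,
and at exactly 2 either copy-neutral LOH (minor allele absent) or neutral.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .intervals import GenomicInterval, IntervalSet, normalize

__all__ = [
    "CNVType",
    "CNVCall",
    "CallSet",
    "Cohort",
    "classify_call",
    "read_segments",
    "write_segments",
    "write_benchmark_vcf",
    "read_benchmark_vcf",
    "DIALECTS",
]

#: Tolerance when comparing (possibly fractional) copy numbers against 2.
CN_EQUAL_TOL = 1e-6


class CNVType(str, enum.Enum):
    GAIN = "GAIN"
    LOSS = "LOSS"
    LOH = "LOH"
    NEUTRAL = "NEUTRAL"

    def __str__(self) -> str:
        return self.value


def classify_call(
    total_cn: float,
    loh: Optional[bool] = None,
    minor_cn: Optional[float] = None,
    tol: float = CN_EQUAL_TOL,
) -> CNVType:
    """Type a segment from its total copy number.

    GAIN iff total_cn > 2, LOSS iff total_cn < 2 (both beyond ``tol``);
    at copy number 2 the call is LOH when the caller flagged it or the
    minor-allele copy number is zero, else NEUTRAL.
    """
    if total_cn < 0:
        raise ValueError(f"negative copy number {total_cn}")
    if total_cn > 2 + tol:
        return CNVType.GAIN
    if total_cn < 2 - tol:
        return CNVType.LOSS
    if loh is True:
        return CNVType.LOH
    if loh is None and minor_cn is not None and abs(minor_cn) <= tol:
        return CNVType.LOH
    return CNVType.NEUTRAL


@dataclass(frozen=True)
class CNVCall:
    """One called segment with copy-number state."""

    interval: GenomicInterval
    total_cn: float
    minor_cn: Optional[float] = None
    loh: Optional[bool] = None
    cnv_type: CNVType = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.minor_cn is not None and not (
            -CN_EQUAL_TOL <= self.minor_cn <= self.total_cn + CN_EQUAL_TOL
        ):
            raise ValueError(
                f"minor_cn {self.minor_cn} outside [0, total_cn={self.total_cn}]"
            )
        if self.cnv_type is None:
            object.__setattr__(
                self, "cnv_type", classify_call(self.total_cn, self.loh, self.minor_cn)
            )


@dataclass
class CallSet:
    """All segments one caller reported on one replicate."""

    caller: str
    center: str
    replicate: str
    platform: str = "WGS"
    calls: List[CNVCall] = field(default_factory=list)

    @property
    def key(self) -> Tuple[str, str, str, str]:
        return (self.caller, self.center, self.replicate, self.platform)

    def typed_regions(self, cnv_type: CNVType) -> IntervalSet:
        """Normalized regions of one CNV type."""
        return normalize(c.interval for c in self.calls if c.cnv_type == cnv_type)

    def has_type(self, cnv_type: CNVType) -> bool:
        return any(c.cnv_type == cnv_type for c in self.calls)


@dataclass
class Cohort:
    """Caller x replicate call sets plus the replicate grouping scheme."""

    callsets: List[CallSet]
    grouping: "GroupingScheme" = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        keys = [cs.key for cs in self.callsets]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (caller, center, replicate, platform) in cohort")
        if self.grouping is not None:
            for cs in self.callsets:
                if (cs.center, cs.replicate) not in self.grouping.group_of:
                    raise ValueError(
                        f"replicate ({cs.center}, {cs.replicate}) missing from grouping"
                    )

    @property
    def callers(self) -> List[str]:
        seen: Dict[str, None] = {}
        for cs in self.callsets:
            seen.setdefault(cs.caller, None)
        return list(seen)

    def by_caller(self, caller: str) -> List[CallSet]:
        return [cs for cs in self.callsets if cs.caller == caller]


# ---------------------------------------------------------------------------
# Segment-table dialects
#
# Each caller emits a different table layout; a dialect maps column
# positions (0-based) to the fields the pipeline needs. All dialects are
# tab-separated, 0-based half-open, no quoting.

DIALECTS: Dict[str, Dict[str, int]] = {
    # chrom start end total_cn [minor_cn] [loh 0/1]
    "default": {"chrom": 0, "start": 1, "end": 2, "total_cn": 3, "minor_cn": 4, "loh": 5},
    "bed4cn": {"chrom": 0, "start": 1, "end": 2, "total_cn": 3},
    # chrom start end total_cn minor_cn
    "allele_specific": {"chrom": 0, "start": 1, "end": 2, "total_cn": 3, "minor_cn": 4},
}


def _parse_optional(parts: Sequence[str], idx: Optional[int], cast):
    if idx is None or idx >= len(parts) or parts[idx] in ("", ".", "NA"):
        return None
    return cast(parts[idx])


def read_segments(
    path,
    dialect: str = "default",
    caller: str = "unknown",
    center: str = "unknown",
    replicate: str = "1",
    platform: str = "WGS",
) -> CallSet:
    """Read a tab-separated segment table into a :class:`CallSet`.

    Unparseable rows raise with the offending line number; an unknown
    dialect raises listing the registered ones.
    """
    if dialect not in DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        )
    cols = DIALECTS[dialect]
    calls: List[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                iv = GenomicInterval(
                    parts[cols["chrom"]],
                    int(parts[cols["start"]]),
                    int(parts[cols["end"]]),
                )
                total_cn = float(parts[cols["total_cn"]])
                minor_cn = _parse_optional(parts, cols.get("minor_cn"), float)
                loh_raw = _parse_optional(parts, cols.get("loh"), str)
                loh = None if loh_raw is None else loh_raw in ("1", "true", "True")
                calls.append(
                    CNVCall(iv, total_cn, minor_cn=minor_cn, loh=loh)
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return CallSet(caller, center, replicate, platform, calls)


def write_segments(callset: CallSet, path) -> None:
    """Write a call set in the 'default' dialect."""
    with open(path, "w") as fh:
        for c in sorted(callset.calls, key=lambda c: c.interval):
            minor = "." if c.minor_cn is None else f"{c.minor_cn:g}"
            loh = "." if c.loh is None else ("1" if c.loh else "0")
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.total_cn:g}\t{minor}\t{loh}\n"
            )


# ---------------------------------------------------------------------------
# Benchmark VCF I/O

_VCF_ALLELE = {CNVType.GAIN: "<DUP>", CNVType.LOSS: "<DEL>", CNVType.LOH: "<LOH>"}
_ALLELE_TYPE = {v: k for k, v in _VCF_ALLELE.items()}

_VCF_HEADER = """\
##fileformat=VCFv4.3
##ALT=<ID=DUP,Description="Copy number gain">
##ALT=<ID=DEL,Description="Copy number loss">
##ALT=<ID=LOH,Description="Copy-neutral loss of heterozygosity">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="CNV type">
##INFO=<ID=CONF,Number=1,Type=String,Description="Consensus confidence level">
##INFO=<ID=MEDCN,Number=1,Type=Float,Description="Median total copy number across supporting callers">
##INFO=<ID=TECHS,Number=.,Type=String,Description="Supporting orthogonal technologies">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_benchmark_vcf(benchmark, path) -> None:
    """Write benchmark intervals as VCF 4.3 records with symbolic alleles.

    Positions are converted from the package's 0-based half-open spans to
    VCF's 1-based POS with inclusive END: ``[s, e)`` becomes POS ``s+1``,
    END ``e``.
    """
    records = sorted(benchmark.intervals, key=lambda b: b.interval)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for i, b in enumerate(records, 1):
            iv = b.interval
            info = [
                f"END={iv.end}",
                f"SVTYPE={'DUP' if b.cnv_type == CNVType.GAIN else 'DEL' if b.cnv_type == CNVType.LOSS else 'LOH'}",
                f"CONF={b.confidence.value}",
                f"MEDCN={b.median_cn:g}",
            ]
            if b.technologies:
                info.append("TECHS=" + ",".join(b.technologies))
            fh.write(
                f"{iv.chrom}\t{iv.start + 1}\tcnv{i}\tN\t{_VCF_ALLELE[b.cnv_type]}"
                f"\t.\tPASS\t{';'.join(info)}\n"
            )


def read_benchmark_vcf(path):
    """Read a benchmark VCF written by :func:`write_benchmark_vcf`."""
    import pysam

    from .validation import BenchmarkInterval, BenchmarkSet, Confidence

    intervals = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0]
            cnv_type = _ALLELE_TYPE[f"<{alt.strip('<>')}>"]
            techs = rec.info.get("TECHS", ())
            if isinstance(techs, str):
                techs = (techs,)
            intervals.append(
                BenchmarkInterval(
                    interval=GenomicInterval(rec.chrom, rec.pos - 1, rec.stop),
                    cnv_type=cnv_type,
                    confidence=Confidence(rec.info["CONF"]),
                    median_cn=float(rec.info["MEDCN"]),
                    technologies=tuple(techs),
                )
            )
    return BenchmarkSet(intervals=intervals)
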
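"""Synthetic truth landscapes and noisy caller / orthogonal call sets.

The generator emulates the statistical structure of a hyper-diploid
breast-cancer genome (overall ploidy near 2.85): large copy-gain blocks
covering close to half the genome, widespread copy-neutral LOH, and rarer
losses. Callers are simulated at the segment level with four noise
channels observed in real multi-caller studies: dropouts (per-type
sensitivity), false segments (a Poisson process along the genome),
breakpoint jitter (rounded Gaussian), and whole-replicate ploidy
mis-centering that shifts every copy number by an integer and re-types the
genome en masse — the failure mode that makes a caller report most of a
genome as gained.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .callsets import CallSet, CNVCall, CNVType, Cohort, classify_call
from .evaluation import estimate_ploidy
from .intervals import ExclusionMask, GenomicInterval, IntervalSet, normalize
from .scoring import GroupingScheme
from .validation import OrthogonalCallSet

__all__ = [
    "GenomeSpec",
    "TruthParams",
    "TruthProfile",
    "CallerModel",
    "OrthogonalModel",
    "derive_seed",
    "default_genome",
    "default_caller_models",
    "default_orthogonal_models",
    "simulate_truth",
    "simulate_callset",
    "simulate_cohort",
    "simulate_orthogonal",
]


def derive_seed(root: int, *keys) -> int:
    """Stable per-stream seed below 2**31 from a root seed and string keys.

    Hash-derived so adding a caller or technology never perturbs the
    streams of existing ones.
    """
    h = hashlib.sha256(("|".join([str(root), *map(str, keys)])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass
class GenomeSpec:
    """Chromosome lengths plus the exclusion mask applied in all accounting."""

    chromosomes: Dict[str, int]
    mask: ExclusionMask = field(default_factory=ExclusionMask.empty)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has nonpositive length")
        for iv in self.mask.regions:
            if iv.chrom in self.chromosomes and iv.end > self.chromosomes[iv.chrom]:
                raise ValueError(f"mask interval {iv} exceeds chromosome bounds")

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())


def default_genome() -> GenomeSpec:
    """Compact three-chromosome genome (30/20/10 Mb) with a small mask
    standing in for centromere/telomere gap exclusions."""
    chroms = {"chr1": 30_000_000, "chr2": 20_000_000, "chr3": 10_000_000}
    mask = ExclusionMask(
        regions=normalize(
            [
                GenomicInterval("chr1", 14_500_000, 15_500_000),
                GenomicInterval("chr2", 0, 500_000),
                GenomicInterval("chr3", 9_500_000, 10_000_000),
            ]
        ),
        label="synthetic gaps",
    )
    return GenomeSpec(chroms, mask)


@dataclass
class TruthParams:
    """Composition of the simulated truth landscape.

    Type fractions and copy-number distributions are chosen so the
    expected length-weighted ploidy is ~2.85 (hyper-diploid): gains on
    ~45% of the genome at copy numbers 3-6, copy-neutral LOH on ~20%,
    losses on ~5%.
    """

    target_ploidy: float = 2.85
    ploidy_tolerance: float = 0.3
    mean_segment_length: float = 1_500_000.0
    min_segment_length: int = 200_000
    frac_gain: float = 0.45
    frac_loss: float = 0.05
    frac_loh: float = 0.20
    gain_cn: Tuple[Tuple[int, float], ...] = ((3, 0.40), (4, 0.35), (5, 0.15), (6, 0.10))
    loss_cn: Tuple[Tuple[int, float], ...] = ((0, 0.20), (1, 0.80))

    @property
    def frac_neutral(self) -> float:
        return 1.0 - self.frac_gain - self.frac_loss - self.frac_loh


@dataclass
class TruthProfile:
    """Segments tiling every chromosome exactly, with true copy numbers."""

    spec: GenomeSpec
    segments: List[CNVCall]

    def typed_regions(self, cnv_type: CNVType) -> IntervalSet:
        return normalize(s.interval for s in self.segments if s.cnv_type == cnv_type)

    def to_callset(self, name: str = "truth") -> CallSet:
        return CallSet(name, "truth", "0", "synthetic", list(self.segments))

    @property
    def overall_ploidy(self) -> float:
        return estimate_ploidy(self.to_callset()).ploidy


def _draw_segments(
    rng: np.random.Generator, spec: GenomeSpec, params: TruthParams
) -> List[CNVCall]:
    types = [CNVType.GAIN, CNVType.LOSS, CNVType.LOH, CNVType.NEUTRAL]
    probs = [params.frac_gain, params.frac_loss, params.frac_loh, params.frac_neutral]
    if params.frac_neutral < 0:
        raise ValueError("type fractions exceed 1")
    gain_vals = [v for v, _ in params.gain_cn]
    gain_p = [p for _, p in params.gain_cn]
    loss_vals = [v for v, _ in params.loss_cn]
    loss_p = [p for _, p in params.loss_cn]
    segments: List[CNVCall] = []
    for chrom, length in spec.chromosomes.items():
        if params.min_segment_length > length:
            raise ValueError(
                f"min segment length {params.min_segment_length} exceeds {chrom}"
            )
        pos = 0
        while pos < length:
            seg_len = int(
                params.min_segment_length
                + rng.exponential(params.mean_segment_length - params.min_segment_length)
            )
            end = min(pos + seg_len, length)
            if length - end < params.min_segment_length:
                end = length  # absorb the remainder into the last segment
            t = types[rng.choice(len(types), p=probs)]
            if t == CNVType.GAIN:
                cn, minor = float(rng.choice(gain_vals, p=gain_p)), None
            elif t == CNVType.LOSS:
                cn, minor = float(rng.choice(loss_vals, p=loss_p)), None
            elif t == CNVType.LOH:
                cn, minor = 2.0, 0.0
            else:
                cn, minor = 2.0, 1.0
            segments.append(
                CNVCall(GenomicInterval(chrom, pos, end), cn, minor_cn=minor, cnv_type=t)
            )
            pos = end
    return segments


def simulate_truth(
    spec: GenomeSpec, params: Optional[TruthParams] = None, seed: int = 0
) -> TruthProfile:
    """Draw a truth landscape tiling the genome; deterministic given seed.

    Redraws (up to 100 substreams) until the realized length-weighted
    ploidy is within ``params.ploidy_tolerance`` of the target, so the
    profile honors the hyper-diploid design even for unlucky draws.
    """
    params = params or TruthParams()
    for attempt in range(100):
        rng = np.random.default_rng(derive_seed(seed, "truth", attempt))
        segments = _draw_segments(rng, spec, params)
        profile = TruthProfile(spec, segments)
        if abs(profile.overall_ploidy - params.target_ploidy) <= params.ploidy_tolerance:
            return profile
    raise RuntimeError(
        "could not draw a truth profile near the target ploidy; "
        "check TruthParams composition"
    )


# ---------------------------------------------------------------------------
# Caller and orthogonal-technology noise models


def _default_sensitivity() -> Dict[CNVType, float]:
    return {CNVType.GAIN: 0.95, CNVType.LOSS: 0.95, CNVType.LOH: 0.95}


@dataclass
class CallerModel:
    """Noise parameters of one simulated caller.

    ``fp_rate`` is expected false segments per 100 Mb per replicate;
    ``breakpoint_jitter_sd`` the SD (bp) of rounded Gaussian endpoint
    noise; ``ploidy_shift_prob`` the per-replicate probability that the
    whole call set's copy numbers shift by ``ploidy_shift_delta`` before
    re-typing (mis-centered baseline).
    """

    sensitivity: Dict[CNVType, float] = field(default_factory=_default_sensitivity)
    fp_rate: float = 1.0
    breakpoint_jitter_sd: float = 5_000.0
    min_detectable_length: int = 50_000
    ploidy_shift_prob: float = 0.0
    ploidy_shift_delta: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for t, p in self.sensitivity.items():
            if not 0 <= p <= 1:
                raise ValueError(f"sensitivity[{t}]={p} outside [0,1]")
        if self.breakpoint_jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if self.ploidy_shift_prob > 0 and self.ploidy_shift_delta == 0:
            raise ValueError("ploidy_shift_delta must be nonzero when shift enabled")


@dataclass
class OrthogonalModel:
    """Resolution/sensitivity model of an orthogonal technology; same
    channels as a caller minus ploidy mis-centering and false calls."""

    sensitivity: Dict[CNVType, float] = field(
        default_factory=lambda: {t: 0.98 for t in (CNVType.GAIN, CNVType.LOSS, CNVType.LOH)}
    )
    breakpoint_jitter_sd: float = 2_000.0
    min_detectable_length: int = 100_000
    seed: int = 0


def _jitter_interval(
    rng: np.random.Generator,
    iv: GenomicInterval,
    sd: float,
    chrom_len: int,
) -> Optional[GenomicInterval]:
    if sd <= 0:
        return iv
    start = int(round(iv.start + rng.normal(0, sd)))
    end = int(round(iv.end + rng.normal(0, sd)))
    start = max(0, min(start, chrom_len - 1))
    end = max(1, min(end, chrom_len))
    if start >= end:
        return None
    return GenomicInterval(iv.chrom, start, end)


def simulate_callset(
    truth: TruthProfile,
    model: CallerModel,
    caller: str,
    center: str,
    replicate: str,
    platform: str = "WGS",
) -> CallSet:
    """One caller's call set on one replicate; deterministic given seeds."""
    rng = np.random.default_rng(derive_seed(model.seed, caller, center, replicate))
    shifted = model.ploidy_shift_prob > 0 and rng.random() < model.ploidy_shift_prob
    delta = model.ploidy_shift_delta if shifted else 0
    calls: List[CNVCall] = []
    for seg in truth.segments:
        cn = max(0.0, seg.total_cn + delta)
        cnv_type = classify_call(cn, loh=None, minor_cn=seg.minor_cn)
        if cnv_type == CNVType.NEUTRAL:
            continue
        if seg.interval.length <= model.min_detectable_length:
            continue
        if rng.random() >= model.sensitivity.get(cnv_type, 0.0):
            continue
        iv = _jitter_interval(
            rng, seg.interval, model.breakpoint_jitter_sd,
            truth.spec.chromosomes[seg.interval.chrom],
        )
        if iv is None:
            continue
        calls.append(CNVCall(iv, cn, minor_cn=seg.minor_cn, cnv_type=cnv_type))
    # false segments: Poisson along the genome
    n_fp = rng.poisson(model.fp_rate * truth.spec.total_length / 1e8)
    chroms = list(truth.spec.chromosomes)
    weights = np.array([truth.spec.chromosomes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(n_fp):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        clen = truth.spec.chromosomes[chrom]
        length = int(model.min_detectable_length + rng.exponential(500_000))
        length = min(length, clen - 1)
        start = int(rng.integers(0, clen - length))
        cn = 3.0 if rng.random() < 0.5 else 1.0
        calls.append(CNVCall(GenomicInterval(chrom, start, start + length), cn))
    return CallSet(caller, center, replicate, platform, calls)


def default_caller_models(seed: int = 0, n_callers: int = 6) -> Dict[str, CallerModel]:
    """Six moderately noisy, high-concordance callers.

    ``callerA`` never reports LOH (sensitivity 0), exercising the
    five-caller LOH scale the way one real caller does in the study design.
    """
    names = [f"caller{chr(ord('A') + i)}" for i in range(n_callers)]
    models = {}
    for name in names:
        sens = _default_sensitivity()
        if name == "callerA":
            sens[CNVType.LOH] = 0.0
        models[name] = CallerModel(sensitivity=sens, seed=derive_seed(seed, "caller", name))
    return models


def default_orthogonal_models(seed: int = 0) -> Dict[str, OrthogonalModel]:
    """Three near-noiseless technologies emulating two SNP arrays and
    optical genome mapping (coarser minimum size)."""
    return {
        "arrayA": OrthogonalModel(seed=derive_seed(seed, "tech", "arrayA")),
        "arrayB": OrthogonalModel(seed=derive_seed(seed, "tech", "arrayB")),
        "optical": OrthogonalModel(
            min_detectable_length=150_000, seed=derive_seed(seed, "tech", "optical")
        ),
    }


def simulate_cohort(
    truth: TruthProfile,
    models: Dict[str, CallerModel],
    grouping: Optional[GroupingScheme] = None,
) -> Cohort:
    """One call set per caller x replicate of the grouping scheme (the
    default layout yields 6 x 21 = 126 call sets)."""
    scheme = grouping or GroupingScheme.default()
    callsets = [
        simulate_callset(truth, model, caller, center, rep)
        for caller, model in models.items()
        for center, rep in scheme.replicates
    ]
    return Cohort(callsets, grouping=scheme)


def simulate_orthogonal(
    truth: TruthProfile, model: OrthogonalModel, technology: str
) -> OrthogonalCallSet:
    """One orthogonal technology's call set: dropouts, size floor and
    jitter, but no false calls and no ploidy mis-centering."""
    rng = np.random.default_rng(derive_seed(model.seed, "orthogonal", technology))
    calls: List[CNVCall] = []
    for seg in truth.segments:
        if seg.cnv_type == CNVType.NEUTRAL:
            continue
        if seg.interval.length <= model.min_detectable_length:
            continue
        if rng.random() >= model.sensitivity.get(seg.cnv_type, 0.0):
            continue
        iv = _jitter_interval(
            rng, seg.interval, model.breakpoint_jitter_sd,
            truth.spec.chromosomes[seg.interval.chrom],
        )
        if iv is None:
            continue
        calls.append(
            CNVCall(iv, seg.total_cn, minor_cn=seg.minor_cn, cnv_type=seg.cnv_type)
        )
    return OrthogonalCallSet(technology, calls)
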
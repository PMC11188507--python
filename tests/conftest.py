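"""Shared fixtures and brute-force per-base oracles.

The oracle represents a region set as one boolean array per chromosome
(coordinates < 10^4), so every interval operation has an obvious,
independently-written reference implementation to compare against.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pytest

from cnvconsensus import (
    CNVType,
    GenomicInterval,
    IntervalSet,
    default_caller_models,
    default_genome,
    default_orthogonal_models,
    normalize,
    score_cohort,
    simulate_cohort,
    simulate_orthogonal,
    simulate_truth,
    subtract,
)
from cnvconsensus.validation import assemble_benchmark

ORACLE_SIZE = 10_000
ORACLE_CHROMS = ("chr1", "chr2", "chr3")


# ---------------------------------------------------------------------------
# per-base oracle


def base_mask(intervals: Iterable[GenomicInterval]) -> Dict[str, np.ndarray]:
    """Boolean per-base membership arrays, one per chromosome."""
    masks = {c: np.zeros(ORACLE_SIZE, dtype=bool) for c in ORACLE_CHROMS}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mask_of_set(iset: IntervalSet) -> Dict[str, np.ndarray]:
    return base_mask(iset)


def mask_to_intervals(masks: Dict[str, np.ndarray]) -> List[GenomicInterval]:
    """Maximal runs of covered bases, per chromosome."""
    out = []
    for chrom in sorted(masks):
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def random_interval_set(rng: np.random.Generator, max_intervals: int = 50) -> List[GenomicInterval]:
    n = int(rng.integers(0, max_intervals + 1))
    out = []
    for _ in range(n):
        chrom = ORACLE_CHROMS[rng.integers(0, len(ORACLE_CHROMS))]
        start = int(rng.integers(0, ORACLE_SIZE - 1))
        length = int(rng.integers(1, 400))
        out.append(GenomicInterval(chrom, start, min(start + length, ORACLE_SIZE)))
    return out


# ---------------------------------------------------------------------------
# session-scoped default simulation (shared by acceptance and unit tests)


@pytest.fixture(scope="session")
def sim_seed() -> int:
    return 1


@pytest.fixture(scope="session")
def sim_truth(sim_seed):
    return simulate_truth(default_genome(), seed=sim_seed)


@pytest.fixture(scope="session")
def sim_techs(sim_truth, sim_seed):
    return [
        simulate_orthogonal(sim_truth, model, name)
        for name, model in default_orthogonal_models(seed=sim_seed).items()
    ]


@pytest.fixture(scope="session")
def sim_cohort(sim_truth, sim_seed):
    return simulate_cohort(sim_truth, default_caller_models(seed=sim_seed))


@pytest.fixture(scope="session")
def sim_scored(sim_cohort, sim_truth):
    mask = sim_truth.spec.mask
    return {
        t: score_cohort(sim_cohort, t, mask)
        for t in (CNVType.GAIN, CNVType.LOSS, CNVType.LOH)
    }


@pytest.fixture(scope="session")
def sim_benchmark(sim_scored, sim_techs, sim_cohort):
    return assemble_benchmark(sim_scored, sim_techs, sim_cohort)


@pytest.fixture(scope="session")
def pathological_benchmark(sim_truth, sim_techs, sim_seed):
    """Benchmark rebuilt with one caller's ploidy systematically mis-centered."""
    models = default_caller_models(seed=sim_seed)
    models["callerF"] = dataclasses.replace(
        models["callerF"], ploidy_shift_prob=1.0, ploidy_shift_delta=2
    )
    cohort = simulate_cohort(sim_truth, models)
    mask = sim_truth.spec.mask
    scored = {
        t: score_cohort(cohort, t, mask)
        for t in (CNVType.GAIN, CNVType.LOSS, CNVType.LOH)
    }
    return cohort, assemble_benchmark(scored, sim_techs, cohort)
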
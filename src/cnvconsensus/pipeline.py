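"""End-to-end orchestration: simulate -> score -> validate -> benchmark ->
evaluate, with a serializable run configuration and deterministic outputs.

Every stage writes a plain-text TSV (or VCF) into the output directory so
each step can be inspected and regenerated independently; the effective
configuration is echoed to ``run_config.yaml`` and a run log is written
alongside the artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .callsets import CNVType, Cohort, write_benchmark_vcf, write_segments
from .evaluation import precision_recall_f1, recenter_shift
from .intervals import ExclusionMask, read_bed, write_bed
from .scoring import GroupingScheme, score_cohort, scored_to_frame
from .simulate import (
    TruthParams,
    default_caller_models,
    default_genome,
    default_orthogonal_models,
    simulate_cohort,
    simulate_orthogonal,
    simulate_truth,
)
from .validation import assemble_benchmark, validation_table

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full simulated-cohort run."""

    out_dir: str = "cnv_run"
    seed: int = 0
    use_orthogonal: bool = True
    n_technologies: int = 3
    mask_bed: Optional[str] = None  # default: the synthetic genome's own mask
    proximity: int = 10_000
    similarity: float = 0.5
    evaluate_queries: bool = True

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline on a simulated cohort; returns the output dir.

    Reruns with an identical config produce byte-identical artifacts. On
    failure, partial outputs are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: List[Path] = []
    try:
        return _run(config, out, created)
    except Exception:
        for p in created:
            if p.exists():
                p.unlink()
        raise


def _run(config: RunConfig, out: Path, created: List[Path]) -> Path:
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cnvconsensus")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    created.append(log_path)

    def emit(path: Path) -> Path:
        created.append(path)
        return path

    try:
        config.to_yaml(emit(out / "run_config.yaml"))

        spec = default_genome()
        mask = (
            ExclusionMask(read_bed(config.mask_bed), label=str(config.mask_bed))
            if config.mask_bed
            else spec.mask
        )
        truth = simulate_truth(spec, TruthParams(), seed=config.seed)
        logger.info("truth ploidy %.3f (re-centering shift %.2f)",
                    truth.overall_ploidy, recenter_shift(truth.overall_ploidy))
        write_segments(truth.to_callset(), emit(out / "truth_segments.tsv"))
        write_bed(mask.regions, emit(out / "mask.bed"))

        scheme = GroupingScheme.default()
        scheme.to_frame().to_csv(emit(out / "grouping.tsv"), sep="\t", index=False)
        models = default_caller_models(seed=config.seed)
        cohort = simulate_cohort(truth, models, scheme)
        logger.info("simulated %d call sets", len(cohort.callsets))
        cohort_dir = out / "cohort"
        cohort_dir.mkdir(exist_ok=True)
        manifest = []
        for cs in cohort.callsets:
            path = cohort_dir / f"{cs.caller}_{cs.center}_{cs.replicate}.tsv"
            write_segments(cs, emit(path))
            manifest.append(
                {"caller": cs.caller, "center": cs.center, "replicate": cs.replicate,
                 "platform": cs.platform, "path": str(path.relative_to(out))}
            )
        import pandas as pd

        pd.DataFrame(manifest).to_csv(emit(out / "manifest.tsv"), sep="\t", index=False)

        techs = []
        if config.use_orthogonal:
            tech_models = default_orthogonal_models(seed=config.seed)
            for name, model in list(tech_models.items())[: config.n_technologies]:
                tech = simulate_orthogonal(truth, model, name)
                techs.append(tech)
                write_segments(
                    # reuse the segment dialect for tech calls
                    type(cohort.callsets[0])(name, "tech", "1", "other", tech.calls),
                    emit(out / f"tech_{name}.tsv"),
                )

        scored_by_type = {}
        for cnv_type in (CNVType.GAIN, CNVType.LOSS, CNVType.LOH):
            scored = score_cohort(cohort, cnv_type, mask)
            scored_by_type[cnv_type] = scored
            scored_to_frame(scored).to_csv(
                emit(out / f"scored_{cnv_type.value.lower()}.tsv"), sep="\t", index=False
            )

        if techs:
            all_scored = [s for scored in scored_by_type.values() for s in scored]
            validation_table(all_scored, techs).to_csv(
                emit(out / "validation_table.tsv"), sep="\t", index=False,
                float_format="%.4f",
            )
        else:
            logger.info("no orthogonal technologies: validation skipped; "
                        "benchmark will contain strong-evidence intervals only")

        benchmark = assemble_benchmark(scored_by_type, techs, cohort)
        benchmark.to_frame().to_csv(
            emit(out / "benchmark.tsv"), sep="\t", index=False, float_format="%.4f"
        )
        write_benchmark_vcf(benchmark, emit(out / "benchmark.vcf"))
        logger.info("benchmark: %d intervals", len(benchmark))

        if config.evaluate_queries:
            rows = []
            for cs in cohort.callsets:
                if cs.replicate != "1":
                    continue
                for cnv_type in (CNVType.GAIN, CNVType.LOSS):
                    m = precision_recall_f1(cs, benchmark, cnv_type, mask)
                    rows.append(
                        {"caller": cs.caller, "center": cs.center,
                         "replicate": cs.replicate, "type": cnv_type.value,
                         "precision": m.precision, "recall": m.recall, "f1": m.f1}
                    )
            pd.DataFrame(rows).to_csv(
                emit(out / "metrics.tsv"), sep="\t", index=False, float_format="%.4f"
            )
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
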
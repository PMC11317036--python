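"""End-to-end experiment orchestration.

An experiment id combines a template pool letter with a primer pool size,
e.g. ``"B27"`` = template pool B (10 equimolar templates) amplified with
primer pool 27 (the 27 double-mismatch primers).  The special id ``"A+"``
runs the head-to-head grid: template ST0 amplified with the perfect-match
primer plus one single-mismatch primer at a time (V1..V9), at both
temperatures, yielding a 9 x 2 mismatch-ratio table.

``run_experiment`` executes design -> simulate -> classify -> metrics ->
report into a run directory, with every parameter and seed echoed into a
manifest so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import classify as cl
from . import metrics as mt
from . import simulate as sim
from . import stats_report as st
from .design import (
    Design,
    DEFAULT_DESIGN_SEED,
    PoolSpec,
    PRIMER_POOL_TABLE,
    TEMPLATE_POOL_TABLE,
    default_design,
    make_pool,
    write_design_fasta,
)
from .errors import PipelineError

#: Per-base substitution-rate presets for the polymerase/sequencing error
#: model, loosely anchored to measured cumulative error ranges for a
#: non-proofreading Taq without modified primers (MT-like) vs polymerases
#: used with phosphorothioate-protected primers (DT/QB-like).
ERROR_RATE_PRESETS: dict[str, float] = {
    "MT-like": 0.010,
    "DT-like": 0.004,
    "QB-like": 0.004,
}

_EXPERIMENT_RE = re.compile(r"^([A-E])(1|9|10|27|64)$")


def parse_experiment_id(experiment_id: str) -> tuple[str, str]:
    """Split e.g. 'B27' into template pool 'B' and primer pool '27'."""
    m = _EXPERIMENT_RE.match(experiment_id)
    if not m:
        raise PipelineError(
            f"cannot parse experiment id {experiment_id!r}; expected "
            "<template pool A-E><primer pool 1|9|10|27|64> or 'A+'"
        )
    return m.group(1), m.group(2)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    experiment_id: str = "A10"
    method: str = "depcr"  # "depcr" | "standard"
    temperatures: tuple[float, ...] = (45.0, 55.0)
    replicates: int = 8
    reads_per_replicate: int = 20_000
    error_rate_preset: str = "MT-like"
    classification_mode: str = "full_primer"
    scrambling_mode: str = "neutral"
    rarefaction_depth: Optional[int] = 7000
    min_mean_quality: float = 20.0
    design_seed: int = DEFAULT_DESIGN_SEED
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment_id != "A+":
            parse_experiment_id(self.experiment_id)
        if self.replicates < 1:
            raise PipelineError("replicates must be >= 1")
        if self.error_rate_preset not in ERROR_RATE_PRESETS:
            raise PipelineError(
                f"unknown error preset {self.error_rate_preset!r}; "
                f"known: {sorted(ERROR_RATE_PRESETS)}"
            )

    @property
    def per_base_error_rate(self) -> float:
        return ERROR_RATE_PRESETS[self.error_rate_preset]

    def manifest(self) -> dict:
        return {"tool": "depcrsim", **dataclasses.asdict(self)}


@dataclass
class ConditionResult:
    """One (temperature,) condition of an experiment."""

    temperature: float
    simulation: sim.SimulationResult
    matrix: cl.InteractionMatrix
    rarefied: Optional[cl.InteractionMatrix]
    metrics: pd.DataFrame


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    design: Design
    conditions: dict[float, ConditionResult]
    comparisons: list[st.GroupComparison]
    report: dict
    run_dir: Optional[Path] = None

    def metrics_table(self) -> pd.DataFrame:
        frames = []
        for temp, cond in self.conditions.items():
            df = cond.metrics.copy()
            df.insert(0, "temperature", temp)
            frames.append(df)
        return pd.concat(frames)


def _pools_for(config: ExperimentConfig) -> tuple[PoolSpec, PoolSpec]:
    tletter, psize = parse_experiment_id(config.experiment_id)
    return make_pool(tletter, TEMPLATE_POOL_TABLE), make_pool(psize, PRIMER_POOL_TABLE)


def run_condition(
    config: ExperimentConfig,
    design: Design,
    template_pool: PoolSpec,
    primer_pool: PoolSpec,
    temperature: float,
    model: Optional[sim.EfficiencyModel] = None,
    fastq_dir: Optional[Path] = None,
) -> ConditionResult:
    """Simulate, emit/classify and score one temperature condition."""
    run_cfg = sim.RunConfig(
        method=config.method,
        temperature=temperature,
        scrambling_mode=config.scrambling_mode,
        per_base_error_rate=config.per_base_error_rate,
        reads_per_replicate=config.reads_per_replicate,
        n_replicates=config.replicates,
        seed=config.seed + int(temperature),
    )
    result = sim.run_simulation(template_pool, primer_pool, run_cfg, design.space, model)
    reads_by_rep = sim.emit_reads(result, design.space, out_dir=fastq_dir)
    if fastq_dir is not None:
        reads_by_rep = {
            rep: list(cl.read_fastq(paths[0], replicate_id=rep))
            for rep, paths in reads_by_rep.items()
        }
    assignments = []
    for rep, reads in reads_by_rep.items():
        kept, _ = cl.quality_filter(reads, config.min_mean_quality)
        assignments.extend(
            cl.classify_reads(
                kept,
                design.space,
                mode=config.classification_mode,
                allowed_primers=primer_pool.members,
                allowed_templates=template_pool.members,
            )
        )
    matrix = cl.build_interaction_matrix(
        assignments,
        design.space,
        template_pool=template_pool,
        primer_pool=primer_pool,
        metadata={
            "experiment": config.experiment_id,
            "method": config.method,
            "temperature": temperature,
            "template_pool": template_pool.pool_id,
            "primer_pool": primer_pool.pool_id,
        },
    )
    rarefied = None
    scored = matrix
    if config.rarefaction_depth:
        rarefied = cl.rarefy(matrix, config.rarefaction_depth, seed=run_cfg.seed)
        scored = rarefied
    metrics = mt.replicate_metrics(scored, design.space, template_pool, primer_pool)
    return ConditionResult(temperature, result, matrix, rarefied, metrics)


def _temperature_comparisons(
    conditions: dict[float, ConditionResult]
) -> list[st.GroupComparison]:
    comps = []
    if len(conditions) != 2:
        return comps
    temps = sorted(conditions)
    for metric in ("its", "ips", "mismatch_ratio"):
        groups = {
            f"{t:g}C": tuple(conditions[t].metrics[metric].astype(float)) for t in temps
        }
        if any(any(math.isinf(v) for v in vals) for vals in groups.values()):
            continue  # Inf-sentinel metric: no finite comparison possible
        try:
            comps.append(st.compare_groups(metric, groups, test="welch_t"))
        except st.StatsError:
            continue
    return comps


def run_experiment(
    config: ExperimentConfig,
    out_dir: Optional[Union[str, Path]] = None,
    model: Optional[sim.EfficiencyModel] = None,
    design: Optional[Design] = None,
) -> ExperimentResult:
    """Execute one experiment end to end; optionally persist a run directory."""
    if config.experiment_id == "A+":
        return run_head_to_head_grid(config, out_dir=out_dir, model=model, design=design)
    design = design or default_design(seed=config.design_seed)
    template_pool, primer_pool = _pools_for(config)
    run_dir = Path(out_dir) if out_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)
        write_design_fasta(design.templates, run_dir / "templates.fasta")
        write_design_fasta(design.primers, run_dir / "primers.fasta")
        design.space.to_mapping_tsv(run_dir / "mapping.tsv")
    conditions: dict[float, ConditionResult] = {}
    for temp in config.temperatures:
        fastq_dir = run_dir / f"fastq_{temp:g}C" if run_dir is not None else None
        cond = run_condition(
            config, design, template_pool, primer_pool, temp, model, fastq_dir
        )
        conditions[temp] = cond
        if run_dir is not None:
            cond.matrix.to_tsv(run_dir / f"matrix_{temp:g}C.tsv")
            cond.matrix.to_biom_json(run_dir / f"matrix_{temp:g}C.biom.json")
            if cond.rarefied is not None:
                cond.rarefied.to_tsv(run_dir / f"matrix_{temp:g}C.rarefied.tsv")
            cond.matrix.status_counts.to_csv(
                run_dir / f"read_accounting_{temp:g}C.tsv", sep="\t"
            )
    comparisons = _temperature_comparisons(conditions)
    metrics_all = pd.concat(
        [
            c.metrics.assign(temperature=t).set_index("temperature", append=True)
            for t, c in conditions.items()
        ]
    )
    report = st.experiment_report(config.manifest(), metrics_all, comparisons)
    if run_dir is not None:
        (run_dir / "manifest.json").write_text(
            json.dumps(st._jsonable(config.manifest()), sort_keys=True, indent=2) + "\n"
        )
        st.write_report(report, run_dir / "report")
    return ExperimentResult(config, design, conditions, comparisons, report, run_dir)


def run_head_to_head_grid(
    config: ExperimentConfig,
    mismatch_primers: tuple[str, ...] = tuple(f"V{i}" for i in range(1, 10)),
    out_dir: Optional[Union[str, Path]] = None,
    model: Optional[sim.EfficiencyModel] = None,
    design: Optional[Design] = None,
) -> ExperimentResult:
    """Experiment "A+": ST0 vs (V0 + one single-mismatch primer) per reaction.

    DePCR only; produces a mismatch-ratio table over primers x temperatures
    with a Welch comparison between temperatures per primer.
    """
    design = design or default_design(seed=config.design_seed)
    template_pool = make_pool("A", TEMPLATE_POOL_TABLE)
    rows = []
    comparisons: list[st.GroupComparison] = []
    conditions: dict[float, ConditionResult] = {}
    per_primer_values: dict[str, dict[float, tuple[float, ...]]] = {}
    for vk in mismatch_primers:
        pool = PoolSpec.from_mapping(f"V0+{vk}", {"V0": 1.0, vk: 1.0})
        for temp in config.temperatures:
            cond = run_condition(
                config, design, template_pool, pool, temp, model, fastq_dir=None
            )
            ratios = tuple(cond.metrics["mismatch_ratio"].astype(float))
            per_primer_values.setdefault(vk, {})[temp] = ratios
            prof = design.space.profiles[(vk, "ST0")]
            rows.append(
                {
                    "primer": vk,
                    "position": prof.positions[0] if prof.entries else "",
                    "pairing": prof.pairings[0] if prof.entries else "",
                    "temperature": temp,
                    "mismatch_ratio_mean": sum(ratios) / len(ratios),
                }
            )
    for vk, by_temp in per_primer_values.items():
        if len(by_temp) == 2:
            groups = {f"{t:g}C": v for t, v in sorted(by_temp.items())}
            try:
                comparisons.append(
                    st.compare_groups(f"mismatch_ratio[{vk}]", groups, test="welch_t")
                )
            except st.StatsError:
                pass
    table = pd.DataFrame(rows)
    metrics = table.set_index(["primer", "temperature"])
    report = st.experiment_report(config.manifest(), metrics, comparisons)
    run_dir = Path(out_dir) if out_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(run_dir / "head_to_head.tsv", sep="\t", index=False)
        st.write_report(report, run_dir / "report")
        (run_dir / "manifest.json").write_text(
            json.dumps(st._jsonable(config.manifest()), sort_keys=True, indent=2) + "\n"
        )
    return ExperimentResult(config, design, conditions, comparisons, report, run_dir)
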
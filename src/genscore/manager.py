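"""The scoring orchestrator: config loading, per-batch pipeline, run records, benchmark mode.

The central object is :class:`Pipeline`: initialised from a JSON objective
configuration, it takes a list of SMILES per iteration and returns one score
per input, running the stages

    parse -> canonicalise -> intra-batch dedupe -> cross-batch cache lookup
          -> score -> transform -> aggregate -> multiplicative filters
          -> diversity filter -> record + CSV

Scorers run only on valid, previously unseen canonical SMILES; invalid
molecules score 0; repeats reuse the cached raw/transformed/aggregate values
(diversity penalties are *not* cached — the memory evolves, and a repeat is
by definition non-diverse, so penalisation is re-applied per evaluation).

Benchmark mode (:class:`Benchmark`) iterates over several objectives with a
shared molecule budget per objective and writes an evaluation summary on
exit.
"""

from __future__ import annotations

import copy
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd

from . import scorers as scorers_mod
from .chemio import ConfigurationError, FingerprintSpec, ParsedMolecule, parse, read_smiles_file
from .divfilter import DiversityFilterSpec, DiversityMemory, ScoredMolecule, penalise
from .shaping import (
    AggregationSpec,
    RunningRange,
    TransformSpec,
    aggregate_batch,
    transform,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "ParameterSpec",
    "ObjectiveConfig",
    "RunState",
    "Pipeline",
    "Benchmark",
    "BenchmarkSpec",
    "ConfigError",
    "load_config",
    "run_benchmark",
    "PRESETS",
]


class ConfigError(ConfigurationError):
    """Configuration failure; carries every problem found, not just the first."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))


# --------------------------------------------------------------------------
# Records

@dataclass
class MoleculeRecord:
    """Full provenance of one scored input SMILES."""

    step: int
    batch_idx: int
    input_smiles: str
    canonical_smiles: str | None
    valid: bool
    unique_in_batch: bool
    seen_before: bool
    raw: dict[str, float] = field(default_factory=dict)
    transformed: dict[str, float] = field(default_factory=dict)
    dscore: float = 0.0
    filter_product: float = 1.0
    passes_diversity: bool = True
    score: float = 0.0
    error: str | None = None


# --------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class ParameterSpec:
    """One objective parameter: a scorer output column plus its shaping."""

    source: str
    transform: TransformSpec
    weight: float = 1.0
    is_filter: bool = False


@dataclass
class ObjectiveConfig:
    """Validated, fully-resolved objective description.

    ``scorers`` holds (name, callable) pairs where each callable maps a
    valid :class:`~genscore.chemio.ParsedMolecule` to ``{metric: value}``;
    this is also the extension point for tests and custom scoring functions.
    """

    task_name: str
    output_dir: str
    scorers: list[tuple[str, Callable[[ParsedMolecule], Mapping[str, float]]]]
    parameters: list[ParameterSpec]
    aggregation: AggregationSpec = field(default_factory=AggregationSpec)
    diversity_filter: DiversityFilterSpec | None = None

    @property
    def filter_parameters(self) -> list[ParameterSpec]:
        return [p for p in self.parameters if p.is_filter]

    @property
    def objective_parameters(self) -> list[ParameterSpec]:
        return [p for p in self.parameters if not p.is_filter]


_SCORER_KINDS = (
    "descriptors",
    "penalised_logp",
    "max_consecutive_rotatable_bonds",
    "fingerprint_similarity",
    "isomer_similarity",
    "substructure_match",
    "substructure_filter",
    "applicability_domain",
    "tabulated_model",
)

_PROBE_SMILES = "CCO"


def _build_scorer(kind: str, params: Mapping[str, Any], base_dir: Path):
    if kind == "descriptors":
        names = tuple(params.get("names", scorers_mod.SUPPORTED_DESCRIPTORS))
        return scorers_mod.DescriptorScorer(names)
    if kind == "penalised_logp":
        return scorers_mod.PenalisedLogPScorer()
    if kind == "max_consecutive_rotatable_bonds":
        return scorers_mod.MaxConsecutiveRotatableBondsScorer()
    if kind == "fingerprint_similarity":
        refs = list(params.get("ref_smiles", []))
        if "ref_file" in params:
            refs.extend(read_smiles_file(base_dir / params["ref_file"]))
        spec = FingerprintSpec(
            family=params.get("family", "ECFP"),
            radius=int(params.get("radius", 2)),
            n_bits=int(params.get("n_bits", 2048)),
            counted=bool(params.get("counted", False)),
        )
        return scorers_mod.FingerprintSimilarityScorer(
            tuple(refs),
            spec=spec,
            measure=params.get("measure", "tanimoto"),
            reduce=params.get("reduce", "max"),
        )
    if kind == "isomer_similarity":
        return scorers_mod.IsomerSimilarityScorer(params["formula"])
    if kind in ("substructure_match", "substructure_filter"):
        smarts = list(params.get("smarts", []))
        if "smarts_file" in params:
            with open(base_dir / params["smarts_file"], encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if line and not line.startswith("#"):
                        smarts.append(line.split("\t")[0])
        mode = "filter" if kind == "substructure_filter" else params.get("mode", "match_any")
        return scorers_mod.SubstructureScorer(tuple(smarts), mode)
    if kind == "applicability_domain":
        if "model_file" in params:
            with open(base_dir / params["model_file"], encoding="utf-8") as fh:
                model = scorers_mod.DomainModel.from_json(fh.read())
        else:
            training = list(params.get("training_smiles", []))
            if "training_file" in params:
                training.extend(read_smiles_file(base_dir / params["training_file"]))
            model = scorers_mod.DomainModel.from_training_smiles(
                training,
                descriptor_names=tuple(
                    params.get("descriptor_names", ("MW", "logP", "TPSA", "HBD", "HBA"))
                ),
            )
        return scorers_mod.ApplicabilityScorer(
            model,
            kind=params.get("domain", "max_similarity"),
            descriptor_names=tuple(params["descriptor_names"]) if "descriptor_names" in params else None,
        )
    if kind == "tabulated_model":
        return scorers_mod.TabulatedModelScorer(
            table=dict(params["table"]), default=float(params.get("default", 0.0))
        )
    raise ConfigurationError(f"unknown scorer kind {kind!r}")


def _transform_spec_from_dict(data: Mapping[str, Any]) -> TransformSpec:
    allowed = {"kind", "direction", "threshold", "buffer", "mu", "sigma", "low", "high"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown transform keys {sorted(unknown)}")
    return TransformSpec(**data)


def load_config(source: str | os.PathLike | Mapping[str, Any]) -> ObjectiveConfig:
    """Load and validate a JSON objective configuration.

    Every problem found is reported at once, each prefixed with the JSON
    path of the offending entry.
    """
    if isinstance(source, (str, os.PathLike)):
        base_dir = Path(source).resolve().parent
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        base_dir = Path.cwd()
        data = dict(source)

    problems: list[str] = []
    known_top = {
        "task_name", "output_dir", "scorers", "parameters",
        "aggregation", "diversity_filter", "filters",
    }
    for key in set(data) - known_top:
        problems.append(f"$.{key}: unknown key")

    task_name = data.get("task_name")
    if not task_name or not isinstance(task_name, str):
        problems.append("$.task_name: required nonempty string")
        task_name = "unnamed"
    output_dir = data.get("output_dir", task_name)

    built_scorers: list[tuple[str, Any]] = []
    columns: list[str] = []
    names_seen: set[str] = set()
    probe = parse(_PROBE_SMILES)
    for i, entry in enumerate(data.get("scorers", []) or []):
        path = f"$.scorers[{i}]"
        name = entry.get("name")
        kind = entry.get("kind")
        if not name:
            problems.append(f"{path}.name: required")
            continue
        if name in names_seen:
            problems.append(f"{path}.name: duplicate scorer name {name!r}")
            continue
        names_seen.add(name)
        if kind not in _SCORER_KINDS:
            problems.append(f"{path}.kind: unknown kind {kind!r}; choose from {_SCORER_KINDS}")
            continue
        try:
            scorer = _build_scorer(kind, entry.get("params", {}), base_dir)
            metrics = scorer(probe)
        except ConfigurationError as exc:
            problems.append(f"{path}: {exc}")
            continue
        except Exception as exc:  # bad files, etc.
            problems.append(f"{path}: {type(exc).__name__}: {exc}")
            continue
        built_scorers.append((name, scorer))
        columns.extend(f"{name}_{metric}" for metric in metrics)
    if not built_scorers and not problems:
        problems.append("$.scorers: at least one scorer is required")

    filter_names = set(data.get("filters", []) or [])
    parameters: list[ParameterSpec] = []
    for i, entry in enumerate(data.get("parameters", []) or []):
        path = f"$.parameters[{i}]"
        source_col = entry.get("source")
        if not source_col:
            problems.append(f"{path}.source: required")
            continue
        if source_col not in columns:
            problems.append(
                f"{path}.source: {source_col!r} is not produced by any scorer "
                f"(available: {columns})"
            )
            continue
        try:
            tspec = _transform_spec_from_dict(entry.get("transform", {"kind": "identity"}))
        except ConfigurationError as exc:
            problems.append(f"{path}.transform: {exc}")
            continue
        parameters.append(
            ParameterSpec(
                source=source_col,
                transform=tspec,
                weight=float(entry.get("weight", 1.0)),
                is_filter=bool(entry.get("filter", False)) or source_col in filter_names,
            )
        )
    for name in filter_names - {p.source for p in parameters}:
        problems.append(f"$.filters: {name!r} does not name a configured parameter")
    if not parameters and not problems:
        problems.append("$.parameters: at least one parameter is required")

    agg_data = dict(data.get("aggregation", {"kind": "amean"}))
    try:
        if agg_data.get("kind") in ("wsum", "wprod") and "weights" not in agg_data:
            agg_data["weights"] = {
                p.source: p.weight for p in parameters if not p.is_filter
            }
        aggregation = AggregationSpec(
            kind=agg_data.get("kind", "amean"), weights=agg_data.get("weights", {})
        )
    except ConfigurationError as exc:
        problems.append(f"$.aggregation: {exc}")
        aggregation = AggregationSpec()

    div_spec = None
    if data.get("diversity_filter"):
        try:
            div_spec = DiversityFilterSpec(**data["diversity_filter"])
        except (ConfigurationError, TypeError) as exc:
            problems.append(f"$.diversity_filter: {exc}")

    if problems:
        raise ConfigError(problems)
    return ObjectiveConfig(
        task_name=task_name,
        output_dir=str(output_dir),
        scorers=built_scorers,
        parameters=parameters,
        aggregation=aggregation,
        diversity_filter=div_spec,
    )


# --------------------------------------------------------------------------
# Run state and pipeline

@dataclass
class _CachedResult:
    raw: dict[str, float]
    transformed: dict[str, float]
    dscore: float
    filter_product: float
    error: str | None = None


@dataclass
class RunState:
    cache: dict[str, _CachedResult] = field(default_factory=dict)
    range_states: dict[str, RunningRange] = field(default_factory=dict)
    memory: DiversityMemory = field(default_factory=DiversityMemory)
    records: list[MoleculeRecord] = field(default_factory=list)
    step: int = 0


class Pipeline:
    """Objective scoring pipeline for iterative molecule generation.

    Parameters
    ----------
    config
        An :class:`ObjectiveConfig`, a path to a JSON configuration file, or
        a configuration mapping.
    map_fn
        Order-preserving map used to evaluate scorers over a batch; swap in
        e.g. a multiprocessing pool map for parallel scoring.  Results must
        be identical to serial execution (scorers are pure functions).
    write_csv
        Write per-iteration CSVs under ``output_dir/iterations`` and the
        final ``scores.csv`` on :meth:`finalize`.
    """

    def __init__(
        self,
        config: ObjectiveConfig | str | os.PathLike | Mapping[str, Any],
        map_fn: Callable[..., Iterable] = map,
        write_csv: bool = True,
    ):
        if not isinstance(config, ObjectiveConfig):
            config = load_config(config)
        self.config = config
        self.map_fn = map_fn
        self.write_csv = write_csv
        self.state = RunState()
        for p in config.parameters:
            if p.transform.kind == "normalise":
                self.state.range_states[p.source] = RunningRange()
        self._out_dir = Path(config.output_dir)
        if self.write_csv:
            (self._out_dir / "iterations").mkdir(parents=True, exist_ok=True)

    # -- scoring ----------------------------------------------------------
    def score(self, smiles: Sequence[str], step: int | None = None) -> list[float]:
        """Score a batch; returns one final score per input, in input order."""
        if step is None:
            self.state.step += 1
            step = self.state.step
        else:
            self.state.step = step

        records: list[MoleculeRecord] = []
        first_idx: dict[str, int] = {}
        to_evaluate: list[ParsedMolecule] = []
        for i, smi in enumerate(smiles):
            mol = parse(smi)
            can = mol.canonical_smiles
            rec = MoleculeRecord(
                step=step,
                batch_idx=i,
                input_smiles=smi if isinstance(smi, str) else "",
                canonical_smiles=can,
                valid=mol.valid,
                unique_in_batch=can not in first_idx if can else True,
                seen_before=can in self.state.cache if can else False,
            )
            records.append(rec)
            if mol.valid:
                if can not in first_idx:
                    first_idx[can] = i
                    if can not in self.state.cache:
                        to_evaluate.append(mol)
            rec._mol = mol  # transient, for the diversity filter
        # evaluate scorers on distinct, valid, unseen molecules
        for mol, result in zip(to_evaluate, self.map_fn(self._evaluate_one, to_evaluate)):
            self.state.cache[mol.canonical_smiles] = result

        # assemble per-record values from the cache
        for rec in records:
            if not rec.valid:
                rec.score = 0.0
                rec.dscore = 0.0
                continue
            cached = self.state.cache[rec.canonical_smiles]
            rec.raw = dict(cached.raw)
            rec.transformed = dict(cached.transformed)
            rec.dscore = cached.dscore
            rec.filter_product = cached.filter_product
            rec.error = cached.error

        # pareto aggregation is batch-wise and cannot be cached
        if self.config.aggregation.kind == "pareto":
            valid_recs = [r for r in records if r.valid and r.error is None]
            maps = [
                {p.source: r.transformed.get(p.source, 0.0) for p in self.config.objective_parameters}
                for r in valid_recs
            ]
            if maps:
                for r, v in zip(valid_recs, aggregate_batch(maps, self.config.aggregation)):
                    r.dscore = v

        # desirability x filters, then the diversity filter over the batch
        pre_filter = [
            0.0 if (not r.valid or r.error is not None) else r.dscore * r.filter_product
            for r in records
        ]
        if self.config.diversity_filter is not None:
            scored = [
                ScoredMolecule(mol=r._mol, score=s) for r, s in zip(records, pre_filter)
            ]
            finals = penalise(scored, self.config.diversity_filter, self.state.memory)
        else:
            finals = pre_filter
        for rec, pre, final in zip(records, pre_filter, finals):
            rec.score = final
            rec.passes_diversity = final == pre
            del rec._mol

        self.state.records.extend(records)
        if self.write_csv:
            self._write_iteration_csv(step, records)
        return [r.score for r in records]

    # callable handed to map_fn; must stay order-preserving and pure
    def _evaluate_one(self, mol: ParsedMolecule) -> _CachedResult:
        raw: dict[str, float] = {}
        error: str | None = None
        for name, scorer in self.config.scorers:
            try:
                for metric, value in scorer(mol).items():
                    raw[f"{name}_{metric}"] = float(value)
            except Exception as exc:
                error = f"{name}: {type(exc).__name__}: {exc}"
                logger.warning("scorer %s failed on %s: %s", name, mol.canonical_smiles, exc)
        transformed: dict[str, float] = {}
        for p in self.config.parameters:
            x = raw.get(p.source, math.nan)
            transformed[p.source] = transform(
                x, p.transform, self.state.range_states.get(p.source)
            )
        if error is not None:
            return _CachedResult(raw, transformed, 0.0, 1.0, error)
        obj = {p.source: transformed[p.source] for p in self.config.objective_parameters}
        if self.config.aggregation.kind == "pareto":
            dscore = 0.0  # filled in batch-wise by score()
        else:
            dscore = aggregate_batch([obj], self.config.aggregation)[0] if obj else 0.0
        fprod = 1.0
        for p in self.config.filter_parameters:
            fprod *= transformed[p.source]
        return _CachedResult(raw, transformed, dscore, fprod)

    # -- output -----------------------------------------------------------
    @property
    def columns(self) -> list[str]:
        raw_cols: list[str] = []
        for rec in self.state.records:
            for c in rec.raw:
                if c not in raw_cols:
                    raw_cols.append(c)
        if not raw_cols:
            raw_cols = [p.source for p in self.config.parameters]
        tr_cols = [f"{p.source}_transformed" for p in self.config.parameters]
        return (
            ["step", "batch_idx", "input_smiles", "canonical_smiles", "valid",
             "unique_in_batch", "seen_before"]
            + raw_cols
            + tr_cols
            + ["dscore", "filter_product", "passes_diversity", "score", "error"]
        )

    def _records_frame(self, records: Sequence[MoleculeRecord]) -> pd.DataFrame:
        cols = self.columns
        rows = []
        for r in records:
            row: dict[str, Any] = {
                "step": r.step,
                "batch_idx": r.batch_idx,
                "input_smiles": r.input_smiles,
                "canonical_smiles": r.canonical_smiles or "",
                "valid": r.valid,
                "unique_in_batch": r.unique_in_batch,
                "seen_before": r.seen_before,
                "dscore": r.dscore,
                "filter_product": r.filter_product,
                "passes_diversity": r.passes_diversity,
                "score": r.score,
                "error": r.error or "",
            }
            row.update(r.raw)
            row.update({f"{k}_transformed": v for k, v in r.transformed.items()})
            rows.append(row)
        return pd.DataFrame(rows, columns=cols)

    def _write_iteration_csv(self, step: int, records: Sequence[MoleculeRecord]) -> None:
        path = self._out_dir / "iterations" / f"step_{step:06d}.csv"
        self._records_frame(records).to_csv(path, index=False)

    def finalize(self) -> Path:
        """Write the full run record to ``output_dir/scores.csv`` and return its path."""
        self._out_dir.mkdir(parents=True, exist_ok=True)
        path = self._out_dir / "scores.csv"
        self._records_frame(self.state.records).to_csv(path, index=False)
        if self.config.diversity_filter is not None:
            self.state.memory.to_csv(self._out_dir / "diversity_memory.csv")
        return path

    @property
    def n_evaluated(self) -> int:
        return len(self.state.records)


# --------------------------------------------------------------------------
# Benchmark mode

#: registry of named benchmark presets: name -> callable() -> list of config
#: mappings/ObjectiveConfig.  The bundled "demo" preset is registered by
#: :mod:`genscore.fixtures` on import.
PRESETS: dict[str, Callable[[], list]] = {}


@dataclass
class BenchmarkSpec:
    """A benchmark: a preset name or explicit configs, plus a per-objective budget."""

    objectives: str | Sequence[ObjectiveConfig | str | Mapping[str, Any]]
    budget: int = 1000
    output_dir: str = "benchmark"

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ConfigurationError("budget must be >= 1")


class _Task:
    """One objective inside a benchmark; ``finished`` flips at the budget."""

    def __init__(self, pipeline: Pipeline, budget: int):
        self.pipeline = pipeline
        self.budget = budget

    @property
    def name(self) -> str:
        return self.pipeline.config.task_name

    @property
    def finished(self) -> bool:
        return self.pipeline.n_evaluated >= self.budget

    def score(self, smiles: Sequence[str], step: int | None = None) -> list[float]:
        return self.pipeline.score(smiles, step=step)


def _resolve_objectives(spec: BenchmarkSpec) -> list[ObjectiveConfig]:
    objectives = spec.objectives
    if isinstance(objectives, str):
        if objectives not in PRESETS:
            from . import fixtures  # registers bundled presets  # noqa: F401
        if objectives not in PRESETS:
            raise ConfigurationError(
                f"unknown benchmark preset {objectives!r}; available: {sorted(PRESETS)}"
            )
        objectives = PRESETS[objectives]()
    configs = []
    for obj in objectives:
        configs.append(obj if isinstance(obj, ObjectiveConfig) else load_config(obj))
    if not configs:
        raise ConfigurationError("benchmark requires at least one objective")
    return configs


class Benchmark:
    """Iterate over objectives, each budgeted; metrics + summary written on exit.

    Usage::

        with Benchmark(spec) as bench:
            for task in bench:
                while not task.finished:
                    smiles = my_generator.sample(...)
                    scores = task.score(smiles)
    """

    def __init__(self, spec: BenchmarkSpec, write_csv: bool = True):
        self.spec = spec
        self.write_csv = write_csv
        self._configs = _resolve_objectives(spec)
        self.tasks: list[_Task] = []
        root = Path(spec.output_dir)
        for cfg in self._configs:
            cfg = replace_output_dir(cfg, str(root / cfg.task_name))
            self.tasks.append(_Task(Pipeline(cfg, write_csv=write_csv), spec.budget))
        self.summary: pd.DataFrame | None = None

    def __iter__(self) -> Iterator[_Task]:
        return iter(self.tasks)

    def __enter__(self) -> "Benchmark":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.close()

    def close(self) -> pd.DataFrame:
        """Finalise every objective, compute evaluation metrics, write the summary."""
        from .metrics import intrinsic_metrics  # local import; metrics is heavier

        rows = []
        for task in self.tasks:
            if self.write_csv:
                task.pipeline.finalize()
            records = task.pipeline.state.records
            scores = [r.score for r in records]
            gen = [r.input_smiles for r in records]
            row: dict[str, Any] = {
                "task": task.name,
                "n_evaluated": len(records),
                "finished": task.finished,
                "mean_score": float(pd.Series(scores).mean()) if scores else math.nan,
                "max_score": max(scores) if scores else math.nan,
            }
            if gen:
                row.update(intrinsic_metrics(gen, sample_n=1000, seed=0))
            rows.append(row)
        self.summary = pd.DataFrame(rows)
        if self.write_csv:
            root = Path(self.spec.output_dir)
            root.mkdir(parents=True, exist_ok=True)
            self.summary.to_csv(root / "benchmark_summary.csv", index=False)
        return self.summary


def replace_output_dir(config: ObjectiveConfig, output_dir: str) -> ObjectiveConfig:
    cfg = copy.copy(config)
    cfg.output_dir = output_dir
    return cfg


def run_benchmark(
    spec: BenchmarkSpec,
    optimizer_factory: Callable[[ObjectiveConfig, int], Any],
    batch_size: int = 32,
    seed: int = 0,
    write_csv: bool = True,
) -> pd.DataFrame:
    """Drive every benchmark objective with a generator until its budget is spent.

    ``optimizer_factory(config, seed)`` must return an object with
    ``propose(k) -> list[str]`` and ``update(smiles, scores)`` (the contract
    the bundled pool optimizer implements).
    """
    with Benchmark(spec, write_csv=write_csv) as bench:
        for i, task in enumerate(bench):
            optimizer = optimizer_factory(task.pipeline.config, seed + i)
            while not task.finished:
                batch = optimizer.propose(batch_size)
                scores = task.score(batch)
                optimizer.update(batch, scores)
    return bench.summary
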
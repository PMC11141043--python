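"""Pipeline orchestration: config loading, caching, CSV output, benchmark mode."""

import json

import pandas as pd
import pytest

from genscore.chemio import parse
from genscore.manager import (
    Benchmark,
    BenchmarkSpec,
    ConfigError,
    ObjectiveConfig,
    ParameterSpec,
    Pipeline,
    load_config,
    run_benchmark,
)
from genscore.shaping import AggregationSpec, TransformSpec


class CountingScorer:
    """Descriptor-like scorer that counts how often it is invoked."""

    def __init__(self):
        self.calls = 0

    def __call__(self, mol):
        self.calls += 1
        return {"heavy": float(mol.mol.GetNumHeavyAtoms())}


def _counting_config(tmp_path, diversity=None, name="count_task"):
    scorer = CountingScorer()
    config = ObjectiveConfig(
        task_name=name,
        output_dir=str(tmp_path / name),
        scorers=[("cnt", scorer)],
        parameters=[
            ParameterSpec(
                source="cnt_heavy",
                transform=TransformSpec(kind="linear_threshold", direction="maximize", threshold=10.0, buffer=10.0),
            )
        ],
        aggregation=AggregationSpec(kind="amean"),
        diversity_filter=diversity,
    )
    return config, scorer


MINIMAL = {
    "task_name": "minimal",
    "output_dir": "out",
    "scorers": [{"name": "d", "kind": "descriptors", "params": {"names": ["MW"]}}],
    "parameters": [{"source": "d_MW", "transform": {"kind": "identity"}}],
    "aggregation": {"kind": "amean"},
}


class TestLoadConfig:
    def test_minimal_config_loads(self):
        config = load_config(MINIMAL)
        assert config.task_name == "minimal"
        assert [name for name, _ in config.scorers] == ["d"]

    def test_json_file_round_trip(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps(MINIMAL))
        assert load_config(path).task_name == "minimal"

    def test_unknown_parameter_source_named_in_error(self):
        bad = dict(MINIMAL, parameters=[{"source": "ghost_col", "transform": {"kind": "identity"}}])
        with pytest.raises(ConfigError, match="ghost_col"):
            load_config(bad)

    def test_all_problems_reported_at_once(self):
        bad = dict(
            MINIMAL,
            scorers=[
                {"name": "s", "kind": "substructure_match", "params": {"smarts": ["[[["]}},
                {"name": "t", "kind": "teleport"},
            ],
            parameters=[{"source": "nope", "transform": {"kind": "identity"}}],
            extra_key=1,
        )
        with pytest.raises(ConfigError) as err:
            load_config(bad)
        assert len(err.value.problems) >= 4

    def test_duplicate_scorer_names_rejected(self):
        bad = dict(MINIMAL, scorers=MINIMAL["scorers"] * 2)
        with pytest.raises(ConfigError, match="duplicate"):
            load_config(bad)


BBB_CONFIG = {
    "task_name": "bbb",
    "output_dir": "bbb",
    "scorers": [
        {"name": "phys", "kind": "descriptors", "params": {"names": ["TPSA", "HBD", "logP", "MW"]}}
    ],
    "parameters": [
        {"source": "phys_TPSA", "transform": {"kind": "step_threshold", "direction": "minimize", "high": 70}},
        {"source": "phys_HBD", "transform": {"kind": "step_threshold", "direction": "minimize", "high": 1}},
        {"source": "phys_logP", "transform": {"kind": "step_threshold", "direction": "range", "low": 2, "high": 4}},
        {"source": "phys_MW", "transform": {"kind": "step_threshold", "direction": "minimize", "high": 400}},
    ],
    "aggregation": {"kind": "amean"},
}

# a polyol chain: TPSA >> 70, many donors, strongly negative logP, MW > 400
BBB_VIOLATOR = "OCC(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)CO"


class TestScoreBatch:
    def test_output_length_and_invalid_zero(self, tmp_path):
        config, _ = _counting_config(tmp_path)
        pipe = Pipeline(config, write_csv=False)
        scores = pipe.score(["CCO", "not_a_smiles", "c1ccccc1"])
        assert len(scores) == 3
        assert scores[1] == 0.0
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_intra_batch_dedupe_scores_once(self, tmp_path):
        config, scorer = _counting_config(tmp_path)
        pipe = Pipeline(config, write_csv=False)
        scores = pipe.score(["CCO", "OCC", "CCO"])
        assert scorer.calls == 1
        assert scores[0] == scores[1] == scores[2]

    def test_cross_batch_cache_reuse(self, tmp_path):
        config, scorer = _counting_config(tmp_path)
        pipe = Pipeline(config, write_csv=False)
        first = pipe.score(["CCO", "CCN"])
        calls_after_step1 = scorer.calls
        second = pipe.score(["CCO", "CCN"])
        assert scorer.calls == calls_after_step1 == 2
        assert first == second
        assert all(r.seen_before for r in pipe.state.records[2:])

    def test_scorer_calls_equal_distinct_valid_unseen(self, tmp_path, mixed_library):
        config, scorer = _counting_config(tmp_path)
        pipe = Pipeline(config, write_csv=False)
        batch = list(mixed_library.smiles)
        pipe.score(batch)
        pipe.score(batch)  # full repeat: no further calls
        distinct = {parse(s).canonical_smiles for s in batch if parse(s).valid}
        assert scorer.calls == len(distinct)

    def test_steps_count_up_from_one(self, tmp_path):
        config, _ = _counting_config(tmp_path)
        pipe = Pipeline(config, write_csv=False)
        pipe.score(["CCO"])
        pipe.score(["CCN"])
        assert [r.step for r in pipe.state.records] == [1, 2]
        pipe.score(["CCC"], step=10)
        assert pipe.state.records[-1].step == 10

    def test_scorer_exception_is_per_molecule(self, tmp_path):
        class Flaky:
            def __call__(self, mol):
                if mol.canonical_smiles == "CCO":
                    raise RuntimeError("boom")
                return {"v": 1.0}

        config = ObjectiveConfig(
            task_name="flaky",
            output_dir=str(tmp_path / "flaky"),
            scorers=[("f", Flaky())],
            parameters=[ParameterSpec(source="f_v", transform=TransformSpec(kind="identity"))],
        )
        pipe = Pipeline(config, write_csv=False)
        scores = pipe.score(["CCO", "CCN"])
        assert scores[0] == 0.0
        assert scores[1] == 1.0
        assert pipe.state.records[0].error is not None

    def test_filter_parameter_multiplies_score(self, tmp_path):
        config = load_config(
            {
                "task_name": "filtered",
                "output_dir": str(tmp_path / "filtered"),
                "scorers": [
                    {"name": "d", "kind": "descriptors", "params": {"names": ["QED"]}},
                    {"name": "alerts", "kind": "substructure_filter", "params": {"smarts": ["[OX2H]"]}},
                ],
                "parameters": [
                    {"source": "d_QED", "transform": {"kind": "identity"}},
                    {"source": "alerts_substructure", "transform": {"kind": "identity"}, "filter": True},
                ],
                "aggregation": {"kind": "amean"},
            }
        )
        pipe = Pipeline(config, write_csv=False)
        scores = pipe.score(["CCO", "CCC"])  # hydroxyl alert hits ethanol
        assert scores[0] == 0.0
        assert scores[1] > 0.0
        assert pipe.state.records[1].dscore == pytest.approx(scores[1])

    def test_serial_and_parallel_map_identical(self, tmp_path, library):
        from multiprocessing.pool import ThreadPool

        batch = list(library.smiles[:40])
        config_a, _ = _counting_config(tmp_path, name="serial")
        serial = Pipeline(config_a, write_csv=False)
        serial_scores = serial.score(batch)
        with ThreadPool(4) as pool:
            config_b, _ = _counting_config(tmp_path, name="parallel")
            parallel = Pipeline(config_b, map_fn=pool.map, write_csv=False)
            parallel_scores = parallel.score(batch)
        assert serial_scores == parallel_scores

    def test_pareto_aggregation_batchwise(self, tmp_path):
        config = load_config(
            {
                "task_name": "pareto",
                "output_dir": str(tmp_path / "pareto"),
                "scorers": [
                    {"name": "d", "kind": "descriptors", "params": {"names": ["MW", "logP"]}}
                ],
                "parameters": [
                    {"source": "d_MW", "transform": {"kind": "linear_threshold", "direction": "minimize", "threshold": 50, "buffer": 100}},
                    {"source": "d_logP", "transform": {"kind": "linear_threshold", "direction": "maximize", "threshold": 3, "buffer": 6}},
                ],
                "aggregation": {"kind": "pareto"},
            }
        )
        pipe = Pipeline(config, write_csv=False)
        scores = pipe.score(["CCO", "CCCCCCCCCC", "c1ccccc1", "bad_smiles"])
        assert scores[3] == 0.0
        assert max(scores[:3]) == 1.0


class TestBBBConfig:
    def test_loads_and_scores_fixture_batch(self, tmp_path, library):
        config = load_config(dict(BBB_CONFIG, output_dir=str(tmp_path / "bbb")))
        pipe = Pipeline(config, write_csv=False)
        scores = pipe.score(list(library.smiles[:20]))
        assert len(scores) == 20
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_molecule_violating_all_windows_scores_zero(self, tmp_path):
        config = load_config(dict(BBB_CONFIG, output_dir=str(tmp_path / "bbb2")))
        pipe = Pipeline(config, write_csv=False)
        assert pipe.score([BBB_VIOLATOR]) == [0.0]

    def test_molecule_inside_all_windows_scores_one(self, tmp_path):
        config = load_config(dict(BBB_CONFIG, output_dir=str(tmp_path / "bbb3")))
        pipe = Pipeline(config, write_csv=False)
        # bibenzyl: TPSA 0, no donors, logP ~3.5, MW 182 -- inside every window
        [score] = pipe.score(["c1ccc(CCc2ccccc2)cc1"])
        assert score == 1.0


class TestOutputs:
    def test_row_conservation_and_iteration_csvs(self, tmp_path):
        config, _ = _counting_config(tmp_path)
        pipe = Pipeline(config)
        for batch in (["CCO", "CCN"], ["CCC", "bad"], ["CCO"]):
            pipe.score(batch)
        path = pipe.finalize()
        frame = pd.read_csv(path)
        assert len(frame) == 5
        iterations = sorted((tmp_path / "count_task" / "iterations").glob("step_*.csv"))
        assert [p.name for p in iterations] == ["step_000001.csv", "step_000002.csv", "step_000003.csv"]

    def test_zero_batches_header_only(self, tmp_path):
        config, _ = _counting_config(tmp_path, name="empty")
        pipe = Pipeline(config)
        frame = pd.read_csv(pipe.finalize())
        assert len(frame) == 0
        assert "score" in frame.columns

    def test_replay_score_column_byte_identical(self, tmp_path, mixed_library):
        batches = [list(mixed_library.smiles[i : i + 25]) for i in range(0, 100, 25)]

        def run(name):
            config, _ = _counting_config(tmp_path, name=name)
            pipe = Pipeline(config)
            for batch in batches:
                pipe.score(batch)
            return pd.read_csv(pipe.finalize(), dtype=str)["score"]

        assert run("replay_a").tolist() == run("replay_b").tolist()


class TestBenchmark:
    def _configs(self, tmp_path):
        return [
            dict(MINIMAL, task_name="obj_a", output_dir="obj_a"),
            dict(MINIMAL, task_name="obj_b", output_dir="obj_b"),
        ]

    def test_budget_flips_finished_flag(self, tmp_path, library):
        spec = BenchmarkSpec(objectives=[dict(MINIMAL)], budget=100, output_dir=str(tmp_path / "b"))
        with Benchmark(spec, write_csv=False) as bench:
            task = bench.tasks[0]
            batches = 0
            while not task.finished:
                task.score(list(library.smiles[:32]))
                batches += 1
            assert batches == 4
            assert task.pipeline.n_evaluated == 128

    def test_two_objectives_two_dirs_two_summary_rows(self, tmp_path, library):
        spec = BenchmarkSpec(
            objectives=self._configs(tmp_path), budget=50, output_dir=str(tmp_path / "bench")
        )
        with Benchmark(spec) as bench:
            for task in bench:
                while not task.finished:
                    task.score(list(library.smiles[:32]))
        assert (tmp_path / "bench" / "obj_a" / "scores.csv").exists()
        assert (tmp_path / "bench" / "obj_b" / "scores.csv").exists()
        summary = pd.read_csv(tmp_path / "bench" / "benchmark_summary.csv")
        assert len(summary) == 2
        assert set(summary["task"]) == {"obj_a", "obj_b"}
        assert summary["finished"].all()

    def test_empty_benchmark_rejected(self, tmp_path):
        with pytest.raises(Exception):
            Benchmark(BenchmarkSpec(objectives=[], budget=10, output_dir=str(tmp_path)))

    def test_run_benchmark_with_pool_optimizer(self, tmp_path):
        from genscore.fixtures import PoolOptimizer, make_library

        def factory(config, seed):
            pool = make_library(100, seed=seed)
            return PoolOptimizer(pool.smiles, seed=seed)

        spec = BenchmarkSpec(objectives="demo", budget=64, output_dir=str(tmp_path / "demo"))
        summary = run_benchmark(spec, factory, batch_size=32, write_csv=False)
        assert len(summary) == 2
        assert (summary["n_evaluated"] >= 64).all()
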
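"""Transformation and aggregation algebra."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genscore.chemio import ConfigurationError
from genscore.shaping import (
    AUTO_WEIGHT_EPS,
    AggregationSpec,
    RunningRange,
    TransformSpec,
    aggregate,
    aggregate_batch,
    pareto_front_ranks,
    reset_range,
    transform,
)


class TestTransforms:
    def test_gaussian_peak_and_inflection(self):
        spec = TransformSpec(kind="gaussian_threshold", direction="range", mu=5.0, sigma=2.0)
        assert transform(5.0, spec) == pytest.approx(1.0, abs=1e-12)
        assert transform(7.0, spec) == pytest.approx(math.exp(-0.5), abs=1e-12)
        assert transform(3.0, spec) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_gaussian_one_sided(self):
        spec = TransformSpec(kind="gaussian_threshold", direction="maximize", mu=5.0, sigma=1.0)
        assert transform(9.0, spec) == 1.0
        assert transform(4.0, spec) == pytest.approx(math.exp(-0.5))

    def test_linear_ramp_midpoint(self):
        spec = TransformSpec(kind="linear_threshold", direction="maximize", threshold=10.0, buffer=4.0)
        assert transform(8.0, spec) == pytest.approx(0.5)
        assert transform(10.0, spec) == 1.0
        assert transform(6.0, spec) == 0.0

    def test_linear_minimize_mirrored(self):
        spec = TransformSpec(kind="linear_threshold", direction="minimize", threshold=10.0, buffer=4.0)
        assert transform(10.0, spec) == 1.0
        assert transform(12.0, spec) == pytest.approx(0.5)
        assert transform(14.0, spec) == 0.0

    def test_step_window(self):
        # a "logP between 2 and 4" style window
        spec = TransformSpec(kind="step_threshold", direction="range", low=2.0, high=4.0)
        assert transform(3.0, spec) == 1.0
        assert transform(5.0, spec) == 0.0
        assert transform(2.0, spec) == 1.0

    def test_non_finite_scored_zero(self):
        spec = TransformSpec(kind="identity")
        assert transform(math.nan, spec) == 0.0
        assert transform(math.inf, spec) == 0.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            TransformSpec(kind="linear_threshold", threshold=1.0, buffer=0.0)
        with pytest.raises(ConfigurationError):
            TransformSpec(kind="gaussian_threshold", mu=0.0, sigma=-1.0)
        with pytest.raises(ConfigurationError):
            TransformSpec(kind="step_threshold", low=4.0, high=2.0)
        with pytest.raises(ConfigurationError):
            TransformSpec(kind="sigmoid")

    @settings(max_examples=300, derandomize=True)
    @given(
        x=st.floats(-1e6, 1e6),
        thr=st.floats(-100, 100),
        buf=st.floats(0.1, 100),
        sigma=st.floats(0.1, 100),
        direction=st.sampled_from(["maximize", "minimize"]),
    )
    def test_codomain_property(self, x, thr, buf, sigma, direction):
        """Every transform maps any finite real into [0, 1]."""
        specs = [
            TransformSpec(kind="linear_threshold", direction=direction, threshold=thr, buffer=buf),
            TransformSpec(kind="gaussian_threshold", direction=direction, mu=thr, sigma=sigma),
            TransformSpec(kind="step_threshold", direction=direction, low=min(thr, thr + buf), high=max(thr, thr + buf)),
            TransformSpec(kind="identity"),
        ]
        for spec in specs:
            assert 0.0 <= transform(x, spec) <= 1.0

    @settings(max_examples=100, derandomize=True)
    @given(
        xs=st.lists(st.floats(-100, 100), min_size=2, max_size=2),
        thr=st.floats(-50, 50),
        buf=st.floats(0.5, 10),
    )
    def test_linear_monotone(self, xs, thr, buf):
        lo, hi = min(xs), max(xs)
        up = TransformSpec(kind="linear_threshold", direction="maximize", threshold=thr, buffer=buf)
        down = TransformSpec(kind="linear_threshold", direction="minimize", threshold=thr, buffer=buf)
        assert transform(lo, up) <= transform(hi, up) + 1e-12
        assert transform(lo, down) >= transform(hi, down) - 1e-12


class TestRunningRange:
    def test_first_observation_is_neutral(self):
        spec = TransformSpec(kind="normalise", direction="maximize")
        state = RunningRange()
        assert transform(3.7, spec, state) == 0.5

    def test_running_extremes(self):
        spec = TransformSpec(kind="normalise", direction="maximize")
        state = RunningRange()
        transform(2.0, spec, state)
        assert transform(4.0, spec, state) == 1.0

    def test_minimize_inverts(self):
        spec = TransformSpec(kind="normalise", direction="minimize")
        state = RunningRange()
        transform(4.0, spec, state)
        assert transform(2.0, spec, state) == 1.0

    def test_reset_and_replay_determinism(self):
        spec = TransformSpec(kind="normalise", direction="maximize")
        state = RunningRange()
        seq = [5.0, 1.0, 3.0, 9.0, 3.0]
        first = [transform(x, spec, state) for x in seq]
        reset_range(state)
        assert state.count == 0
        second = [transform(x, spec, state) for x in seq]
        assert first == second

    def test_missing_state_is_config_error(self):
        with pytest.raises(ConfigurationError):
            transform(1.0, TransformSpec(kind="normalise"))


def _brute_force_fronts(points):
    """Independent O(n^2) oracle: peel non-dominated layers by scanning."""

    def dominated(p, q):  # q dominates p
        return all(b >= a for a, b in zip(p, q)) and any(b > a for a, b in zip(p, q))

    remaining = list(range(len(points)))
    ranks = [0] * len(points)
    front = 1
    while remaining:
        layer = [
            i
            for i in remaining
            if not any(dominated(points[i], points[j]) for j in remaining if j != i)
        ]
        for i in layer:
            ranks[i] = front
        remaining = [i for i in remaining if i not in layer]
        front += 1
    return ranks


class TestAggregation:
    def test_weighted_sum_hand_formula(self):
        spec = AggregationSpec(kind="wsum", weights={"a": 2, "b": 1, "c": 1})
        assert aggregate({"a": 0.5, "b": 1.0, "c": 0.0}, spec) == pytest.approx(0.5)

    def test_amean_is_unit_weight_wsum(self):
        scores = {"a": 0.2, "b": 0.8, "c": 0.5}
        assert aggregate(scores, AggregationSpec(kind="amean")) == pytest.approx(0.5)

    def test_zero_annihilates_products(self):
        scores = {"a": 0.9, "b": 0.0, "c": 0.7}
        assert aggregate(scores, AggregationSpec(kind="prod")) == 0.0
        assert aggregate(scores, AggregationSpec(kind="gmean")) == 0.0

    def test_auto_weighting_emphasises_weakest(self):
        # w_i = (1 - s_i) + eps, normalised
        scores = {"a": 0.9, "b": 0.1}
        wa, wb = 0.1 + AUTO_WEIGHT_EPS, 0.9 + AUTO_WEIGHT_EPS
        expected = (wa * 0.9 + wb * 0.1) / (wa + wb)
        assert aggregate(scores, AggregationSpec(kind="auto_wsum")) == pytest.approx(expected)

    def test_weights_need_not_sum_to_one(self):
        scores = {"a": 0.5, "b": 1.0}
        s1 = aggregate(scores, AggregationSpec(kind="wsum", weights={"a": 1, "b": 3}))
        s2 = aggregate(scores, AggregationSpec(kind="wsum", weights={"a": 10, "b": 30}))
        assert s1 == pytest.approx(s2)

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_am_gm_inequality(self, values):
        scores = {f"p{i}": v for i, v in enumerate(values)}
        gm = aggregate(scores, AggregationSpec(kind="gmean"))
        am = aggregate(scores, AggregationSpec(kind="amean"))
        assert gm <= am + 1e-9

    @settings(max_examples=100, derandomize=True)
    @given(st.permutations(["a", "b", "c", "d"]), st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_permutation_invariance_unweighted(self, names, values):
        base = dict(zip(["a", "b", "c", "d"], values))
        shuffled = {k: base[k] for k in names}
        for kind in ("amean", "gmean", "prod", "auto_wsum"):
            spec = AggregationSpec(kind=kind)
            assert aggregate(base, spec) == pytest.approx(aggregate(shuffled, spec))

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            aggregate({}, AggregationSpec(kind="amean"))

    def test_pareto_requires_context(self):
        with pytest.raises(ConfigurationError):
            aggregate({"a": 0.5}, AggregationSpec(kind="pareto"))

    def test_pareto_example_fronts(self):
        pts = [{"x": 1.0, "y": 0.0}, {"x": 0.0, "y": 1.0}, {"x": 0.5, "y": 0.5}, {"x": 0.2, "y": 0.2}]
        ranks = pareto_front_ranks([[p["x"], p["y"]] for p in pts])
        assert ranks == [1, 1, 1, 2]
        values = aggregate_batch(pts, AggregationSpec(kind="pareto"))
        assert values[0] == values[1] == values[2] == 1.0
        assert values[3] == pytest.approx(0.5)

    def test_pareto_matches_brute_force_oracle(self):
        rng = random.Random(0)
        for _ in range(25):
            n = rng.randint(2, 60)
            pts = [[rng.random() for _ in range(rng.randint(2, 4))] for _ in range(n)]
            dims = min(len(p) for p in pts)
            pts = [p[:dims] for p in pts]
            assert pareto_front_ranks(pts) == _brute_force_fronts(pts)
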
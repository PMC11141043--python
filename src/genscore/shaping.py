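"""Score transformation and aggregation: the desirability algebra.

Raw scorer outputs live on arbitrary scales (Daltons, log units, counts);
each is mapped into [0, 1] by a transformation function encoding the
preference direction, and the transformed vector is collapsed into a single
desirability score by an aggregation function.

Transform kinds
---------------
``normalise``
    Running max-min normalisation: the observed minimum and maximum are
    updated with every value seen during a run and the value is scaled into
    the current range (inverted for ``minimize``).  This is the "moving goal
    post" transform appropriate when the achievable range of a score (e.g. a
    docking score) is unknown a priori.
``linear_threshold``
    A linear ramp of width ``buffer`` ending at ``threshold``: for
    ``maximize``, 0 at or below threshold - buffer, 1 at or above threshold.
``gaussian_threshold``
    ``exp(-(x - mu)^2 / (2 sigma^2))``; with a one-sided direction the score
    is 1 anywhere past ``mu`` on the desired side.
``step_threshold``
    A hard window: 1 inside [low, high], 0 outside.  One-sided windows leave
    the other bound open.
``identity``
    The raw value clamped to [0, 1] (for scorers already on that scale).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chemio import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "TransformSpec",
    "RunningRange",
    "AggregationSpec",
    "transform",
    "aggregate",
    "aggregate_batch",
    "pareto_front_ranks",
    "reset_range",
]

_TRANSFORM_KINDS = ("normalise", "linear_threshold", "gaussian_threshold", "step_threshold", "identity")
_DIRECTIONS = ("maximize", "minimize", "range")
_AGG_KINDS = ("wsum", "auto_wsum", "prod", "wprod", "auto_wprod", "gmean", "amean", "pareto")

#: weight floor for auto-weighting, so fully-satisfied objectives keep a
#: small nonzero pull; see AggregationSpec.
AUTO_WEIGHT_EPS = 0.01

_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class TransformSpec:
    """Declarative description of one raw-score -> [0,1] mapping."""

    kind: str
    direction: str = "maximize"
    threshold: float | None = None
    buffer: float | None = None
    mu: float | None = None
    sigma: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _TRANSFORM_KINDS:
            raise ConfigurationError(f"unknown transform kind {self.kind!r}")
        if self.direction not in _DIRECTIONS:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.kind == "linear_threshold":
            if self.threshold is None or self.buffer is None:
                raise ConfigurationError("linear_threshold requires threshold and buffer")
            if self.buffer <= 0:
                raise ConfigurationError("buffer must be strictly positive")
        if self.kind == "gaussian_threshold":
            if self.mu is None or self.sigma is None:
                raise ConfigurationError("gaussian_threshold requires mu and sigma")
            if self.sigma <= 0:
                raise ConfigurationError("sigma must be strictly positive")
        if self.kind == "step_threshold":
            if self.low is None and self.high is None:
                raise ConfigurationError("step_threshold requires low and/or high")
            if self.low is not None and self.high is not None and self.low > self.high:
                raise ConfigurationError("step_threshold requires low <= high")


@dataclass
class RunningRange:
    """Mutable min/max state for the running ``normalise`` transform."""

    min_seen: float = math.inf
    max_seen: float = -math.inf
    count: int = 0

    def update(self, x: float) -> None:
        self.min_seen = min(self.min_seen, x)
        self.max_seen = max(self.max_seen, x)
        self.count += 1


def reset_range(range_state: RunningRange) -> RunningRange:
    """Return the state to its pristine, no-observations condition."""
    range_state.min_seen = math.inf
    range_state.max_seen = -math.inf
    range_state.count = 0
    return range_state


def _clamp(v: float) -> float:
    if -_CLAMP_TOL < v < 0.0:
        return 0.0
    if 1.0 < v < 1.0 + _CLAMP_TOL:
        return 1.0
    return min(1.0, max(0.0, v))


def transform(x: float, spec: TransformSpec, range_state: RunningRange | None = None) -> float:
    """Map a raw value into [0, 1] according to ``spec``.

    Non-finite input is scored 0 with a logged warning.  ``normalise``
    requires (and mutates) ``range_state``.
    """
    if not math.isfinite(x):
        logger.warning("non-finite raw value %r scored as 0", x)
        return 0.0
    kind = spec.kind
    if kind == "identity":
        return _clamp(x)
    if kind == "normalise":
        if range_state is None:
            raise ConfigurationError("normalise transform requires a RunningRange state")
        range_state.update(x)
        if range_state.max_seen == range_state.min_seen:
            # no range yet: neutral desirability
            return 0.5
        v = (x - range_state.min_seen) / (range_state.max_seen - range_state.min_seen)
        if spec.direction == "minimize":
            v = 1.0 - v
        return _clamp(v)
    if kind == "linear_threshold":
        thr, buf = spec.threshold, spec.buffer
        if spec.direction == "minimize":
            if x <= thr:
                return 1.0
            if x >= thr + buf:
                return 0.0
            return _clamp(1.0 - (x - thr) / buf)
        if x >= thr:
            return 1.0
        if x <= thr - buf:
            return 0.0
        return _clamp(1.0 - (thr - x) / buf)
    if kind == "gaussian_threshold":
        mu, sigma = spec.mu, spec.sigma
        if spec.direction == "maximize" and x >= mu:
            return 1.0
        if spec.direction == "minimize" and x <= mu:
            return 1.0
        return _clamp(math.exp(-((x - mu) ** 2) / (2.0 * sigma**2)))
    if kind == "step_threshold":
        lo = -math.inf if spec.low is None else spec.low
        hi = math.inf if spec.high is None else spec.high
        return 1.0 if lo <= x <= hi else 0.0
    raise ConfigurationError(f"unknown transform kind {kind!r}")  # pragma: no cover


# --------------------------------------------------------------------------
# Aggregation

@dataclass(frozen=True)
class AggregationSpec:
    """How to collapse the transformed score vector into one desirability.

    ``weights`` maps parameter name to a nonnegative weight; weights are
    normalised internally so they need not sum to 1.  The auto-weighted
    kinds recompute weights per molecule as ``w_i = (1 - s_i) + eps``,
    emphasising the currently least-satisfied objectives.
    """

    kind: str = "amean"
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _AGG_KINDS:
            raise ConfigurationError(f"unknown aggregation kind {self.kind!r}")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigurationError("weights must be nonnegative")
        if self.kind in ("wsum", "wprod") and self.weights and not any(
            w > 0 for w in self.weights.values()
        ):
            raise ConfigurationError("at least one weight must be positive")


def _weights_for(scores: Mapping[str, float], spec: AggregationSpec) -> dict[str, float]:
    if spec.kind in ("auto_wsum", "auto_wprod"):
        w = {k: (1.0 - s) + AUTO_WEIGHT_EPS for k, s in scores.items()}
    elif spec.kind in ("wsum", "wprod"):
        missing = [k for k in scores if k not in spec.weights]
        if missing:
            raise ConfigurationError(f"weights missing for parameters: {missing}")
        w = {k: float(spec.weights[k]) for k in scores}
    else:
        w = {k: 1.0 for k in scores}
    total = sum(w.values())
    if total <= 0:
        raise ConfigurationError("weights sum to zero")
    return {k: v / total for k, v in w.items()}


def aggregate(
    scores: Mapping[str, float],
    spec: AggregationSpec,
    batch_context: Sequence[Mapping[str, float]] | None = None,
) -> float:
    """Aggregate a per-parameter score map (all values in [0, 1]) into one value.

    The ``pareto`` kind is batch-wise: ``batch_context`` must contain this
    molecule's score map (by identity or equality); its value is derived
    from the non-dominated front rank.
    """
    if not scores:
        raise ValueError("cannot aggregate an empty score map")
    kind = spec.kind
    if kind == "pareto":
        if batch_context is None:
            raise ConfigurationError("pareto aggregation requires batch_context")
        values = aggregate_batch(list(batch_context), spec)
        for i, ctx in enumerate(batch_context):
            if ctx is scores:
                return values[i]
        for i, ctx in enumerate(batch_context):
            if dict(ctx) == dict(scores):
                return values[i]
        raise ConfigurationError("batch_context must contain this molecule's scores")
    w = _weights_for(scores, spec)
    if kind in ("wsum", "auto_wsum", "amean"):
        return _clamp(sum(w[k] * scores[k] for k in scores))
    if kind in ("prod",):
        v = 1.0
        for s in scores.values():
            v *= s
        return _clamp(v)
    if kind in ("wprod", "auto_wprod"):
        v = 1.0
        for k, s in scores.items():
            if s == 0.0:
                return 0.0
            v *= s ** w[k]
        return _clamp(v)
    if kind == "gmean":
        v = 1.0
        for s in scores.values():
            v *= s
        return _clamp(v ** (1.0 / len(scores)))
    raise ConfigurationError(f"unknown aggregation kind {kind!r}")  # pragma: no cover


def _dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))


def pareto_front_ranks(points: Sequence[Sequence[float]]) -> list[int]:
    """Non-dominated sorting: 1-based front rank per point (1 = best front).

    Fast non-dominated sort; ties (identical points) share a front.
    """
    n = len(points)
    dominated_by: list[int] = [0] * n
    dominates_set: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(points[i], points[j]):
                dominates_set[i].append(j)
                dominated_by[j] += 1
            elif _dominates(points[j], points[i]):
                dominates_set[j].append(i)
                dominated_by[i] += 1
    ranks = [0] * n
    current = [i for i in range(n) if dominated_by[i] == 0]
    front = 1
    while current:
        nxt: list[int] = []
        for i in current:
            ranks[i] = front
            for j in dominates_set[i]:
                dominated_by[j] -= 1
                if dominated_by[j] == 0:
                    nxt.append(j)
        current = nxt
        front += 1
    return ranks


def aggregate_batch(
    score_maps: Sequence[Mapping[str, float]], spec: AggregationSpec
) -> list[float]:
    """Aggregate a whole batch; required entry point for the ``pareto`` kind.

    Pareto scalarisation: rank the batch by non-dominated sorting and map
    front rank r of R fronts to ``1 - (r - 1)/R``, so the best front gets the
    highest value and every front a distinct one.
    """
    if spec.kind != "pareto":
        return [aggregate(s, spec) for s in score_maps]
    if not score_maps:
        return []
    keys = sorted(score_maps[0])
    pts = [[float(s[k]) for k in keys] for s in score_maps]
    ranks = pareto_front_ranks(pts)
    n_fronts = max(ranks)
    return [_clamp(1.0 - (r - 1) / n_fronts) for r in ranks]
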
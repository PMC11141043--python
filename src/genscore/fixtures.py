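"""Deterministic synthetic molecule libraries and a demo pool optimizer.

The library generator enumerates drug-like SMILES from a small grammar of
scaffolds (alkanes, substituted benzenes, piperazines/piperidines, fused
bicyclics) and decorations, with an exact, seeded fraction of syntactically
corrupted entries (unclosed rings, bad valence tokens) standing in for the
invalid SMILES a generative model emits.  The pool optimizer is a
resampling-based stand-in for a generative model: it samples molecules from
a fixed pool with probability proportional to ``exp(score / temperature)``
using the last known scores, which is enough to exercise the full iterative
scoring loop (propose -> score -> update) end to end.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .chemio import parse
from .manager import PRESETS, ObjectiveConfig, Pipeline, load_config

__all__ = ["FixtureLibrary", "make_library", "PoolOptimizer", "demo_optimize"]


_SCAFFOLD_TEMPLATES = (
    "C" * 3, "C" * 4, "C" * 5, "C" * 6, "C" * 8,          # alkanes
    "c1ccccc1{d}", "c1ccc({d})cc1", "Cc1ccccc1{d}",        # benzenes
    "c1ccncc1{d}", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",   # pyridine, fused
    "C1CCNCC1", "C1CN({d})CCN1{d}", "O=C(c1ccccc1){d}",    # amines, ketone
    "c1ccc(CCN{d})cc1", "C1CCC(C(=O)O)CC1",
)

_DECORATIONS = ("C", "CC", "CCO", "O", "OC", "N", "NC", "F", "Cl", "Br",
                "C(=O)O", "C(=O)N", "C#N", "CO", "CN(C)C")

_CORRUPTIONS = ("C1CC", "C(C)(C)(C)(C)C", "c1ccc1cc", "C((C)", "X1CC1", "CC)O")


@dataclass(frozen=True)
class FixtureLibrary:
    """A reproducible SMILES list with a known invalid fraction."""

    smiles: tuple[str, ...]
    seed: int
    invalid_fraction: float

    def __len__(self) -> int:
        return len(self.smiles)

    @property
    def valid_smiles(self) -> list[str]:
        return [s for s in self.smiles if parse(s).valid]


def make_library(n: int, seed: int = 0, invalid_fraction: float = 0.0) -> FixtureLibrary:
    """Generate ``n`` SMILES; exactly ``round(n * invalid_fraction)`` are invalid.

    Deterministic for a given (n, seed, invalid_fraction).  Every valid
    entry is guaranteed to parse (asserted at build time).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= invalid_fraction <= 1.0:
        raise ValueError("invalid_fraction must be in [0, 1]")
    rng = random.Random(seed)
    n_invalid = round(n * invalid_fraction)
    smiles: list[str] = []
    seen: set[str] = set()
    while len(smiles) < n - n_invalid:
        template = rng.choice(_SCAFFOLD_TEMPLATES)
        smi = template.replace("{d}", rng.choice(_DECORATIONS)) if "{d}" in template else template
        # occasional chain extension for variety
        if rng.random() < 0.3:
            smi = smi + rng.choice(("C", "CC", "CO"))
        mol = parse(smi)
        if not mol.valid:
            continue
        if mol.canonical_smiles in seen and rng.random() < 0.7:
            continue  # mostly distinct, some deliberate repeats
        seen.add(mol.canonical_smiles)
        smiles.append(smi)
    invalid = [rng.choice(_CORRUPTIONS) for _ in range(n_invalid)]
    assert all(not parse(s).valid for s in invalid)
    smiles.extend(invalid)
    rng.shuffle(smiles)
    return FixtureLibrary(tuple(smiles), seed=seed, invalid_fraction=invalid_fraction)


@dataclass
class PoolOptimizer:
    """Score-weighted resampler over a fixed molecule pool.

    Implements the generator contract the benchmark driver expects:
    ``propose(k)`` samples k SMILES with weights ``exp(score/temperature)``
    (unscored molecules count as score 0), ``update(smiles, scores)``
    records the latest scores.  With temperature -> infinity sampling is
    uniform; low temperatures concentrate on the best-scoring molecules,
    giving hill-climb-like behaviour.
    """

    pool: Sequence[str]
    temperature: float = 0.1
    seed: int = 0
    _scores: dict[str, float] = field(default_factory=dict)
    _rng: random.Random = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.pool:
            raise ValueError("empty pool")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        self._rng = random.Random(self.seed)

    def propose(self, k: int) -> list[str]:
        weights = [math.exp(self._scores.get(s, 0.0) / self.temperature) for s in self.pool]
        return self._rng.choices(list(self.pool), weights=weights, k=k)

    def update(self, smiles: Sequence[str], scores: Sequence[float]) -> None:
        for s, v in zip(smiles, scores):
            self._scores[s] = float(v)


def demo_optimize(
    objective,
    pool_size: int = 500,
    batches: int = 30,
    batch_size: int = 64,
    seed: int = 0,
    temperature: float = 0.1,
    write_csv: bool = True,
):
    """Run the full iterative scoring loop with the pool optimizer.

    Returns the :class:`~genscore.manager.Pipeline` after ``batches``
    iterations; its ``state.records`` carry the whole run.
    """
    pipeline = objective if isinstance(objective, Pipeline) else Pipeline(objective, write_csv=write_csv)
    library = make_library(pool_size, seed=seed, invalid_fraction=0.0)
    optimizer = PoolOptimizer(library.smiles, temperature=temperature, seed=seed)
    for _ in range(batches):
        batch = optimizer.propose(batch_size)
        scores = pipeline.score(batch)
        optimizer.update(batch, scores)
    return pipeline


# --------------------------------------------------------------------------
# Bundled benchmark preset: two fixture-based similarity objectives

def _demo_preset() -> list[dict]:
    library = make_library(50, seed=7, invalid_fraction=0.0)
    targets = library.valid_smiles[:2]
    configs = []
    for i, target in enumerate(targets):
        configs.append(
            {
                "task_name": f"demo_similarity_{i}",
                "output_dir": f"demo_similarity_{i}",
                "scorers": [
                    {
                        "name": "sim",
                        "kind": "fingerprint_similarity",
                        "params": {"ref_smiles": [target], "measure": "tanimoto", "reduce": "max"},
                    }
                ],
                "parameters": [
                    {"source": "sim_similarity", "transform": {"kind": "identity"}}
                ],
                "aggregation": {"kind": "amean"},
            }
        )
    return configs


PRESETS.setdefault("demo", _demo_preset)
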
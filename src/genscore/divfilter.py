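"""Diversity filters: stateful memories that penalise over-exploited chemotypes.

During goal-directed optimisation a generative model tends to collapse onto
a handful of rewarding scaffolds.  A diversity filter maintains a memory of
clusters (buckets) across the run; once a bucket is full, further molecules
landing in it receive a score of 0, pushing the model to explore elsewhere.

Kinds
-----
``Unique``                       every canonical SMILES is its own bucket of size 1
                                 (a repeat scores 0).
``Occurrence``                   graded decay with repetition count instead of a
                                 hard zero.
``IdenticalMurckoScaffold``      bucket key = Bemis-Murcko scaffold.
``IdenticalTopologicalScaffold`` bucket key = generic (all-carbon) framework.
``CompoundSimilarity``           leader-style clustering on whole-molecule ECFP
                                 Tanimoto at ``minsimilarity``.
``ScaffoldSimilarityAtomPair`` / ``ScaffoldSimilarityECFP``
                                 the same leader clustering over the scaffold's
                                 fingerprint.

Only molecules scoring at least ``minscore`` enter the memory; sub-threshold
molecules are never penalised and never recorded.  A molecule arriving at a
bucket already holding ``nbmax`` members is scored 0 (and not appended).
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

from .chemio import (
    BitVector,
    ConfigurationError,
    FingerprintSpec,
    ParsedMolecule,
    fingerprint,
    murcko_scaffold,
    parse,
    similarity,
    topological_scaffold,
)

__all__ = [
    "DiversityFilterSpec",
    "DiversityMemory",
    "ScoredMolecule",
    "assign_cluster",
    "penalise",
]

FILTER_KINDS = (
    "Unique",
    "Occurrence",
    "IdenticalMurckoScaffold",
    "IdenticalTopologicalScaffold",
    "CompoundSimilarity",
    "ScaffoldSimilarityAtomPair",
    "ScaffoldSimilarityECFP",
)

_SIMILARITY_KINDS = ("CompoundSimilarity", "ScaffoldSimilarityAtomPair", "ScaffoldSimilarityECFP")


@dataclass(frozen=True)
class DiversityFilterSpec:
    """Configuration of one diversity filter.

    ``nbmax`` is the bucket capacity (``None`` = unbounded, a no-op filter);
    ``minscore`` gates memory insertion; ``minsimilarity`` is the leader-
    clustering threshold for the similarity kinds; ``occurrence_tolerance``
    repeats are free before the Occurrence decay starts, which then reaches
    zero after ``occurrence_buffer`` further repeats.
    """

    kind: str = "IdenticalMurckoScaffold"
    nbmax: int | None = 25
    minscore: float = 0.5
    minsimilarity: float = 0.6
    occurrence_tolerance: int = 5
    occurrence_buffer: int = 5

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ConfigurationError(f"unknown diversity filter kind {self.kind!r}")
        if self.nbmax is not None and self.nbmax < 1:
            raise ConfigurationError("nbmax must be >= 1 (or None for unbounded)")
        if not 0.0 <= self.minscore <= 1.0:
            raise ConfigurationError("minscore must be in [0, 1]")
        if not 0.0 <= self.minsimilarity <= 1.0:
            raise ConfigurationError("minsimilarity must be in [0, 1]")
        if self.occurrence_tolerance < 0 or self.occurrence_buffer < 1:
            raise ConfigurationError("bad occurrence parameters")


@dataclass
class _Cluster:
    key: str
    centroid: BitVector | None
    members: list[str] = field(default_factory=list)

    @property
    def occupancy(self) -> int:
        return len(self.members)


@dataclass
class DiversityMemory:
    """Mutable clustering state accumulated over a run."""

    clusters: dict[str, _Cluster] = field(default_factory=dict)
    seen_counts: dict[str, int] = field(default_factory=dict)
    _order: list[str] = field(default_factory=list)  # creation order for tie-breaks

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_csv(self, path: str | os.PathLike) -> None:
        """Dump cluster occupancy and members for monitor-style tooling."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cluster_key", "occupancy", "members"])
            for key in self._order:
                cluster = self.clusters[key]
                writer.writerow([key, cluster.occupancy, " ".join(cluster.members)])


@dataclass(frozen=True)
class ScoredMolecule:
    """A molecule with its pre-filter desirability, the filter's input unit."""

    mol: ParsedMolecule
    score: float


_AP_SPEC = FingerprintSpec(family="AtomPair")
_ECFP_SPEC = FingerprintSpec(family="ECFP", radius=2, n_bits=2048)


def _cluster_fingerprint(mol: ParsedMolecule, kind: str) -> BitVector | None:
    if kind == "CompoundSimilarity":
        return fingerprint(mol, _ECFP_SPEC)
    scaffold = murcko_scaffold(mol)
    scaffold_mol = parse(scaffold) if scaffold else None
    if scaffold_mol is None or not scaffold_mol.valid:
        return None  # acyclic molecules share the "" cluster
    spec = _AP_SPEC if kind == "ScaffoldSimilarityAtomPair" else _ECFP_SPEC
    return fingerprint(scaffold_mol, spec)


def assign_cluster(
    record: ScoredMolecule, spec: DiversityFilterSpec, memory: DiversityMemory
) -> str:
    """Cluster key for a molecule under ``spec`` given the current ``memory``.

    For similarity kinds the molecule joins the nearest existing centroid at
    Tanimoto >= ``minsimilarity`` (earlier-created cluster wins ties) or
    founds a new cluster; assignment does not itself mutate the memory.
    """
    mol = record.mol
    kind = spec.kind
    if kind in ("Unique", "Occurrence"):
        return mol.canonical_smiles or ""
    if kind == "IdenticalMurckoScaffold":
        return murcko_scaffold(mol)
    if kind == "IdenticalTopologicalScaffold":
        return topological_scaffold(mol)
    # similarity kinds
    fp = _cluster_fingerprint(mol, kind)
    if fp is None:
        return ""
    best_key, best_sim = None, -1.0
    for key in memory._order:
        centroid = memory.clusters[key].centroid
        if centroid is None:
            continue
        sim = similarity(fp, centroid, "tanimoto")
        if sim > best_sim:  # strict: earlier cluster wins ties
            best_key, best_sim = key, sim
    if best_key is not None and best_sim >= spec.minsimilarity:
        return best_key
    return mol.canonical_smiles or ""


def _get_or_create(
    memory: DiversityMemory, key: str, centroid: BitVector | None
) -> _Cluster:
    cluster = memory.clusters.get(key)
    if cluster is None:
        cluster = _Cluster(key=key, centroid=centroid)
        memory.clusters[key] = cluster
        memory._order.append(key)
    return cluster


def penalise(
    records: Sequence[ScoredMolecule],
    spec: DiversityFilterSpec,
    memory: DiversityMemory,
) -> list[float]:
    """Apply the diversity filter to a batch in order; returns final scores.

    The memory is updated in record order, so earlier molecules in a batch
    can fill a bucket that penalises later ones.  Penalised scores are never
    above the input score and stay in [0, 1].
    """
    out: list[float] = []
    for record in records:
        score = record.score
        if not record.mol.valid or score < spec.minscore:
            out.append(score)  # sub-threshold: untouched, not recorded
            continue
        smi = record.mol.canonical_smiles or ""
        if spec.kind == "Unique":
            if smi in memory.seen_counts:
                out.append(0.0)
            else:
                memory.seen_counts[smi] = 1
                _get_or_create(memory, smi, None).members.append(smi)
                out.append(score)
            continue
        if spec.kind == "Occurrence":
            seen = memory.seen_counts.get(smi, 0)
            scale = max(
                0.0,
                1.0 - max(0, seen - spec.occurrence_tolerance) / spec.occurrence_buffer,
            )
            memory.seen_counts[smi] = seen + 1
            _get_or_create(memory, smi, None).members.append(smi)
            out.append(score * scale)
            continue
        key = assign_cluster(record, spec, memory)
        centroid = (
            _cluster_fingerprint(record.mol, spec.kind)
            if spec.kind in _SIMILARITY_KINDS and key not in memory.clusters
            else None
        )
        cluster = _get_or_create(memory, key, centroid)
        capacity = math.inf if spec.nbmax is None else spec.nbmax
        if cluster.occupancy >= capacity:
            out.append(0.0)  # bucket full: hard zero, member not appended
        else:
            cluster.members.append(smi)
            out.append(score)
    return out
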
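"""Self-contained scoring functions: descriptors, similarity, substructures, domains.

Every scorer is a pure callable ``scorer(mol: ParsedMolecule) -> dict[str, float]``
mapping metric names to raw values; the pipeline prefixes metric names with
the scorer's configured name to build output columns.  Because scorers are
pure functions of the canonical SMILES, the pipeline may evaluate a batch
through any order-preserving parallel map and obtain results identical to
serial execution.
"""

from __future__ import annotations

import base64
import json
import math
import os
import re
import sys
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors

from .chemio import (
    BitVector,
    ConfigurationError,
    FingerprintSpec,
    ParsedMolecule,
    fingerprint,
    parse,
    similarity,
)

__all__ = [
    "DescriptorScorer",
    "PenalisedLogPScorer",
    "MaxConsecutiveRotatableBondsScorer",
    "FingerprintSimilarityScorer",
    "IsomerSimilarityScorer",
    "SubstructureScorer",
    "DomainModel",
    "ApplicabilityScorer",
    "TabulatedModelScorer",
    "descriptors",
    "penalised_logp",
    "max_consecutive_rotatable_bonds",
    "synthetic_accessibility",
    "natural_product_likeness",
]


# --------------------------------------------------------------------------
# Toolkit-contrib synthetic accessibility / natural-product likeness

_sascorer = None
_npscorer = None
_np_model = None


def synthetic_accessibility(mol: ParsedMolecule) -> float:
    """Ertl & Schuffenhauer SA score in [1, 10] (1 = easy to make)."""
    global _sascorer
    if _sascorer is None:
        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer  # noqa: PLC0415

        _sascorer = sascorer
    return float(_sascorer.calculateScore(mol.require_valid()))


def natural_product_likeness(mol: ParsedMolecule) -> float:
    """Ertl natural-product likeness score (roughly [-5, 5])."""
    global _npscorer, _np_model
    if _npscorer is None:
        sys.path.append(os.path.join(RDConfig.RDContribDir, "NP_Score"))
        import npscorer  # noqa: PLC0415

        _npscorer = npscorer
        _np_model = npscorer.readNPModel()
    return float(_npscorer.scoreMol(mol.require_valid(), _np_model))


# --------------------------------------------------------------------------
# Descriptors

_DESCRIPTOR_FUNCS: dict[str, Callable[[Chem.Mol], float]] = {
    "MW": Descriptors.MolWt,
    "logP": Crippen.MolLogP,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "HBD": Lipinski.NumHDonors,
    "HBA": Lipinski.NumHAcceptors,
    "RotatableBonds": Lipinski.NumRotatableBonds,
    "AromaticRings": rdMolDescriptors.CalcNumAromaticRings,
    "RingCount": rdMolDescriptors.CalcNumRings,
    "HeavyAtoms": lambda m: m.GetNumHeavyAtoms(),
    "FormalCharge": Chem.GetFormalCharge,
    "QED": QED.qed,
}

SUPPORTED_DESCRIPTORS = tuple(_DESCRIPTOR_FUNCS)


def descriptors(mol: ParsedMolecule, names: Sequence[str]) -> dict[str, float]:
    """Physicochemical descriptors by name (MW in Da, TPSA in A^2)."""
    unknown = [n for n in names if n not in _DESCRIPTOR_FUNCS]
    if unknown:
        raise ConfigurationError(
            f"unknown descriptors {unknown}; supported: {SUPPORTED_DESCRIPTORS}"
        )
    m = mol.require_valid()
    return {n: float(_DESCRIPTOR_FUNCS[n](m)) for n in names}


@dataclass(frozen=True)
class DescriptorScorer:
    names: tuple[str, ...] = SUPPORTED_DESCRIPTORS

    def __post_init__(self) -> None:
        descriptors(parse("C"), self.names)  # validate names eagerly

    def __call__(self, mol: ParsedMolecule) -> dict[str, float]:
        return descriptors(mol, self.names)


# --------------------------------------------------------------------------
# Penalised logP

def _ring_penalty(m: Chem.Mol) -> int:
    # number of rings with more than 6 atoms in the SSSR
    return sum(1 for ring in m.GetRingInfo().AtomRings() if len(ring) > 6)


def penalised_logp(mol: ParsedMolecule) -> float:
    """logP - SA - (number of rings larger than 6).

    The classic generative-chemistry toy objective; reported on its natural
    scale, without the ZINC z-normalisation some papers apply.
    """
    m = mol.require_valid()
    return float(Crippen.MolLogP(m)) - synthetic_accessibility(mol) - _ring_penalty(m)


@dataclass(frozen=True)
class PenalisedLogPScorer:
    def __call__(self, mol: ParsedMolecule) -> dict[str, float]:
        return {"plogp": penalised_logp(mol)}


# --------------------------------------------------------------------------
# Maximum number of consecutive rotatable bonds

#: strict rotatable-bond pattern: a non-ring single bond between two
#: non-terminal heavy atoms that are not part of a triple bond.
ROTATABLE_SMARTS = "[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]"
_ROT_PATTERN = Chem.MolFromSmarts(ROTATABLE_SMARTS)
_AMIDE_PATTERN = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")


def _rotatable_bond_indices(m: Chem.Mol) -> list[tuple[int, int]]:
    amide_bonds = set()
    for match in m.GetSubstructMatches(_AMIDE_PATTERN):
        amide_bonds.add(frozenset(match[:2]))
    bonds = []
    for a, b in m.GetSubstructMatches(_ROT_PATTERN):
        if frozenset((a, b)) not in amide_bonds:
            bonds.append((a, b))
    return bonds


def max_consecutive_rotatable_bonds(mol: ParsedMolecule) -> int:
    """Length (in bonds) of the longest simple path made only of rotatable bonds.

    Rotatable bonds are matched with :data:`ROTATABLE_SMARTS` (amide C-N
    excluded); bonds are consecutive when they share an atom and the path
    never revisits a bond.
    """
    m = mol.require_valid()
    bonds = _rotatable_bond_indices(m)
    if not bonds:
        return 0
    # adjacency over rotatable bonds: bonds are neighbours iff they share an atom
    adj: dict[int, list[int]] = {i: [] for i in range(len(bonds))}
    for i in range(len(bonds)):
        for j in range(i + 1, len(bonds)):
            if set(bonds[i]) & set(bonds[j]):
                adj[i].append(j)
                adj[j].append(i)
    best = 1

    def dfs(current: int, visited: set[int], length: int) -> None:
        nonlocal best
        best = max(best, length)
        for nxt in adj[current]:
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, visited, length + 1)
                visited.remove(nxt)

    for start in range(len(bonds)):
        dfs(start, {start}, 1)
    return best


@dataclass(frozen=True)
class MaxConsecutiveRotatableBondsScorer:
    def __call__(self, mol: ParsedMolecule) -> dict[str, float]:
        return {"max_consecutive_rotatable_bonds": float(max_consecutive_rotatable_bonds(mol))}


# --------------------------------------------------------------------------
# Fingerprint similarity to references

@dataclass(frozen=True)
class FingerprintSimilarityScorer:
    """reduce(max|mean) of fingerprint similarity to a reference set."""

    ref_smiles: tuple[str, ...]
    spec: FingerprintSpec = FingerprintSpec()
    measure: str = "tanimoto"
    reduce: str = "max"
    _ref_fps: tuple[BitVector, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        if not self.ref_smiles:
            raise ConfigurationError("fingerprint similarity requires a nonempty reference set")
        if self.reduce not in ("max", "mean"):
            raise ConfigurationError("reduce must be 'max' or 'mean'")
        fps = []
        for smi in self.ref_smiles:
            ref = parse(smi)
            if not ref.valid:
                raise ConfigurationError(f"invalid reference SMILES {smi!r}")
            fps.append(fingerprint(ref, self.spec))
        object.__setattr__(self, "_ref_fps", tuple(fps))

    def __call__(self, mol: ParsedMolecule) -> dict[str, float]:
        fp = fingerprint(mol, self.spec)
        sims = [similarity(fp, r, self.measure) for r in self._ref_fps]
        value = max(sims) if self.reduce == "max" else sum(sims) / len(sims)
        return {"similarity": value}


# --------------------------------------------------------------------------
# Isomer similarity (molecular-formula matching)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ConfigurationError(f"unparseable molecular formula {formula!r}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ConfigurationError(f"unparseable molecular formula {formula!r}")
    return counts


def _element_counts(m: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in m.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


@dataclass(frozen=True)
class IsomerSimilarityScorer:
    """Soft molecular-formula agreement.

    Per element e present in either formula, a Gaussian term
    ``exp(-(n_mol(e) - n_target(e))^2 / 2)`` (sigma = 1 count unit); one more
    term of the same form compares total heavy-atom counts.  The score is
    the geometric mean of all terms and equals 1 iff the composition matches
    exactly.
    """

    formula: str
    _target: Mapping[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_target", _parse_formula(self.formula))

    def __call__(self, mol: ParsedMolecule) -> dict[str, float]:
        return {"isomer_score": self.score(mol)}

    def score(self, mol: ParsedMolecule) -> float:
        m = mol.require_valid()
        mol_counts = _element_counts(m)
        elements = set(self._target) | set(mol_counts)
        terms = [
            math.exp(-((mol_counts.get(e, 0) - self._target.get(e, 0)) ** 2) / 2.0)
            for e in elements
        ]
        heavy_target = sum(v for k, v in self._target.items() if k != "H")
        heavy_mol = sum(v for k, v in mol_counts.items() if k != "H")
        terms.append(math.exp(-((heavy_mol - heavy_target) ** 2) / 2.0))
        prod = 1.0
        for t in terms:
            prod *= t
        return prod ** (1.0 / len(terms))


def isomer_similarity(mol: ParsedMolecule, formula: str) -> float:
    return IsomerSimilarityScorer(formula).score(mol)


# --------------------------------------------------------------------------
# Substructure match / filters

_SUB_MODES = ("match_any", "match_all", "filter")


@dataclass(frozen=True)
class SubstructureScorer:
    """SMARTS matching with match (reward) or filter (alert) semantics.

    ``filter`` returns 1 when NO pattern matches, i.e. the complement of
    ``match_any``; SMARTS are compiled at construction so configuration
    errors surface at load time, never during scoring.
    """

    smarts: tuple[str, ...]
    mode: str = "match_any"
    _patterns: tuple[Chem.Mol, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        if self.mode not in _SUB_MODES:
            raise ConfigurationError(f"unknown substructure mode {self.mode!r}")
        if not self.smarts:
            raise ConfigurationError("substructure scorer requires at least one SMARTS")
        patterns = []
        bad = []
        for s in self.smarts:
            p = Chem.MolFromSmarts(s)
            if p is None:
                bad.append(s)
            else:
                patterns.append(p)
        if bad:
            raise ConfigurationError(f"invalid SMARTS patterns: {bad}")
        object.__setattr__(self, "_patterns", tuple(patterns))

    def __call__(self, mol: ParsedMolecule) -> dict[str, float]:
        m = mol.require_valid()
        hits = [m.HasSubstructMatch(p) for p in self._patterns]
        if self.mode == "match_any":
            value = 1.0 if any(hits) else 0.0
        elif self.mode == "match_all":
            value = 1.0 if all(hits) else 0.0
        else:  # filter: 1 iff clean
            value = 0.0 if any(hits) else 1.0
        return {"substructure": value}


def substructure_score(mol: ParsedMolecule, smarts: Sequence[str], mode: str = "match_any") -> float:
    return SubstructureScorer(tuple(smarts), mode)(mol)["substructure"]


# --------------------------------------------------------------------------
# Applicability domain

@dataclass
class DomainModel:
    """Training-set summary for applicability-domain scoring.

    Holds the training fingerprints (for max-similarity) and per-descriptor
    min/max bounds (for feature/physchem range).
    """

    fingerprints: list[BitVector]
    spec: FingerprintSpec
    feature_mins: dict[str, float]
    feature_maxs: dict[str, float]

    def __post_init__(self) -> None:
        if not self.fingerprints and not self.feature_mins:
            raise ConfigurationError("empty applicability-domain model")
        for k in self.feature_mins:
            if self.feature_mins[k] > self.feature_maxs.get(k, -math.inf):
                raise ConfigurationError(f"min > max for feature {k!r}")

    @classmethod
    def from_training_smiles(
        cls,
        smiles: Iterable[str],
        descriptor_names: Sequence[str] = ("MW", "logP", "TPSA", "HBD", "HBA"),
        spec: FingerprintSpec = FingerprintSpec(),
    ) -> "DomainModel":
        fps: list[BitVector] = []
        mins: dict[str, float] = {}
        maxs: dict[str, float] = {}
        n = 0
        for smi in smiles:
            mol = parse(smi)
            if not mol.valid:
                continue
            n += 1
            fps.append(fingerprint(mol, spec))
            for name, value in descriptors(mol, descriptor_names).items():
                mins[name] = min(mins.get(name, math.inf), value)
                maxs[name] = max(maxs.get(name, -math.inf), value)
        if n == 0:
            raise ConfigurationError("no valid molecules in training set")
        return cls(fps, spec, mins, maxs)

    # -- JSON round-trip (bit sets hex-encoded as sorted 4-byte big-endian ints)
    def to_json(self) -> str:
        def encode(fp: BitVector) -> str:
            payload = b"".join(b.to_bytes(4, "big") for b in sorted(fp.on_bits))
            return base64.b16encode(payload).decode()

        return json.dumps(
            {
                "spec": {
                    "family": self.spec.family,
                    "radius": self.spec.radius,
                    "n_bits": self.spec.n_bits,
                    "counted": self.spec.counted,
                },
                "fingerprints": [encode(fp) for fp in self.fingerprints],
                "feature_mins": self.feature_mins,
                "feature_maxs": self.feature_maxs,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DomainModel":
        data = json.loads(text)
        spec = FingerprintSpec(**data["spec"])

        def decode(hexstr: str) -> BitVector:
            raw = base64.b16decode(hexstr)
            bits = frozenset(
                int.from_bytes(raw[i : i + 4], "big") for i in range(0, len(raw), 4)
            )
            return BitVector(bits, n_bits=spec.n_bits)

        return cls(
            [decode(h) for h in data["fingerprints"]],
            spec,
            dict(data["feature_mins"]),
            dict(data["feature_maxs"]),
        )


_AD_KINDS = ("max_similarity", "feature_range", "physchem_range")


def applicability(
    mol: ParsedMolecule,
    model: DomainModel,
    kind: str = "max_similarity",
    descriptor_names: Sequence[str] | None = None,
) -> float:
    """Applicability-domain score in [0, 1].

    ``max_similarity``: max Tanimoto to the training fingerprints.
    ``feature_range`` / ``physchem_range``: fraction of the descriptor set
    whose value falls inside the training [min, max] (the two kinds are the
    same mechanism over two configurable descriptor lists).
    """
    if kind not in _AD_KINDS:
        raise ConfigurationError(f"unknown applicability kind {kind!r}")
    if kind == "max_similarity":
        if not model.fingerprints:
            raise ConfigurationError("model has no training fingerprints")
        fp = fingerprint(mol, model.spec)
        return max(similarity(fp, r, "tanimoto") for r in model.fingerprints)
    names = tuple(descriptor_names) if descriptor_names else tuple(model.feature_mins)
    if not names:
        raise ConfigurationError("model has no descriptor bounds")
    values = descriptors(mol, names)
    inside = sum(
        1
        for n in names
        if model.feature_mins[n] <= values[n] <= model.feature_maxs[n]
    )
    return inside / len(names)


@dataclass(frozen=True)
class ApplicabilityScorer:
    model: DomainModel
    kind: str = "max_similarity"
    descriptor_names: tuple[str, ...] | None = None

    def __call__(self, mol: ParsedMolecule) -> dict[str, float]:
        return {self.kind: applicability(mol, self.model, self.kind, self.descriptor_names)}


# --------------------------------------------------------------------------
# Generic tabulated / callable predictive-model slot

@dataclass(frozen=True)
class TabulatedModelScorer:
    """Generic external-model slot: canonical SMILES -> score.

    Stands in for trained predictive models; any mapping or callable over
    canonical SMILES plugs in.  Unknown molecules receive ``default``.
    """

    table: Mapping[str, float] | None = None
    func: Callable[[str], float] | None = None
    default: float = 0.0

    def __post_init__(self) -> None:
        if (self.table is None) == (self.func is None):
            raise ConfigurationError("provide exactly one of table or func")

    def __call__(self, mol: ParsedMolecule) -> dict[str, float]:
        smi = mol.canonical_smiles
        if smi is None:
            raise ConfigurationError("tabulated model requires a valid molecule")
        if self.table is not None:
            return {"pred": float(self.table.get(smi, self.default))}
        return {"pred": float(self.func(smi))}
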
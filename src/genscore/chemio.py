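"""Molecule parsing, fingerprints, similarity coefficients and substructure extraction.

This module is the chemistry substrate for the whole package: everything that
touches an RDKit ``Mol`` lives behind the functions defined here.  Molecules
are represented by :class:`ParsedMolecule`, which treats unparseable input as
a value (``valid=False``) rather than an error, and fingerprints by the
toolkit-agnostic :class:`BitVector`, so that similarity coefficients and the
diversity/metric machinery never depend on RDKit data structures directly.
"""

from __future__ import annotations

import math
import os
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import BRICS, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.Pharm2D import Generate as Pharm2DGenerate
from rdkit.Chem.Pharm2D import Gobbi_Pharm2D
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit import RDConfig

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ParsedMolecule",
    "FingerprintSpec",
    "BitVector",
    "parse",
    "fingerprint",
    "similarity",
    "SIMILARITY_MEASURES",
    "murcko_scaffold",
    "topological_scaffold",
    "substructure_sets",
    "read_smiles_file",
    "write_smiles_file",
]


class InvalidMoleculeError(ValueError):
    """Raised when an operation requiring a valid molecule receives an invalid one."""


class ConfigurationError(ValueError):
    """Raised for invalid user configuration (unknown names, bad parameters)."""


# --------------------------------------------------------------------------
# Parsing

@dataclass(frozen=True)
class ParsedMolecule:
    """A single input SMILES together with its parse outcome.

    ``valid`` is true iff RDKit could parse and sanitise the input, in which
    case ``canonical_smiles`` holds the toolkit's canonical isomeric SMILES.
    The underlying ``Mol`` is kept for downstream featurisation but excluded
    from equality/hashing.
    """

    input_smiles: str
    canonical_smiles: str | None
    mol: Chem.Mol | None = field(default=None, compare=False, repr=False)

    @property
    def valid(self) -> bool:
        return self.canonical_smiles is not None

    def require_valid(self) -> Chem.Mol:
        if not self.valid or self.mol is None:
            raise InvalidMoleculeError(
                f"operation requires a valid molecule, got {self.input_smiles!r}"
            )
        return self.mol


def parse(smiles: str) -> ParsedMolecule:
    """Parse a SMILES string; malformed input yields ``valid=False``, never raises.

    Canonicalisation is idempotent: parsing the canonical SMILES again gives
    back the same canonical SMILES.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return ParsedMolecule(input_smiles=smiles if isinstance(smiles, str) else "", canonical_smiles=None)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return ParsedMolecule(input_smiles=smiles, canonical_smiles=None)
    return ParsedMolecule(
        input_smiles=smiles, canonical_smiles=Chem.MolToSmiles(mol), mol=mol
    )


# --------------------------------------------------------------------------
# Fingerprints

_FAMILIES = ("ECFP", "AtomPair", "TopologicalTorsion", "MACCS", "RDKitPath", "Avalon", "Pharm2D")


@dataclass(frozen=True)
class FingerprintSpec:
    """Which fingerprint to compute.

    family one of ECFP (Morgan circular), AtomPair, TopologicalTorsion,
    MACCS (166 structural keys), RDKitPath (Daylight-like path fingerprint),
    Avalon, Pharm2D (Gobbi 2-point/3-point pharmacophore pairs).  ``radius``
    applies to ECFP only; ``counted`` to AtomPair/TopologicalTorsion.
    """

    family: str = "ECFP"
    radius: int = 2
    n_bits: int = 2048
    counted: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown fingerprint family {self.family!r}; choose from {_FAMILIES}"
            )
        if self.n_bits <= 0:
            raise ConfigurationError("n_bits must be positive")
        if self.radius < 0:
            raise ConfigurationError("radius must be >= 0")
        if self.counted and self.family not in ("AtomPair", "TopologicalTorsion"):
            raise ConfigurationError(
                "counted fingerprints supported for AtomPair/TopologicalTorsion only"
            )


@dataclass(frozen=True)
class BitVector:
    """A hashed fingerprint as a set of on bits, optionally with counts."""

    on_bits: frozenset[int]
    n_bits: int
    counts: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        if self.on_bits and (min(self.on_bits) < 0 or max(self.on_bits) >= self.n_bits):
            raise ValueError("on_bits out of range")
        if self.counts is not None and set(self.counts) != set(self.on_bits):
            raise ValueError("counts keys must equal on_bits")

    def __len__(self) -> int:
        return len(self.on_bits)


_GOBBI_FACTORY = Gobbi_Pharm2D.factory


def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def fingerprint(mol: ParsedMolecule, spec: FingerprintSpec = FingerprintSpec()) -> BitVector:
    """Compute the fingerprint described by ``spec`` for a valid molecule."""
    m = mol.require_valid()
    fam = spec.family
    if fam == "ECFP":
        gen = _morgan_generator(spec.radius, spec.n_bits)
    elif fam == "AtomPair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=spec.n_bits)
    elif fam == "TopologicalTorsion":
        gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=spec.n_bits)
    elif fam == "RDKitPath":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=spec.n_bits)
    elif fam == "MACCS":
        bv = MACCSkeys.GenMACCSKeys(m)
        return BitVector(frozenset(bv.GetOnBits()), n_bits=bv.GetNumBits())
    elif fam == "Avalon":
        bv = pyAvalonTools.GetAvalonFP(m, nBits=spec.n_bits)
        return BitVector(frozenset(bv.GetOnBits()), n_bits=spec.n_bits)
    elif fam == "Pharm2D":
        sparse = Pharm2DGenerate.Gen2DFingerprint(m, _GOBBI_FACTORY)
        n = sparse.GetNumBits()
        return BitVector(frozenset(sparse.GetOnBits()), n_bits=n)
    else:  # pragma: no cover - guarded in FingerprintSpec
        raise ConfigurationError(f"unknown family {fam}")
    if spec.counted:
        cfp = gen.GetCountFingerprint(m)
        counts = {int(b): int(c) for b, c in cfp.GetNonzeroElements().items()}
        return BitVector(frozenset(counts), n_bits=spec.n_bits, counts=counts)
    bv = gen.GetFingerprint(m)
    return BitVector(frozenset(bv.GetOnBits()), n_bits=spec.n_bits)


# --------------------------------------------------------------------------
# Similarity coefficients
#
# All coefficients are defined on binary fingerprints through the four set
# counts: na = |A|, nb = |B|, c = |A ∩ B|, n = bit-space size.  Formulas
# follow the classical binary-similarity literature as implemented in RDKit's
# DataStructs module (Todeschini & Consonni, "Molecular Descriptors", and
# RDKit source); the test-suite cross-checks each against RDKit on random
# vectors.  McConnaughey is natively in [-1, 1] and is rescaled to [0, 1]
# here so every exposed coefficient shares the [0, 1] codomain.


def _tanimoto(na, nb, c, n):
    d = na + nb - c
    return c / d if d else 0.0


def _dice(na, nb, c, n):
    return 2.0 * c / (na + nb) if (na + nb) else 0.0


def _cosine(na, nb, c, n):
    return c / math.sqrt(na * nb) if na and nb else 0.0


def _allbit(na, nb, c, n):
    # fraction of bit positions with equal value in both vectors
    return (n - (na + nb - 2.0 * c)) / n if n else 0.0


def _asymmetric(na, nb, c, n):
    m = min(na, nb)
    return c / m if m else 0.0


def _braunblanquet(na, nb, c, n):
    m = max(na, nb)
    return c / m if m else 0.0


def _mcconnaughey(na, nb, c, n):
    if not (na and nb):
        return -1.0
    return (c * (na + nb) - na * nb) / (na * nb)


def _kulczynski(na, nb, c, n):
    if not (na and nb):
        return 0.0
    return 0.5 * c * (na + nb) / (na * nb)


def _russel(na, nb, c, n):
    return c / n if n else 0.0


def _onbit(na, nb, c, n):
    d = na + nb - c
    return c / d if d else 0.0


def _rogotgoldberg(na, nb, c, n):
    d = n - na - nb + c  # common off bits
    if c == na == nb:  # identical vectors (incl. both empty)
        return 1.0
    t1 = c / (na + nb) if (na + nb) else 0.0
    t2 = d / (2 * n - na - nb) if (2 * n - na - nb) else 0.0
    return t1 + t2


def _sokal(na, nb, c, n):
    d = 2 * na + 2 * nb - 3 * c
    return c / d if d else 0.0


_RAW_MEASURES = {
    "tanimoto": _tanimoto,
    "allbit": _allbit,
    "asymmetric": _asymmetric,
    "braunblanquet": _braunblanquet,
    "cosine": _cosine,
    "mcconnaughey": _mcconnaughey,
    "dice": _dice,
    "kulczynski": _kulczynski,
    "russel": _russel,
    "onbit": _onbit,
    "rogotgoldberg": _rogotgoldberg,
    "sokal": _sokal,
}

SIMILARITY_MEASURES = tuple(sorted(_RAW_MEASURES))


def _normalise_measure(measure: str) -> str:
    key = measure.lower().replace(" ", "").replace("_", "").replace("-", "")
    if key not in _RAW_MEASURES:
        raise ConfigurationError(
            f"unknown similarity measure {measure!r}; choose from {SIMILARITY_MEASURES}"
        )
    return key


def raw_similarity(a: BitVector, b: BitVector, measure: str = "tanimoto") -> float:
    """Similarity on the measure's native scale (McConnaughey in [-1, 1])."""
    key = _normalise_measure(measure)
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints built with different bit-space sizes")
    if key == "tanimoto" and a.counts is not None and b.counts is not None:
        # min/max count generalisation of Tanimoto for counted fingerprints
        keys = set(a.counts) | set(b.counts)
        num = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
        den = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
        return num / den if den else 0.0
    na, nb = len(a.on_bits), len(b.on_bits)
    c = len(a.on_bits & b.on_bits)
    return _RAW_MEASURES[key](na, nb, c, a.n_bits)


def similarity(a: BitVector, b: BitVector, measure: str = "tanimoto") -> float:
    """Binary-fingerprint similarity coefficient in [0, 1].

    Counted fingerprints use the min/max generalisation for Tanimoto and are
    binarised for every other coefficient.  McConnaughey is affinely rescaled
    from its native [-1, 1] to [0, 1].
    """
    key = _normalise_measure(measure)
    value = raw_similarity(a, b, key)
    if key == "mcconnaughey":
        value = (value + 1.0) / 2.0
    return min(1.0, max(0.0, value))


# --------------------------------------------------------------------------
# Scaffolds and substructure vocabularies

def murcko_scaffold(mol: ParsedMolecule) -> str:
    """Bemis-Murcko framework (rings + linkers) as canonical SMILES; "" if acyclic."""
    m = mol.require_valid()
    scaffold = MurckoScaffold.GetScaffoldForMol(m)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def topological_scaffold(mol: ParsedMolecule) -> str:
    """Generic framework: the Murcko scaffold with all atoms C and all bonds single."""
    m = mol.require_valid()
    scaffold = MurckoScaffold.GetScaffoldForMol(m)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    generic = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return Chem.MolToSmiles(generic)


_IFG = None


def _ertl_functional_groups(m: Chem.Mol) -> list[str]:
    # Ertl's algorithm as bundled with the toolkit's contrib area.
    global _IFG
    if _IFG is None:
        sys.path.append(os.path.join(RDConfig.RDContribDir, "IFG"))
        import ifg  # noqa: PLC0415

        _IFG = ifg
    return [g.type for g in _IFG.identify_functional_groups(m)]


def _ring_systems(m: Chem.Mol) -> list[str]:
    """Connected fused-ring components, keeping atoms double-bonded to a ring.

    Rings sharing at least one atom are merged into one system; exocyclic
    atoms attached through a double bond (e.g. the carbonyl O of
    cyclohexanone) are retained, side chains are not.
    """
    ri = m.GetRingInfo()
    if ri.NumRings() == 0:
        return []
    systems: list[set[int]] = []
    for ring in ri.AtomRings():
        ring = set(ring)
        merged = ring
        rest = []
        for s in systems:
            if s & merged:
                merged = merged | s
            else:
                rest.append(s)
        rest.append(merged)
        systems = rest
    out: list[str] = []
    for system in systems:
        atoms = set(system)
        for bond in m.GetBonds():
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
                if a in system and b not in system:
                    atoms.add(b)
                elif b in system and a not in system:
                    atoms.add(a)
        bonds = [
            bond.GetIdx()
            for bond in m.GetBonds()
            if bond.GetBeginAtomIdx() in atoms and bond.GetEndAtomIdx() in atoms
        ]
        sub = Chem.PathToSubmol(m, bonds)
        try:
            smi = Chem.MolToSmiles(sub)
        except Exception:  # pragma: no cover - degenerate submol
            continue
        if smi:
            out.append(smi)
    return out


def substructure_sets(mol: ParsedMolecule) -> dict[str, list[str]]:
    """BRICS fragments, Ertl functional groups and fused ring systems.

    Returned values are multisets (lists) of canonical SMILES / SMARTS-like
    identifiers; callers build count vectors from them.
    """
    m = mol.require_valid()
    try:
        fragments = sorted(BRICS.BRICSDecompose(m))
    except Exception:
        fragments = []
    try:
        fgs = _ertl_functional_groups(m)
    except Exception:
        fgs = []
    return {
        "fragments": fragments,
        "functional_groups": fgs,
        "ring_systems": _ring_systems(m),
    }


# --------------------------------------------------------------------------
# .smi files

def read_smiles_file(path: str | os.PathLike) -> list[str]:
    """Read a ``.smi`` file: one SMILES per line, optional name column, ``#`` comments."""
    out: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split()[0])
    return out


def write_smiles_file(path: str | os.PathLike, smiles: Iterable[str], names: Sequence[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, smi in enumerate(smiles):
            if names is not None:
                fh.write(f"{smi}\t{names[i]}\n")
            else:
                fh.write(f"{smi}\n")
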
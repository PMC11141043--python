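"""Evaluation metrics for generated molecule sets.

Intrinsic metrics describe a generated set on its own (validity, uniqueness,
several diversity measures, structural-alert pass rate); extrinsic metrics
compare it against one or more reference corpora (novelty, nearest-neighbour
and substructure-vocabulary similarity, property-distribution distances).
Two headline metrics of the wider literature, the Frechet ChemNet Distance
and catalogue purchasability, require trained network weights or an external
catalogue; they are reported as NaN ("unavailable") so report schemas stay
stable.

All stochastic components (subsampling for sphere-exclusion and
Solow-Polasky diversity) are driven by an explicit seed.
"""

from __future__ import annotations

import math
import os
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import FilterCatalog, rdFingerprintGenerator

from .chemio import (
    BitVector,
    ConfigurationError,
    ParsedMolecule,
    murcko_scaffold,
    parse,
    substructure_sets,
)
from .scorers import descriptors, natural_product_likeness, synthetic_accessibility

__all__ = [
    "ReferenceSet",
    "MetricsCalculator",
    "intrinsic_metrics",
    "extrinsic_metrics",
    "internal_diversity",
    "se_div",
    "solow_polasky",
    "statistics_by_n",
    "alert_pass",
]

_ECFP4_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
_UNAVAILABLE = float("nan")


def _ecfp4(mol: Chem.Mol):
    return _ECFP4_GEN.GetFingerprint(mol)


def _to_bitvector(fp) -> BitVector:
    return BitVector(frozenset(fp.GetOnBits()), n_bits=fp.GetNumBits())


# --------------------------------------------------------------------------
# Structural alerts (MCF-style reactive/unstable groups + PAINS)

_ALERTS = None


def _load_alerts():
    global _ALERTS
    if _ALERTS is not None:
        return _ALERTS
    mcf_patterns = []
    with resources.files("genscore").joinpath("data/alerts_mcf.smarts").open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                smarts = line.split("\t")[0]
                patt = Chem.MolFromSmarts(smarts)
                if patt is not None:
                    mcf_patterns.append(patt)
    params = FilterCatalog.FilterCatalogParams()
    params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
    pains = FilterCatalog.FilterCatalog(params)
    _ALERTS = (mcf_patterns, pains)
    return _ALERTS


def alert_pass(mol: ParsedMolecule) -> bool:
    """True iff the molecule hits no MCF-style alert and no PAINS pattern."""
    m = mol.require_valid()
    mcf, pains = _load_alerts()
    if any(m.HasSubstructMatch(p) for p in mcf):
        return False
    return not pains.HasMatch(m)


# --------------------------------------------------------------------------
# Diversity measures on fingerprints

def internal_diversity(
    fps: Sequence[BitVector], p: int = 1, include_self_pairs: bool = False
) -> float:
    """IntDiv_p = 1 - (mean over ordered pairs i != j of Tanimoto^p)^(1/p).

    0 for a single distinct fingerprint; larger is more diverse.  The
    default convention excludes self-pairs so that IntDiv of one molecule is
    exactly 0; ``include_self_pairs`` switches to the convention that
    averages over all n^2 ordered pairs.
    """
    n = len(fps)
    if n == 0:
        raise ValueError("internal_diversity requires at least one fingerprint")
    if n == 1 and not include_self_pairs:
        return 0.0
    sets = [fp.on_bits for fp in fps]
    sizes = [len(s) for s in sets]
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(n):
            if i == j and not include_self_pairs:
                continue
            c = len(sets[i] & sets[j])
            denom = sizes[i] + sizes[j] - c
            sim = c / denom if denom else 1.0
            total += sim**p
            count += 1
    return 1.0 - (total / count) ** (1.0 / p)


def se_div(fps: Sequence[BitVector], threshold: float = 0.65) -> float:
    """Sphere-exclusion diversity: fraction of molecules accepted as sphere centres.

    Greedy pass in input order: a fingerprint becomes a new centre iff its
    Tanimoto similarity to every previously accepted centre is strictly
    below ``threshold``.  1.0 means every molecule is its own centre; a set
    of n identical fingerprints gives exactly 1/n.
    """
    if not fps:
        raise ValueError("se_div requires at least one fingerprint")
    centres: list[frozenset[int]] = []
    centre_sizes: list[int] = []
    for fp in fps:
        bits = fp.on_bits
        nb = len(bits)
        accept = True
        for cbits, cn in zip(centres, centre_sizes):
            c = len(bits & cbits)
            denom = nb + cn - c
            sim = c / denom if denom else 1.0
            if sim >= threshold:
                accept = False
                break
        if accept:
            centres.append(bits)
            centre_sizes.append(nb)
    return len(centres) / len(fps)


def solow_polasky(fps: Sequence[BitVector], theta: float = 1.0) -> float:
    """Solow-Polasky diversity, normalised to (0, 1] by set size.

    With pairwise Tanimoto distances d_ij, F_ij = exp(-theta * d_ij) and the
    raw diversity is D = 1' F^-1 1 (the "effective number of species");
    D/n is returned.  A near-singular F (duplicates) is regularised with a
    ridge of 1e-10 on the diagonal.
    """
    n = len(fps)
    if n == 0:
        raise ValueError("solow_polasky requires at least one fingerprint")
    sets = [fp.on_bits for fp in fps]
    sizes = [len(s) for s in sets]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = len(sets[i] & sets[j])
            denom = sizes[i] + sizes[j] - c
            sim = c / denom if denom else 1.0
            dist[i, j] = dist[j, i] = 1.0 - sim
    f_matrix = np.exp(-theta * dist)
    f_matrix[np.diag_indices(n)] += 1e-10
    ones = np.ones(n)
    d_total = float(ones @ np.linalg.solve(f_matrix, ones))
    return d_total / n


# --------------------------------------------------------------------------
# Intrinsic metrics

def _parse_all(gen: Sequence[str]) -> list[ParsedMolecule]:
    return [parse(s) for s in gen]


def intrinsic_metrics(
    gen: Sequence[str],
    sample_n: int = 1000,
    seed: int = 0,
    se_threshold: float = 0.65,
    sp_theta: float = 1.0,
    include_self_pairs: bool = False,
) -> dict[str, float]:
    """Intrinsic evaluation of a generated SMILES list.

    Internal diversity IntDiv_p = 1 - (mean over ordered pairs i != j of
    Tanimoto(i,j)^p)^(1/p) over ECFP4; sphere-exclusion and Solow-Polasky
    diversity run on a seeded subsample of at most ``sample_n`` unique
    molecules (greedy order = seeded shuffle).  ``include_self_pairs``
    switches IntDiv to the convention that includes i == j pairs.

    With zero valid molecules every downstream metric is NaN, never an
    exception.
    """
    if not gen:
        raise ValueError("empty generated set")
    mols = _parse_all(gen)
    n_total = len(mols)
    valid = [m for m in mols if m.valid]
    out: dict[str, float] = {"n_total": float(n_total), "validity": len(valid) / n_total}
    nan_keys = (
        "uniqueness", "scaffold_uniqueness", "int_div1", "int_div2", "se_div",
        "solow_polasky", "scaffold_diversity", "fg_diversity", "ring_diversity",
        "filters",
    )
    if not valid:
        out.update({k: _UNAVAILABLE for k in nan_keys})
        out["fcd"] = _UNAVAILABLE
        out["purchasability"] = _UNAVAILABLE
        return out

    unique_map: dict[str, ParsedMolecule] = {}
    for m in valid:
        unique_map.setdefault(m.canonical_smiles, m)
    unique = list(unique_map.values())
    n_unique = len(unique)
    out["uniqueness"] = n_unique / len(valid)

    scaffolds = [murcko_scaffold(m) for m in unique]
    out["scaffold_uniqueness"] = len(set(scaffolds)) / n_unique
    out["scaffold_diversity"] = len(set(scaffolds)) / n_unique

    fps = [_ecfp4(m.mol) for m in unique]
    if n_unique == 1:
        out["int_div1"] = 0.0 if not include_self_pairs else 0.0
        out["int_div2"] = 0.0
    else:
        sims = []
        for i, fp in enumerate(fps):
            row = DataStructs.BulkTanimotoSimilarity(fp, fps)
            for j, s in enumerate(row):
                if include_self_pairs or i != j:
                    sims.append(s)
        sims_arr = np.asarray(sims)
        out["int_div1"] = float(1.0 - sims_arr.mean())
        out["int_div2"] = float(1.0 - math.sqrt((sims_arr**2).mean()))

    rng = np.random.default_rng(seed)
    k = min(sample_n, n_unique)
    idx = rng.permutation(n_unique)[:k]
    sample_bvs = [_to_bitvector(fps[i]) for i in idx]
    out["se_div"] = se_div(sample_bvs, threshold=se_threshold)
    out["solow_polasky"] = solow_polasky(sample_bvs, theta=sp_theta)

    fg_counts: Counter[str] = Counter()
    ring_counts: Counter[str] = Counter()
    for m in unique:
        subs = substructure_sets(m)
        fg_counts.update(subs["functional_groups"])
        ring_counts.update(subs["ring_systems"])
    out["fg_diversity"] = (
        len(fg_counts) / sum(fg_counts.values()) if fg_counts else _UNAVAILABLE
    )
    out["ring_diversity"] = (
        len(ring_counts) / sum(ring_counts.values()) if ring_counts else _UNAVAILABLE
    )
    out["filters"] = sum(alert_pass(m) for m in unique) / n_unique
    out["fcd"] = _UNAVAILABLE
    out["purchasability"] = _UNAVAILABLE
    return out


# --------------------------------------------------------------------------
# Reference sets and extrinsic metrics

_PROPERTY_DESCRIPTORS = ("logP", "QED", "MW")


def _property_sample(mol: ParsedMolecule) -> dict[str, float]:
    vals = descriptors(mol, _PROPERTY_DESCRIPTORS)
    sample = {"LogP": vals["logP"], "QED": vals["QED"], "Weight": vals["MW"]}
    try:
        sample["SA"] = synthetic_accessibility(mol)
    except Exception:  # pragma: no cover
        sample["SA"] = _UNAVAILABLE
    try:
        sample["NP"] = natural_product_likeness(mol)
    except Exception:  # pragma: no cover
        sample["NP"] = _UNAVAILABLE
    return sample


@dataclass
class ReferenceSet:
    """Precompiled reference corpus for extrinsic metrics."""

    canonical_set: set[str]
    fps: list  # RDKit ExplicitBitVects, ECFP4/2048
    bit_union: frozenset[int]
    scaffold_counts: Counter
    fragment_counts: Counter
    fg_counts: Counter
    ring_counts: Counter
    property_samples: dict[str, list[float]]

    @classmethod
    def from_smiles(cls, smiles: Iterable[str]) -> "ReferenceSet":
        unique: dict[str, ParsedMolecule] = {}
        for smi in smiles:
            mol = parse(smi)
            if mol.valid:
                unique.setdefault(mol.canonical_smiles, mol)
        if not unique:
            raise ConfigurationError("reference set contains no valid molecules")
        fps = []
        bit_union: set[int] = set()
        scaffold_counts: Counter[str] = Counter()
        fragment_counts: Counter[str] = Counter()
        fg_counts: Counter[str] = Counter()
        ring_counts: Counter[str] = Counter()
        props: dict[str, list[float]] = {}
        for mol in unique.values():
            fp = _ecfp4(mol.mol)
            fps.append(fp)
            bit_union.update(fp.GetOnBits())
            scaffold_counts[murcko_scaffold(mol)] += 1
            subs = substructure_sets(mol)
            fragment_counts.update(subs["fragments"])
            fg_counts.update(subs["functional_groups"])
            ring_counts.update(subs["ring_systems"])
            for k, v in _property_sample(mol).items():
                props.setdefault(k, []).append(v)
        return cls(
            canonical_set=set(unique),
            fps=fps,
            bit_union=frozenset(bit_union),
            scaffold_counts=scaffold_counts,
            fragment_counts=fragment_counts,
            fg_counts=fg_counts,
            ring_counts=ring_counts,
            property_samples=props,
        )


def _cosine_counts(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    if not a or not b:
        return _UNAVAILABLE
    keys = set(a) | set(b)
    va = np.array([a.get(k, 0) for k in keys], dtype=float)
    vb = np.array([b.get(k, 0) for k in keys], dtype=float)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    return float(va @ vb / denom) if denom else _UNAVAILABLE


def extrinsic_metrics(
    gen: Sequence[str],
    ref: ReferenceSet,
    analogue_threshold: float = 0.4,
) -> dict[str, float]:
    """Extrinsic evaluation of a generated set against a reference corpus.

    Computed over the unique valid generated molecules: novelty, single
    nearest-neighbour similarity (SNN), analogue similarity and coverage at
    ``analogue_threshold`` Tanimoto, cosine similarity of the fragment /
    scaffold / functional-group / ring-system count vectors, the mean
    fraction of ECFP4 bits absent from the reference bit union
    ("silliness", flagging idiosyncratic atomic environments), and the 1-D
    Wasserstein distance between property distributions (LogP, SA, NP, QED,
    molecular weight).
    """
    from scipy.stats import wasserstein_distance

    if not gen:
        raise ValueError("empty generated set")
    if not ref.canonical_set:
        raise ConfigurationError("empty reference set")
    unique: dict[str, ParsedMolecule] = {}
    for smi in gen:
        mol = parse(smi)
        if mol.valid:
            unique.setdefault(mol.canonical_smiles, mol)
    out: dict[str, float] = {}
    metric_keys = (
        "novelty", "snn", "analogue_similarity", "analogue_coverage",
        "fragment_similarity", "scaffold_similarity", "fg_similarity",
        "ring_similarity", "silliness",
    )
    if not unique:
        out.update({k: _UNAVAILABLE for k in metric_keys})
        for prop in ref.property_samples:
            out[f"wasserstein_{prop}"] = _UNAVAILABLE
        out["fcd"] = _UNAVAILABLE
        return out

    mols = list(unique.values())
    out["novelty"] = sum(s not in ref.canonical_set for s in unique) / len(unique)

    gen_fps = [_ecfp4(m.mol) for m in mols]
    max_sims = np.array(
        [max(DataStructs.BulkTanimotoSimilarity(fp, ref.fps)) for fp in gen_fps]
    )
    out["snn"] = float(max_sims.mean())
    out["analogue_similarity"] = float((max_sims >= analogue_threshold).mean())
    covered = 0
    for rfp in ref.fps:
        sims = DataStructs.BulkTanimotoSimilarity(rfp, gen_fps)
        if max(sims) >= analogue_threshold:
            covered += 1
    out["analogue_coverage"] = covered / len(ref.fps)

    gen_scaffolds: Counter[str] = Counter(murcko_scaffold(m) for m in mols)
    gen_frag: Counter[str] = Counter()
    gen_fg: Counter[str] = Counter()
    gen_ring: Counter[str] = Counter()
    for m in mols:
        subs = substructure_sets(m)
        gen_frag.update(subs["fragments"])
        gen_fg.update(subs["functional_groups"])
        gen_ring.update(subs["ring_systems"])
    out["fragment_similarity"] = _cosine_counts(gen_frag, ref.fragment_counts)
    out["scaffold_similarity"] = _cosine_counts(gen_scaffolds, ref.scaffold_counts)
    out["fg_similarity"] = _cosine_counts(gen_fg, ref.fg_counts)
    out["ring_similarity"] = _cosine_counts(gen_ring, ref.ring_counts)

    silliness = []
    for fp in gen_fps:
        bits = set(fp.GetOnBits())
        if bits:
            silliness.append(len(bits - ref.bit_union) / len(bits))
    out["silliness"] = float(np.mean(silliness)) if silliness else _UNAVAILABLE

    gen_props: dict[str, list[float]] = {}
    for m in mols:
        for k, v in _property_sample(m).items():
            gen_props.setdefault(k, []).append(v)
    for prop, ref_sample in ref.property_samples.items():
        sample = [v for v in gen_props.get(prop, []) if math.isfinite(v)]
        ref_vals = [v for v in ref_sample if math.isfinite(v)]
        out[f"wasserstein_{prop}"] = (
            float(wasserstein_distance(sample, ref_vals))
            if sample and ref_vals
            else _UNAVAILABLE
        )
    out["fcd"] = _UNAVAILABLE
    return out


class MetricsCalculator:
    """Convenience wrapper: intrinsic metrics plus extrinsic per reference set.

    ``references`` maps a name to a :class:`ReferenceSet` or a SMILES list;
    extrinsic metric keys are prefixed ``{name}_``.
    """

    def __init__(
        self,
        references: Mapping[str, ReferenceSet | Sequence[str]] | None = None,
        sample_n: int = 1000,
        analogue_threshold: float = 0.4,
    ):
        self.references: dict[str, ReferenceSet] = {}
        for name, ref in (references or {}).items():
            if not isinstance(ref, ReferenceSet):
                ref = ReferenceSet.from_smiles(ref)
            self.references[name] = ref
        self.sample_n = sample_n
        self.analogue_threshold = analogue_threshold

    def calculate(self, gen: Sequence[str], seed: int = 0) -> dict[str, float]:
        report = intrinsic_metrics(gen, sample_n=self.sample_n, seed=seed)
        for name, ref in self.references.items():
            ext = extrinsic_metrics(gen, ref, analogue_threshold=self.analogue_threshold)
            report.update({f"{name}_{k}": v for k, v in ext.items()})
        return report


# --------------------------------------------------------------------------
# Chunked statistics over run records

def statistics_by_n(
    records: pd.DataFrame | str | os.PathLike,
    n: int | str,
    smiles_column: str = "input_smiles",
    sample_n: int = 250,
    seed: int = 0,
    references: Mapping[str, ReferenceSet] | None = None,
) -> pd.DataFrame:
    """Evaluation metrics and basic statistics over chunks of a run record.

    ``n`` is either a chunk size (consecutive groups of n molecules) or the
    name of a column to group by (e.g. ``"step"``).  Each output row carries
    the intrinsic metrics of the chunk's molecules (plus extrinsic metrics
    for any ``references``) and the mean, median and standard deviation of
    every numeric column.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records)
    if smiles_column not in records.columns:
        raise ConfigurationError(
            f"column {smiles_column!r} not in records; available: {list(records.columns)}"
        )
    if isinstance(n, str):
        if n not in records.columns:
            raise ConfigurationError(
                f"column {n!r} not in records; available: {list(records.columns)}"
            )
        groups = [(key, grp) for key, grp in records.groupby(n, sort=True)]
    else:
        if n < 1:
            raise ValueError("chunk size must be >= 1")
        groups = [
            (i // n + 1, records.iloc[i : i + n]) for i in range(0, len(records), n)
        ]
    numeric = records.select_dtypes(include="number").columns
    rows = []
    for key, grp in groups:
        row: dict[str, float] = {"group": key, "n_molecules": float(len(grp))}
        gen = [s for s in grp[smiles_column].astype(str) if s]
        if gen:
            row.update(intrinsic_metrics(gen, sample_n=sample_n, seed=seed))
            for name, ref in (references or {}).items():
                ext = extrinsic_metrics(gen, ref)
                row.update({f"{name}_{k}": v for k, v in ext.items()})
        for col in numeric:
            values = grp[col].dropna()
            if values.empty:
                row[f"{col}_mean"] = row[f"{col}_median"] = row[f"{col}_std"] = _UNAVAILABLE
                continue
            row[f"{col}_mean"] = float(values.mean())
            row[f"{col}_median"] = float(values.median())
            row[f"{col}_std"] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
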
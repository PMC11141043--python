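# Methods

This note documents the models, conventions and numerical choices behind
`genscore`, in the order the pipeline applies them.

## Parsing and canonical forms

Molecules are parsed with RDKit; anything RDKit rejects is treated as an
invalid *value* (final score 0), never as an error — long optimisation runs
must survive malformed generator output. The canonical form is RDKit's
default canonical isomeric SMILES, and uniqueness/caching comparisons use
it, so stereoisomers are distinct molecules. Canonicalisation is idempotent
and the test-suite asserts it on generated libraries.

## Fingerprints and similarity

Seven fingerprint families are exposed (Morgan/ECFP, atom-pair, topological
torsion, MACCS keys, RDKit path, Avalon, Gobbi 2-D pharmacophore). The
default for every similarity-based component is ECFP with radius 2 hashed to
2048 bits ("ECFP4"), the de facto standard in the de novo design
literature; using one family everywhere keeps diversity filters, nearest-
neighbour metrics and analogue detection mutually comparable.

Binary similarity coefficients (Tanimoto, Dice, cosine, all-bit,
asymmetric, Braun–Blanquet, Kulczynski, McConnaughey, Russel, on-bit,
Rogot–Goldberg, Sokal) are computed from the four set counts (|A|, |B|,
|A∩B|, bit-space size) with the formulas stated in the source; the tests
cross-check every coefficient against RDKit's `DataStructs`
implementations on random vectors. McConnaughey is natively in [−1, 1] and
is affinely rescaled to [0, 1] so all exposed coefficients share one
codomain (the raw value remains available as `raw_similarity`). Counted
fingerprints (atom-pair, torsion) use the min/max-count generalisation for
Tanimoto and are binarised for the other coefficients.

## Scorers

- **Descriptors** delegate to RDKit (MW in Da, TPSA in Å², Crippen logP,
  Lipinski donor/acceptor counts, QED, …).
- **Penalised logP** is logP − SA − (# rings larger than 6 in the SSSR),
  with the synthetic-accessibility score from the toolkit's contrib
  implementation. The value is reported on its natural scale; no
  training-set z-normalisation is applied, since that would tie the score
  to a specific corpus.
- **Maximum consecutive rotatable bonds** uses the strict rotatable-bond
  SMARTS `[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]` with amide C–N bonds excluded,
  and reports the longest simple path (counted in bonds) through the
  adjacency graph of rotatable bonds, found by depth-first search. A
  brute-force path-enumeration oracle (networkx) confirms it in tests.
- **Isomer similarity** scores agreement with a molecular formula as the
  geometric mean of per-element Gaussian terms exp(−Δ²/2) (σ = 1 count
  unit) over every element in either formula, plus one term of the same
  form on the total heavy-atom count. It is 1 exactly when the composition
  matches and strictly decreases with any deviation.
- **Substructure match/filter** compiles all SMARTS at configuration time;
  `filter` is the exact complement of `match_any` (alert semantics).
- **Applicability domain**: maximum Tanimoto to a training set, or the
  fraction of a descriptor list inside the training min/max box. "Feature
  range" and "physchem range" are the same mechanism over two configurable
  descriptor lists, serialisable to JSON.
- A generic **tabulated model** slot (mapping or callable over canonical
  SMILES) stands in for trained predictive models, keeping that position in
  the architecture exercisable without shipping weights.

Scorers are pure functions of the canonical SMILES; the pipeline may
evaluate a batch through any order-preserving map (`map_fn`), and a thread
pool reproduces serial results bit-for-bit (asserted in tests).

## Transforms and aggregation

All transforms map ℝ → [0, 1]; values within 1e−9 outside the interval from
floating error are clamped. The running max–min normalisation returns 0.5
until two distinct values have been seen — a neutral desirability while no
range exists. Non-finite raw values score 0 with a logged warning.

Weights are normalised internally, so user weights need not sum to one.
The auto-weighted kinds recompute weights per molecule as
wᵢ = (1 − sᵢ) + ε with ε = 0.01: objectives that are nearly satisfied lose
influence and the weakest objective dominates; ε keeps fully-satisfied
objectives from vanishing entirely. This is this package's reading of
"auto-weighting"; the formula is documented here and unit-tested.

The Pareto aggregation is batch-wise: the batch's transformed score vectors
are non-dominated sorted and front rank r of R fronts maps to
1 − (r − 1)/R, so the best front scores 1 and ties within a front share a
value. Because it is defined only relative to a batch, Pareto desirability
is recomputed per batch even for cached molecules.

## Diversity filters

Bucket-overflow kinds (identical Murcko scaffold, identical generic
framework, and the leader-clustering similarity kinds) zero the score of
any molecule arriving at a bucket that already holds `nbmax` members
(default 25); the overflowing molecule is not appended, so a bucket never
exceeds its capacity. `Unique` zeroes every repeat of an already-recorded
canonical SMILES, and `Occurrence` decays the score gradually:
scale = max(0, 1 − max(0, seen − tolerance)/buffer) with tolerance 5 and
buffer 5 by default. Only molecules scoring at least `minscore` (default
0.5) enter the memory; sub-threshold molecules are never penalised and
never recorded. Leader clustering ties (two equally-similar centroids) join
the earlier-created cluster for determinism. All defaults are exposed in
the configuration; the hard-zero penalty follows the memory-assisted
scheme standard in reinforcement-learning molecule generators.

Interaction with caching: raw, transformed and aggregate values are cached
per canonical SMILES, but the diversity penalty is *not* — the memory
evolves over the run and a repeated molecule is by definition non-diverse,
so penalisation is re-applied at every evaluation.

## Evaluation metrics

Intrinsic metrics operate on the unique valid molecules of a set. Internal
diversity IntDiv_p = 1 − (mean over ordered pairs i ≠ j of T(i,j)^p)^(1/p);
self-pairs are excluded so a single distinct molecule gives exactly 0 (the
convention that includes them is behind a flag, as some suites average over
all n² pairs). Sphere-exclusion diversity does a greedy pass accepting a
molecule iff its Tanimoto to every accepted centre is below 0.65, on a
seed-shuffled subsample of at most `sample_n` (default 1000) molecules.
Solow–Polasky diversity is D = 1ᵀF⁻¹1 with F = exp(−θ·d), θ = 1 by
default, normalised by set size to (0, 1]; a ridge of 1e−10 regularises
duplicate rows. Functional groups use Ertl's perception algorithm (toolkit
contrib), ring systems are fused-ring components with exocyclic
double-bonded atoms retained, fragments are BRICS leaves. The alert pass
rate combines a curated list of reactive/unstable-group SMARTS shipped with
the package and the toolkit's PAINS catalog.

Extrinsic metrics use ECFP4 throughout: novelty (canonical SMILES absent
from the reference), SNN (mean nearest-neighbour Tanimoto), analogue
similarity/coverage at threshold 0.4 (coverage is normalised by the
*reference* size — the natural reading of "coverage"), cosine similarity of
substructure count vectors, silliness (mean fraction of a molecule's bits
outside the reference bit union), and 1-D Wasserstein distances for logP,
SA, NP, QED and molecular weight. The Fréchet ChemNet Distance and
catalogue purchasability require trained weights or an external catalogue
and are reported as NaN placeholders so report schemas stay stable.

With zero valid molecules every downstream metric is NaN, never an
exception.

## Synthetic libraries and the demo optimizer

The fixture generator enumerates drug-like SMILES from a grammar of
scaffolds (alkanes, substituted benzenes, pyridines, piperazines, fused
bicyclics) and decorations, seeded and fully deterministic, with an exact
requested fraction of syntactically corrupted entries — emulating the mix
of valid, repeated and malformed SMILES a generative model emits. It does
not emulate the learned chemistry of a real generator (no activity cliffs,
no training-set bias, property ranges narrower than ChEMBL-like corpora),
so passing tests demonstrate pipeline correctness, not chemical quality of
any model.

The demo optimizer resamples the pool with weights exp(score/temperature)
(temperature 0.1 by default) using the last known scores: a minimal
hill-climbing stand-in that exercises the three-call integration contract
(initialise, score a batch, repeat) without any neural model. Default
problem sizes — pool 500, 30 batches of 64 — complete in seconds and are
also the sizes the acceptance script reports.

## Benchmark mode

A benchmark is a list of objective configurations (or a named preset) plus
a per-objective molecule budget; each objective's `finished` flag flips
once the number of evaluated molecules reaches the budget. On exit the
intrinsic metric suite runs over every objective's records and a one-row-
per-objective `benchmark_summary.csv` is written. The bundled `demo`
preset builds two fingerprint-similarity objectives from the fixture
library; presets needing external reference corpora are out of scope.

## Known limitations

- Scoring functions that require external executables, servers, licences
  or trained weights (docking, 3-D alignment, retrosynthesis, bioactivity
  models) are outside this package; the tabulated-model slot marks where
  they would plug in.
- The running normalisation makes desirability values incomparable across
  runs (the goal post moves); compare raw columns instead.
- Pharm2D fingerprints use the toolkit's Gobbi feature factory and are
  substantially slower than the hashed families.
- The rotatable-bond path search is exponential in the worst case; for
  drug-like molecules (tens of rotatable bonds, tree-like) it is
  effectively instantaneous.
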
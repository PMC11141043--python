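# genscore

Configuration-driven scoring, diversity filtering and evaluation of de novo
generated molecules.

Generative models for molecular design propose batches of SMILES and need a
scalar reward per molecule. In practice that reward is a *multi-parameter
objective*: several scoring functions (physicochemical descriptors,
similarity to references, substructure matches, applicability-domain
checks), each mapped into a desirability on [0, 1] by a transformation
function and collapsed by an aggregation function, optionally penalised by a
stateful diversity filter so the model cannot collapse onto one rewarding
scaffold. `genscore` implements this pipeline, a suite of intrinsic and
extrinsic evaluation metrics for the resulting molecule sets, and a
benchmark mode that runs several budgeted objectives and summarises them —
all driven by a JSON configuration file, so objectives are shareable and
reproducible without writing code.

The package is aimed at researchers building or evaluating generative
models: the scoring pipeline plugs into any model that can emit SMILES, and
the metrics run on any `.smi` file.

## The model

For a molecule *m* with raw scorer outputs *x₁ … x_k*, each parameter is
transformed by one of

- running max–min normalisation: *(x − min_seen)/(max_seen − min_seen)*,
  with the extremes updated during the run ("moving goal post"),
- linear ramp of width *b* ending at threshold *t*,
- Gaussian *exp(−(x − μ)²/2σ²)*, optionally one-sided,
- hard window: 1 on [low, high], 0 outside,

and the transformed vector **s** is aggregated by weighted/arithmetic mean,
(weighted/geometric) product, dynamically auto-weighted variants
(*wᵢ ∝ (1 − sᵢ) + ε*, emphasising the least-satisfied objective), or a
Pareto non-dominated-sort rank scalarised to [0, 1]. Parameters marked as
*filters* instead multiply the aggregate. A diversity filter assigns each
molecule to a cluster (canonical SMILES, Murcko scaffold, generic framework,
or leader clustering on fingerprint similarity) and zeroes the score once a
cluster holds `nbmax` members.

Evaluation metrics include validity, uniqueness, internal diversity
(IntDiv₁/₂ over ECFP4 Tanimoto), sphere-exclusion diversity, Solow–Polasky
diversity, scaffold/functional-group/ring-system diversity and alert pass
rate (intrinsic); and novelty, single-nearest-neighbour similarity, analogue
similarity/coverage, substructure-vocabulary cosine similarities, outlier
fingerprint bits ("silliness") and 1-D Wasserstein distances of property
distributions (extrinsic).

## Worked example

A blood-brain-barrier-style multi-window objective (TPSA < 70, H-bond
donors ≤ 1, logP in [2, 4], MW < 400 Da, arithmetic mean):

```python
from genscore import Pipeline

config = {
    "task_name": "bbb_mpo",
    "output_dir": "bbb_mpo",
    "scorers": [
        {"name": "phys", "kind": "descriptors",
         "params": {"names": ["TPSA", "HBD", "logP", "MW"]}}
    ],
    "parameters": [
        {"source": "phys_TPSA", "transform": {"kind": "step_threshold", "direction": "minimize", "high": 70}},
        {"source": "phys_HBD",  "transform": {"kind": "step_threshold", "direction": "minimize", "high": 1}},
        {"source": "phys_logP", "transform": {"kind": "step_threshold", "direction": "range", "low": 2, "high": 4}},
        {"source": "phys_MW",   "transform": {"kind": "step_threshold", "direction": "minimize", "high": 400}},
    ],
    "aggregation": {"kind": "amean"},
}
pipe = Pipeline(config, write_csv=False)
batch = ["c1ccc(CCc2ccccc2)cc1", "CCO", "OCC(O)C(O)C(O)CO", "not_a_smiles"]
for smi, s in zip(batch, pipe.score(batch)):
    print(f"{smi:24s} {s:.2f}")
```

prints

```
c1ccc(CCc2ccccc2)cc1     1.00
CCO                      0.75
OCC(O)C(O)C(O)CO         0.25
not_a_smiles             0.00
```

Bibenzyl sits inside all four windows (score 1.00); ethanol misses only the
logP window (3 of 4 → 0.75); the tetraol misses TPSA, donors and logP
(0.25); the unparseable string scores 0 by contract. Repeated calls to
`pipe.score(...)` auto-increment the step counter, reuse cached scores for
previously seen molecules, and write one CSV per iteration plus a full
`scores.csv` on `pipe.finalize()`.

The same machinery is available from a shell:

```bash
genscore score --config cfg.json --smiles batch.smi
genscore evaluate --gen de_novo.smi --ref training.smi --out report.csv --seed 1
genscore stats-by-n --records scores.csv --column step --out per_step.csv
genscore benchmark --preset demo --budget 100 --seed 0 --out bench/
genscore demo --config cfg.json --batches 30 --batch-size 64 --seed 1
```

`genscore demo` drives the objective with a bundled score-weighted
resampling optimizer over a synthetic molecule pool — a deterministic
stand-in for a generative model that exercises the whole iterative loop.

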
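# pseusite

Prediction of RNA pseudouridine (Ψ) sites from fixed-length,
uridine-centred sequence windows, using a stacking ensemble whose
intermediate representation — the **RNA profile** — is re-weighted by a
particle swarm.

Pseudouridine is the most abundant internal RNA modification, and mapping
it experimentally is expensive; sequence-based predictors fill the gap.
This package is for computational biologists who want a transparent,
retrainable implementation of the profile-stacking architecture: every
stage is an importable function with explicit seeds, and every design
choice is documented in `docs/methods.md`.

## The method

Given λ-nt windows centred on a candidate U (λ = 21 or 31 in the usual
benchmarks), each window is encoded six ways — one-hot of k-nucleotides
(dimension 4^k(λ−k+1)) and k-mer frequencies (dimension 4^k), for
k = 1, 2, 3.  Five tree-ensemble families (ADA, GBDT, XGB, RF, ET) are
fitted per encoding after a two-step feature selection that sweeps the
distinct feature-importance values as keep-thresholds.  Out-of-fold
probabilities from the resulting 30 base classifiers form the RNA profile
x ∈ [0,1]^30 of each sequence.  A particle swarm then searches weights
w ∈ [0,1]^30 maximising the 10-fold cross-validated accuracy of a logistic
regression on x ⊙ w, and that logistic model is the final classifier.
Performance is reported as ACC, SN, SP and MCC from pooled confusion
counts.

## Worked example

```bash
pseusite simulate --preset human-like -n 120 --out train.fasta --seed 0
pseusite train --train train.fasta --out bundle --fast --seed 0
pseusite simulate --preset human-like -n 40 --out test.fasta --seed 99
pseusite predict --model bundle --input test.fasta --out preds.tsv --score
```

which prints (numbers from this exact command sequence):

```
240 windows (21 nt, preset human-like, strength 0.45, seed 0) written to train.fasta
training on 240 windows of 21 nt (30-dim profile)
swarm fitness: 0.9750 after 20 iterations
bundle written to bundle
80 windows (21 nt, preset human-like, strength 0.45, seed 99) written to test.fasta
80 predictions written to preds.tsv
ACC=0.963 MCC=0.925 SN=0.950 SP=0.975
```

The swarm fitness (0.975) is the 10-fold CV accuracy of the
meta-classifier at the best weights found; the last line scores the 80
held-out windows — on this strongly enriched synthetic preset the planted
A/U-vs-C/G contrast beside the centre U is recovered almost perfectly.
`preds.tsv` has one row per input window: id, Ψ-site probability, and the
0.5-threshold call.

The same pipeline is available as a library — see `examples/` for short
scripts covering generation, encodings and the profile, training, and the
stack-vs-PSO comparison:

```python
from pseusite import PipelineConfig, cross_validate, default_specs, generate

data = generate(default_specs(n_pos=200, n_neg=200, seed=11)["human-like"])
results = cross_validate(data, PipelineConfig.fast(seed=1), n_folds=10)
print(results["pso"].pooled.as_dict())
```

`PipelineConfig.default()` is the full-size architecture (100-estimator
ensembles, 60 × 100 swarm); `PipelineConfig.fast()` keeps the same
30-column structure at CI-friendly sizes.

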
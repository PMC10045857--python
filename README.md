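# elmseizure

Seizure-vs-non-seizure recognition of chunked EEG with an Extreme Learning
Machine (ELM), connection-weight feature selection, and a full evaluation
harness — exercisable end-to-end on a built-in synthetic data generator, no
download required.

## Who this is for

The package targets the tabular form of the Bonn EEG corpus distributed as
the UCI "Epileptic Seizure Recognition" dataset: one row per 1-second EEG
chunk, 178 integer amplitude columns `X1..X178`, and a label column `y` in
{1..5} where 1 is ictal (recorded during a seizure) and 2–5 are non-seizure
conditions (pre-ictal, inter-ictal, healthy eyes closed, healthy eyes open).
The five classes collapse to a binary target (seizure = 1, everything else
= 0), giving 2300 positive vs 9200 negative rows in the canonical
11,500-row table.

## The model

An ELM is a single-hidden-layer feedforward network

```
f(x) = Σⱼ βⱼ · σ(wⱼ·x + bⱼ),      σ(z) = 1 / (1 + e⁻ᶻ)
```

whose hidden parameters are never trained: the input weights `W` (L×m,
uniform in [−1, 1]) and biases `b` (uniform in [0, 1]) are drawn once and
frozen. With `H` the n×L hidden-layer output matrix, the output weights are
the minimum-norm least-squares solution

```
β = H⁺ Y
```

where `H⁺` is the Moore–Penrose pseudoinverse (SVD with a relative
singular-value cutoff). There is no backpropagation and no iteration; one
linear solve trains the network. The hidden-layer size defaults to the
one-tenth heuristic `L = round(0.1 · n_train)` (9200 training rows → 920
neurons); a validation-accuracy sweep is also provided.

Feature importance is read off the trained weights: significance
coefficients `C[i,k] = Σⱼ β[j,k]·tanh(W[j,i]/2)`, squashed to magnitudes
`R = |tanh(C/2)|`, normalized per output to influence shares `S` (columns
sum to 1), and averaged over outputs into feature weights `W_feat`.
High-weight features are retained (mean-threshold or top-k policy).

## Worked example

```python
from elmseizure import (
    CANONICAL_SPLITS, ExperimentConfig, SynthConfig, run_experiment,
)

cfg = ExperimentConfig(
    source=SynthConfig(seed=1),            # synthetic Bonn-like table, 11,500 x 178
    split_specs=CANONICAL_SPLITS(seed=1),  # 80/20 (halved holdout), 70/30, 60/40
    seed=1,
)
print(run_experiment(cfg).to_string(index=False))
```

prints

```
Model    Phase  Accuracy %  Dataset Division %  Samples  Prevalence  Precision   Recall  F1-Score  Specificity  Sensitivity      AUC
  ELM Training     99.6196                80.0     9200         0.2   0.998894 0.982065  0.990408     0.999728     0.982065 0.999713
  ELM  Testing     97.5652                10.0     1150         0.2   0.985577 0.891304  0.936073     0.996739     0.891304 0.997046
  ELM Training     99.4534                70.0     8050         0.2   0.995570 0.977019  0.986207     0.998913     0.977019 0.999695
  ELM  Testing     96.6957                30.0     3450         0.2   0.980000 0.852174  0.911628     0.995652     0.852174 0.987213
  ELM Training     99.3043                60.0     6900         0.2   0.995536 0.969565  0.982379     0.998913     0.969565 0.999651
  ELM  Testing     96.9565                40.0     4600         0.2   0.983871 0.861957  0.918888     0.996467     0.861957 0.990615
```

Each protocol contributes one Training and one Testing row. At the 80%
ratio the holdout is halved, so the 11,500 rows split 9200/1150/1150
(train/validation/test) and the Testing row covers 10% of the data; the
one-tenth heuristic picks 920, 805 and 690 hidden neurons for the three
ratios. Accuracy is a percentage; prevalence (the seizure fraction),
precision, recall/sensitivity, F1, specificity and AUC are fractions.
Training accuracy exceeds testing accuracy, and the 80% ratio generalizes
best — with less training data the one-shot linear solve underfits.

The same pipeline is available from the shell:

```
elmseizure synth --out data.csv --seed 1
elmseizure run --data data.csv --outdir results/run1 --seed 1
elmseizure compare --synthetic --outdir results/cmp --seed 1   # + KNN, NB, LR, RF, DT, SGDC, GB, ANN
```

`run` writes `report.csv` (deterministic under a fixed seed) and
`manifest.json` (config, seeds, versions, timings). Real UCI-dialect CSVs
are accepted anywhere the synthetic table is.

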
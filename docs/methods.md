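# Methods

## Problem and data model

The package classifies 1-second EEG chunks (178 samples at 178 Hz, raw ADC
amplitudes in roughly −1415..2047) as seizure (ictal) or non-seizure. The
canonical table has five classes of 2300 chunks each — ictal, pre-ictal,
inter-ictal, healthy eyes-closed, healthy eyes-open — collapsed to a binary
target with prevalence 0.2. Rows are treated as i.i.d. feature vectors; no
temporal structure across chunks is modelled.

## The classifier

A single-hidden-layer feedforward network with L sigmoid units. Input
weights `W ~ U[−1, 1]^(L×m)` and biases `b ~ U[0, 1]^L` are drawn once from
a seeded generator and frozen; the only learned parameters are the output
weights `β = H⁺Y`, the minimum-norm least-squares solution for the hidden
output matrix `H[r,j] = σ(w_j·x_r + b_j)`. The solve uses SVD with relative
singular-value cutoff `max(n, L)·ε` by default (`pinv_rtol` configurable);
no ridge term is added. The sigmoid is evaluated through `scipy.special.expit`,
which is overflow-free for saturated pre-activations.

Targets: binary problems use a single output column on {0,1} with decision
threshold 0.5 (a boundary score counts as positive); K-class problems use
one-hot columns with arg-max decoding, ties resolved to the lowest class
index.

Hidden-layer size: the default is the one-tenth heuristic
`L = round(0.1·n_train)` (920/805/690 at the three canonical ratios). The
alternative is a validation sweep over a grid of quarter-multiples of that
anchor; each grid point draws a fresh hidden layer sub-seeded from
(seed, L), and the smallest L attaining maximal validation accuracy wins.
ELM as implemented has no pruning of hidden units; accuracy can degrade for
very large L through overfitting of the least-squares solve, which is what
the sweep guards against.

## Data preparation

Rescaling standardizes each feature column to zero mean and unit variance
using the *population* variance convention (divide by n), so a two-point
column maps to ±1. Parameters are fitted on the training partition only and
applied unchanged to validation/test — fitting on the full table would leak
holdout statistics into training. Zero-variance columns are dropped with a
warning by default (configurable to raise).

Splitting allocates `round(train_frac·n)` rows to training. The 80/20
protocol halves the holdout into validation and test (11,500 →
9200/1150/1150); 70/30 and 60/40 use plain two-way splits. Stratification
is on by default and apportions each class by largest remainder, test
partition first, so the test prevalence matches the full table within one
row. An optional `balance_train` mode duplicates minority-class training
rows to 50/50 prevalence; it is off by default and not part of the
canonical protocol.

## Feature selection

Connection-weight analysis of a trained network, in four steps:
`C[i,k] = Σⱼ β[j,k]·g(W[j,i])` with `g(x) = (1−e^(−x))/(1+e^(−x)) = tanh(x/2)`;
`R = |tanh(C/2)|`; `S = R` normalized per output column; `W_feat` the
per-feature mean of `S` over outputs. The `tanh(x/2)` form is used because
the literal exponential ratio overflows for large negative arguments; the
two agree to ~1e−12 over the operating range (property-tested). Selection
keeps features with weight ≥ mean weight (parameter-free default) or the
top k, ties to the lower index. An alternative reading of the final step —
averaging over features instead of outputs — yields a constant 1/m and
carries no ranking information; it is kept behind `as_printed=True` purely
for auditability. The canonical experiments run on all 178 features;
selection is opt-in.

## Evaluation

Binary confusion counts with positive class 1; the panel reports accuracy,
prevalence, precision, recall, F1, specificity, sensitivity and AUC, where
recall and sensitivity are the same quantity emitted twice for schema
compatibility with reports that list both columns. Zero-denominator ratios
return 0 and set a `degenerate` flag instead of raising, so sweep loops
never abort on a degenerate fold. The ROC curve sweeps all distinct score
thresholds with tied scores grouped into a single step; AUC is the
trapezoidal integral, equivalent to Mann–Whitney pair counting with half
credit for ties, which is implemented independently (rank sums) as a
cross-check. The identity accuracy = prevalence·sensitivity +
(1−prevalence)·specificity is property-tested exactly.

## Synthetic data generator

Every class is an AR(2)-filtered Gaussian process (coefficients 1.35,
−0.45 — a stable low-pass resembling band-limited background activity) at a
class-specific innovation scale; the ictal class additionally carries a
high-amplitude ~3 Hz spike-and-wave burst (fundamental plus a cubed third
harmonic, random phase, gated over at least half of each chunk). Values are
clipped to [−1415, 2047]. Defaults: innovation scales 100/22/15/10/6 for
classes 1–5, burst amplitude 800, burst probability 1 (a chunk recorded
during a seizure is ictal throughout). These scales were chosen so that the
non-seizure classes remain inside the sigmoid's informative range after
standardization while ictal rows saturate it — when two classes both
saturate the units, amplitude information beyond the saturation point is
lost and the linear readout cannot separate them. Under the defaults the
reference configuration (80/20, L = 920) reaches ≈97–98% test accuracy and
AUC ≥ 0.99.

What the generator does *not* emulate: electrode montage, 1/f spectral
shape, artifacts, inter-subject variability beyond independent draws, or
any physiological seizure morphology beyond "high-amplitude rhythmic
discharge". Passing tests therefore demonstrate that the pipeline's
mechanics are correct and that the classifier detects planted
amplitude/rhythm structure of the right shape and scale — not clinical
performance on real EEG. Real tables in the same CSV dialect can be run
through the identical protocol.

A second generator produces two unit-variance Gaussian clouds separated by
a configurable margin, used for oracle tests; with `n_informative` set, the
shift is supported on that many coordinates with equal magnitude and random
signs, a planted-feature setup for selection-recovery tests (equal
magnitudes ensure every planted feature carries the same signal, so
"informative" is well-defined).

## Numerical choices and degenerate inputs

- Pseudoinverse cutoff `max(n, L)·ε·σ_max`; instances whose hidden matrix is
  near rank-deficient (e.g. near-linear activations) yield large-norm
  minimum-norm solutions — the solver handles them, but oracle-equivalence
  checks use well-conditioned instances because absolute agreement between
  two SVD routes is meaningless when ‖β‖ ~ 1e7.
- Deterministic sub-seeding everywhere via `SeedSequence` on integer parts
  (`derive_seed`), kept below 2³¹.
- Threshold convention: score exactly at threshold → positive.
- Reports round to 4–6 decimals and are byte-identical under a fixed seed;
  wall-clock timings are recorded in the run manifest, not the report, so
  determinism of the report bytes is preserved.
- Already-binary labels fed to the binarizer raise (prevents accidental
  double relabelling); empty inputs, single-class ROC, zero-count confusion
  matrices and out-of-range split fractions raise `ValueError`.

## Baselines

KNN, Gaussian NB, logistic regression, random forest, decision tree, SGD
(logistic loss), gradient boosting and an MLP are thin scikit-learn
adapters fitted on the identical partitions, for comparison tables only;
they are not part of the core method. An LSTM baseline is declared but
skipped with a warning, as no deep-learning runtime is a dependency of this
package.

## Known limitations

- The one-shot least-squares solve is O(n·L²) memory/time; very large L on
  large tables is the practical bottleneck (the canonical 9200×920 solve
  takes a few seconds on one CPU).
- Feature ranking from a single random hidden layer is noisy; rankings
  stabilize with larger L and can differ between seeds.
- The mean-threshold selection policy has no statistical guarantee; it is a
  parameter-free heuristic.
- Multi-class support (one-hot) is functional but the metric panel is
  binary-only by design.
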
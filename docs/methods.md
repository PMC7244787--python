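# Methods

## Model

`smurf` addresses binary classification under extreme class imbalance by a
hyper-ensemble: an ensemble of random forests, each of which is itself an
ensemble of decision trees. The negatives are partitioned into `nParts`
disjoint, near-equal parts by a uniformly random shuffle; each part is
joined with the complete positive set, rebalanced, and used to train one
forest. The consensus score of a sample is the arithmetic mean over the
forests of their positive-class probabilities, each forest's probability
being the mean over its trees of the leaf class-proportion estimate (the
standard probability-forest rule; tree-level hard voting is not used).

Rebalancing combines two mechanisms:

* **SMOTE oversampling.** For each original positive `p`, `fp` synthetic
  positives are generated as `p + u·(q − p)` with `u ~ U[0,1)` and `q`
  drawn uniformly (independently per synthetic row) from the `k` nearest
  positive neighbours of `p` under Euclidean distance on the raw features,
  `p` itself excluded. `k` is clamped to `n_pos − 1` when it exceeds the
  pool. Because every part contains the same positives, the k-NN table is
  computed once per training run and shared across parts. `fp = 0` disables
  oversampling and is allowed as a baseline.
* **Uniform undersampling.** Each part contributes
  `min(ratio · (1 + fp) · n_pos, negatives in the part)` negatives, drawn
  without replacement. When a part holds enough negatives, the resulting
  negative:positive ratio is exactly `ratio`. The `min` rule is a deliberate
  degenerate-case choice: a part that cannot meet the target silently
  contributes everything it has rather than failing.

### Hyper-parameters

| name | meaning | default |
|---|---|---|
| `n_parts` | parts of the negative partition = forests in the ensemble | 100 |
| `fp` | synthetic positives per original positive (SMOTE factor) | 2 |
| `ratio` | negatives per effective (original + synthetic) positive | 3 |
| `k` | SMOTE nearest-neighbour count | 5 |
| `n_trees` | trees per forest | 10 |
| `m_try` | candidate features per split node | 5 |

All are dimensionless positive integers (`fp` may be 0). The defaults are
the method's conventional operating point for variant-prioritization data.
Trees are fully grown (the forest backend's default depth limits); only
`n_trees` and `m_try` are controlled, all other forest settings are the
scikit-learn defaults.

## Determinism and parallelism

Reproducibility is achieved by contract rather than by scheduling: the RNG
stream of part `i` is `SeedSequence(master_seed, spawn_key=(i,))`, which
also seeds that part's forest. Parts are grouped into `q` near-equal chunks
(one per worker, sizes differing by at most one) and dispatched to a
thread pool; since no part's stream depends on any other part or on the
chunking, the trained model — and every downstream score — is bit-identical
for any worker count. The multi-node message-passing execution model of
large-cluster deployments is out of scope; the chunk abstraction and the
invariance contract are what is kept.

## Cross-validation

* **Stratified k-fold** splits each class as evenly as possible
  (per-class fold counts differ by at most one), shuffled by seed.
* **Band-aware k-fold** assigns entire cytogenetic bands (or any
  locality-group labels) to folds so nearby variants never straddle the
  train/test boundary. The balancing rule is longest-processing-time
  greedy: bands sorted by descending positive count (ties: descending total
  size, then band id) are placed one by one into the fold currently
  lightest in positives (ties: smallest total size, then lowest fold
  index). The rule is deterministic; the greedy bound guarantees the
  max−min fold positive spread never exceeds the largest band's positive
  count. Grouped CV only constrains *which* samples co-occur, so any
  deterministic balanced assignment is valid; LPT was chosen as the
  standard balanced-partition heuristic.
* **Per-region-balanced subsampling** equalises the negative:positive
  imbalance across regulatory-region categories: the target `r*` is the
  minimum over categories of `negatives_c / positives_c`; every category
  keeps all positives and a uniform sample of `floor(r* · positives_c)`
  negatives. `floor` never exceeds the minimum imbalance.

Repeated CV re-draws the fold structure per repeat through a seed offset,
so repeats are genuinely independent resamplings rather than reruns.
Internal (tuning) folds are band-aware whenever band ids are present.

## Metrics

AUROC is the Mann–Whitney statistic (ties credited ½). AUPRC is the
non-interpolated average-precision step sum with equal scores handled as a
single tie group; linear PR interpolation is optimistic and is not used.
Both are computed through scikit-learn, whose implementations match these
definitions exactly; the test suite and the acceptance script verify the
agreement against independent pair-counting and threshold-sweep oracles,
exhaustively over all labelings of up to 8 samples and on random 50-sample
instances to 1e-12. AUPRC is the tuning objective because AUROC saturates
under extreme imbalance.

## Hyper-parameter tuning

The search space is a discrete 6-D lattice: explicit per-axis value lists
for grid search, inclusive integer intervals for Bayesian optimization.
Every candidate is evaluated by the mean held-out AUPRC of an internal
k-fold CV; an infeasible candidate (e.g. more parts than a split's
negatives) is recorded as a failed evaluation with score −∞, never raised
out of the search.

The Bayesian optimizer samples `n_init` distinct lattice points at random,
then iterates: fit a Gaussian-process surrogate (Matérn ν=2.5 kernel plus a
small white-noise term, inputs scaled to [0,1] per axis, `normalize_y`) to
the finite history, and evaluate the expected-improvement maximiser among
unevaluated candidates (the whole lattice when it has ≤ 2,048 points, else
a 2,048-point random pool). Failed evaluations are excluded from the
surrogate but kept in the history; a surrogate-fit failure falls back to a
random unevaluated proposal. Stopping: `max_iter` total evaluations
(default 60) or `patience = 10` consecutive proposals improving the best
value by at most `tol = 1e-4`. No lattice point is ever evaluated twice.
The published iteration budget and convergence threshold for this kind of
search are not standardised; these defaults are the package's own.

Nested tuning (`run_nested_tune`) repeats the search independently inside
each external fold's training portion and reports one best combination per
external fold; external test indices are structurally excluded from tuning
(the search only ever receives the training subset).

## Synthetic data generator

The generator emulates the benchmark datasets used for this method family:
30 independent ("spherical") Gaussian features of which 4 are informative —
positives are mean-shifted by `effect_size` (default 1.0, in units of
`sigma = 1`) on the informative features and identical to negatives on the
rest. Class counts are exact; imbalance is set directly by
`n_samples`/`n_pos` (the benchmark range spans 1:700 to 1:50,000).
Optional band ids are contiguous blocks (emulating chromosomal locality)
and category ids cycle round-robin, so the grouped-CV and region-balancing
machinery is testable without external data. The published descriptions of
these benchmarks state the feature counts and imbalances but not the mean
shift or variance, so `effect_size` is a declared, configurable default.

What the generator does **not** emulate: correlated features, heavy tails,
category- or band-dependent feature distributions, and label noise. Tests
passing on this generator therefore demonstrate the mechanics and the
imbalance behaviour of the pipeline, not performance on real annotation
features.

The imbalance formatter renders negatives-per-positive as `1:x`, rounding
to the nearest hundred for ratios ≥ 100 (the convention of published
dataset summaries; e.g. 36,342.9 → `1:36,300`) and to the nearest integer
below that.

## Problem sizes in the tests and acceptance script

The verification runs use desk-scale problem sizes chosen to exercise every
code path with stable statistics: worker-invariance on 5,000 samples;
sampling laws at `n_pos = 100` with `fp = 2, ratio = 2` (300 positives /
600 negatives per part, 1,000 oracle-checked SMOTE rows); and the tuning
comparison on 20,000 samples at 1:100 imbalance with an 8-point grid,
3 internal folds and 5 repeats of 5-fold external CV. For the tuning
comparison the grid is tuned once on the full dataset and then both the
tuned and default parameter sets are evaluated by the same repeated
external CV; this measures the improvement direction of tuning at desk
scale, not a leakage-free generalisation estimate (the nested, per-fold
variant is implemented and tested separately).

## Known limitations

* Feature matrices are dense `float64` in memory; out-of-core or sparse
  inputs are not supported.
* SMOTE assumes continuous features; categorical-aware variants
  (SMOTE-NC, ADASYN, borderline-SMOTE) are out of scope.
* The band-aware fold balancing optimises positive counts only; total fold
  sizes may be uneven when band sizes are very skewed.
* Model archives are Python pickles with a format-version tag: portable
  across runs of the same library versions, not a long-term storage format.
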
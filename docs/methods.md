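# Methods

## The optimizer

Trader is a greedy population metaheuristic. The population of `C` real
vectors is partitioned among `T` traders; per iteration the schedule is
fixed: group allocation → master→slave distribution (per group) → slave
self-change (per group) → master exchange → property update. All four
variation operators submit trials through strict greedy acceptance
(accepted iff the objective strictly decreases; ties rejected to prevent
random-walk drift under plateaus), which makes the best-so-far history
non-increasing by construction.

Decisions taken where the procedure is under-determined:

- **Initial property.** Traders start equal; the value is set to 1 since
  only relative property matters in the allocation rule.
- **Allocation rounding.** `NB_i = 2 + round(P_i/ΣP · (C − 2T))` is
  computed with round-half-to-even; the integer residual is then added to
  the groups with the largest fractional share (or removed from the
  smallest, never below 2) until `Σ NB_i = C`. This preserves
  proportionality while conserving the population.
- **Membership.** Deterministic ranked competition: solutions sorted by
  objective ascending are claimed in rounds, traders picking in
  property-descending order until each reaches its quota. Reproducible, and
  wealthier traders get first pick of the better solutions.
- **Positional copies.** The master→slave and master-exchange operators
  copy `R` randomly indexed values *position to position* (one shared index
  per copy). Each variable is a specific network edge, so cross-position
  copies would scramble semantics.
- **Self-change.** `R ~ U{1..max(1, ⌊n/10⌋)}` steps; each step draws a
  fresh index `M`, a sign `k`, and `u ~ U[0,1)`, and applies
  `v_M ← v_M + k·u·v_M` to the running trial. The perturbation is
  multiplicative (a zero coordinate is a fixed point); sign changes enter
  the population only through copies between members.
- **Bounds.** Trials are clamped to the search box after perturbation;
  copies never leave it.
- **Property update direction.** The literal reading — property as the raw
  *sum* of member objective values — rewards worse groups under
  minimization and couples group size to property. The default
  `inverse_fitness` mode therefore scores each member as `1/(1 + OF)`, so
  better groups earn more members; the literal mode is retained behind
  `property_mode="literal_sum"` (with non-positive contributions floored at
  1e-12). With objectives that can go negative (e.g. the six-hump camel
  function), `inverse_fitness` shifts by `min(0, min OF)` so properties
  stay strictly positive; for non-negative objectives this is exactly
  `1/(1 + OF)`.
- **Randomness.** One `numpy` generator owned by the run; operators draw
  in a fixed documented order, giving bit-for-bit reproducibility.
- **Termination.** A fixed iteration count only. `max_iterations = 0` is
  allowed and returns the best of the initial population.

## The network and its training objective

The default architecture is 8-3-2-1 (38 variables: 32 synapses + 6
biases), logistic activations throughout. The activation is a modeling
choice — outputs are compared to 0/1 labels via RMSE, so a (0, 1) output
is natural; `tanh` is available. Weight layout is layer-by-layer, weights
row-major then biases, with a bit-exact encode/decode round trip. The
search box for training defaults to [−10, 10], wide enough to saturate a
logistic unit; the classification threshold is 0.5, with the boundary
mapped to positive. Both are documented conventions, not fitted values.

## Similarity kernels

- **Drug–drug**: weighted cosine over non-negative fingerprint vectors.
  Feature frequencies `d_i` count nonzero entries per column; `σ` is their
  *population* standard deviation; `h = 0.1`. At that `h` the weights decay
  as `exp(−(d_i/(0.1σ))²)`, concentrating nearly all mass on the rarest
  features, and the raw exponentials underflow. The kernel therefore
  evaluates in log-weight space, rescaling each vector by the largest
  weight on its support — a constant factor that cancels in the cosine —
  so the computation is exact where the naive formula is representable and
  well-defined everywhere else. A zero-support vector is an error naming
  the drug.
- **Target–target**: normalized Smith–Waterman, `SW(a,b)/√(SW(aa)·SW(bb))`,
  via Biopython's local `PairwiseAligner`. Default scheme BLOSUM62 with gap
  open 10 / extend 0.5, the convention of the gold-standard chemogenomic
  benchmark constructions; a match/mismatch/linear-gap scheme is provided
  for hand-checkable tests and is validated against a textbook dynamic
  program in the test suite.

## Pair features and datasets

The eight descriptors of a pair (d, t) are the max / second-max / mean
similarity of d to the drugs known to bind t, the same three statistics of
t against the targets known to bind d, and the two interaction degrees
normalized by panel size. The evidence sets always exclude the pair being
scored (leave-self-out), so a pair's own label can never leak into its
features; empty evidence slots are 0, and the second-max of a singleton
evidence set is 0. The exact descriptor set is a design choice constrained
by the 8-input architecture; the builder is a pluggable callable.

Datasets are positives-only by construction (one row per known pair). For
two-class evaluation, negatives are sampled uniformly from non-interacting
pairs at a 1:1 ratio, seeded. The train/test split is a seeded permutation
at a configurable fraction (default 0.8, matching the roughly 78–80%
train shares of typical benchmark set splits).

## Evaluation

Accuracy, sensitivity, specificity and precision are reported as
percentages; any metric with a zero denominator is `None` (undefined),
never silently 0. In the positives-only ("one-class") setting accuracy
reduces to TP/(TP+FN). Folds are stratified by label, seeded, disjoint and
exhaustive (scikit-learn's splitter behind the module surface). Fold
metrics are averaged arithmetically; ROC and PR curves pool the held-out
scores of all folds — pooling is deterministic and avoids the
interpolation choices of vertical averaging — with trapezoidal AUC, and
are omitted when the pooled labels contain one class. Each fold's training
run offsets the optimizer seed by the fold index.

The Wilcoxon rank-sum comparison uses the exact null distribution for
small tie-free samples (identical to exhaustive permutation enumeration)
and the tie-corrected normal approximation otherwise; two samples with all
values identical are degenerate and report p = 1 with a flag.

## Synthetic worlds

The generator emulates the structure the pipeline assumes: drugs and
targets fall into latent blocks; each block has a prototype fingerprint
(columns drawn against Beta(1, 4) base rates, giving the frequency-skewed
columns real panels show) and a prototype amino-acid sequence; members are
noisy copies (default 5% bit flips, 10% point substitutions); interactions
are Bernoulli, 0.9 within block vs 0.05 across. Defaults — 60 drugs, 40
targets, 3 blocks, 200 properties, sequence lengths 60–100 — define the
standard study world used by the end-to-end tests.

What it does not emulate: real pharmacological effect annotations and
their correlation structure, true protein family composition statistics,
and the extreme sparsity of a 17k-column property panel. Passing the
planted-signal study shows the pipeline recovers block structure from its
own feature definitions; it is not evidence about any real benchmark. One
empirical consequence of the `h = 0.1` weighting: with block-sized feature
frequencies, cross-drug similarities are nearly zero, so on the synthetic
world the predictive signal is carried mostly by the sequence-similarity
features and the degree features.

## Problem sizes and numerics

The standard study sizes used throughout the tests: sphere convergence at
10-D with population 40, 4 traders, 500 iterations over 50 seeds; XOR
recovery with a 2-2-1 network over 50 seeds at 1500 iterations; the
planted-world study at 5 folds with the default training configuration
(population 40, 4 traders, 300 iterations, bounds ±10). Multi-run
summaries report the population standard deviation (a single execution
gives std 0). Similarity matrices are stored symmetric with unit diagonal
and written at 17 significant digits so files round-trip losslessly.

## Known limitations

- No gradient-based trainer; the optimizer is the only training path.
- Comparator metaheuristics and learners are out of scope by design.
- The multiplicative self-change cannot change a coordinate's sign, so
  sign diversity comes entirely from the initial population and
  inter-member copies; very small populations can stall on problems whose
  optima require rare sign patterns.
- Curve AUCs are fold-pooled, which can differ slightly from averaging
  per-fold AUCs when folds are unbalanced.
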
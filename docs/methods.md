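# Methods

## Data and encoding

The packaged dataset has one row per treatment combination of a factorial
greenhouse experiment: melatonin dose (0, 50, 100, 150 μM) × drought level
(40, 75, 100 % of field capacity) × observation day (15, 30, 45, 60) ×
species (Persian lime, Mexican lime), with five measured morphological
responses per row. The printed values are treatment means over four
replicate seedlings; the replicate-level measurements are not available.
Two cells are wildly inconsistent with their factorial neighbours (a leaf
count of 105.50 amid ~1060; a crown diameter of 2.130 amid ~3.44) and are
almost certainly transcription errors in the source. They are preserved
verbatim and flagged `suspect`; every pipeline stage accepts
`exclude_suspect=True` to drop those rows, but the default keeps them —
source data are never silently edited.

Species is coded −1 (Persian) / +1 (Mexican): a symmetric, order-free
binary code that min–max scaling leaves untouched. All features and
targets are normalized per column to [−1, 1] by the affine map
2(x − min)/(max − min) − 1, fitted on the training partition only;
normalization is inverted before any metric is computed, so RMSE/MBE are
in leaves or cm. Train/test splits take round-half-up(0.7·N) rows at
random (96 → 67/29), seeded.

## Models

One scalar model per response per family (5 × 3 models), matching the
per-response structure of the comparison table.

*GRNN.* Lazy kernel regressor; the only parameter is the kernel
half-width h (the 0.8326 ≈ √ln 2 factor in the Gaussian makes the kernel
0.5 at distance h). h is selected by exact leave-one-out RMSE over a
geometric grid (0.05–4.0, 40 points, in normalized input units), ties
toward the larger (smoother) h. Kernel sums use a max-shift in the
exponent so the denominator cannot underflow; in the h → 0 limit the
predictor degenerates gracefully to nearest-neighbour. Predictions are
convex combinations of training targets and therefore never overshoot the
observed range.

*RBF.* Centers at all training points — the exact-design convention
implied by the half-width kernel — with a small default ridge (1e−8) for
conditioning. The bias is fixed at the target mean and the weights solve
(ΦᵀΦ + λI)w = Φᵀ(T − w̄): at λ = 0 on distinct points this interpolates
exactly; constant targets give zero weights; far from all centers the
prediction returns to the bias. Spread by seeded 5-fold CV (the linear
solve makes exact LOO less attractive than for the GRNN).

*MLP.* One hidden layer, logistic activations, linear output, full-batch
L-BFGS on the mean-squared error with a small weight decay (1e−4) for
reproducible optima, 2 seeded restarts, 500 iterations. Hidden-size
candidates {2, 4, 6, 8} for n = 4 inputs and K = 96 rows (the n, 2n,
⌈log₁₀K⌉ heuristics plus a midpoint), chosen on a 25 % validation
holdout of the training rows, then refit on the full training partition.

## Optimization

Surrogates for optimization are five GRNNs trained on **all** 96 rows
(not a 70 % partition): family selection happens beforehand on held-out
splits; at optimization time the best available surrogate of the data is
wanted. NSGA-II runs over the continuous box melatonin ∈ [0, 150] μM,
day ∈ [15, 60], FC ∈ [40, 100] with species as a discrete gene. Defaults
follow the study settings (population 200, generations 1000, mutation
rate 0.5, crossover rate 0.7); the reduced budget pop 100 / 200
generations used in tests and the acceptance script converges to the same
region in a few seconds. Parent selection is roulette-wheel on the
fitness (1 + c)/(2·rank), where c is crowding normalized to [0, 1]
within each front — canonical NSGA-II uses binary tournament, but the
procedure reproduced here specifies roulette selection; the fitness
transform is this package's choice. Variation is SBX (η = 15) and
polynomial mutation (η = 20, per-individual probability 0.5, per-gene
1/4), offspring clipped to bounds; survival is elitist (μ+λ) truncation
by (rank, crowding). The ideal point normalizes each objective over the
final front to [0, 1] and picks the member nearest the all-ones vector
(ties by larger leaf count). Mutation/crossover rates are interpreted as
per-individual/per-pair probabilities.

Per-generation logs report the first front's dominated hypervolume —
exact by sweep in 2 objectives, seeded Monte-Carlo estimate otherwise.
Hypervolume is guaranteed non-decreasing only while the first front fits
inside the population; once it saturates, crowding-based truncation may
discard boundary members.

## Sensitivity

VSE of an input = test RMSE of a GRNN retrained from scratch (fresh
spread selection) without that input; VSR = per-seed ratio of VSE to the
full model's test RMSE, median over the same seed set as the model
comparison. "Removed" means retrained-without-feature: substituting a
constant would leave a lazy kernel model ill-defined rather than reduced.
A predict-time mean-clamp variant (`mode="substitute"`) is provided as a
diagnostic; it probes how much the *fitted* model uses an input rather
than how much *information* the input carries.

## Synthetic data

The generator emulates the qualitative structure of the experiment with a
multiplicative surface per response: base level × species multiplier
(default 1.4 for Mexican) × drought factor (1 − 0.01·(100 − FC), monotone
in FC) × dose factor × weak time trend (1 + 0.002·(day − 15)) + Gaussian
noise, truncated at 0. The dose factor is a quadratic bump
1 + A(1 − ((m − m*)/m*)²) peaking at m* = 100 μM with amplitude A = 1.5:
value 1 at 0 μM, maximal at the peak, dipping below the peak at 150 μM —
the biphasic promotion/inhibition pattern seen in the data. (A quadratic
in *log*-dose was considered and rejected: log compression makes the bump
nearly flat over 50–150 μM, leaving the peak unresolvable on the
experimental grid.) Base levels are sized so response ranges roughly
match the real measurements (leaf counts in the hundreds, lengths of a
few cm); default noise SDs are a few percent of the response range. The
analytic maximizer of the noiseless surface is exported as ground truth
for optimizer-recovery tests. The generator makes no attempt at
mechanistic physiology, replicate structure, or non-Gaussian noise, so
passing recovery tests demonstrate correctness of the estimation and
optimization machinery, not fidelity of any biological claim.

## What is and is not reproducible from the published table

The optimization stage reproduces well: surrogates trained on all 96 rows
nearly memorize the table, and the GRNN-NSGA-II ideal point lands in the
published region (Mexican lime, ≈100 μM, full irrigation, ≈1054 predicted
leaves vs the published 1063.21).

The published *test-partition* accuracies do not reproduce, for a
structural reason. The table prints treatment means; after [−1, 1]
normalization the factor grid places day-neighbours and dose-neighbours
at exactly the same distance (2/3), so an isotropic single-spread kernel
cannot smooth along the (nearly flat) day axis without mixing melatonin
cells whose responses differ several-fold. Scanning the spread
exhaustively caps the median 70/30 test R² near 0.67 (crown), 0.43 (leaf
length), 0.65 (leaf count) — far from the published 0.99/0.95/0.99 —
while an oracle that averages same-cell training rows reaches 0.94–0.99.
Published test RMSEs that equal training RMSEs and plausible replicate
SDs (e.g. 16.07/17.86 leaves) are consistent with modeling
replicate-level lines, where every test line's factor cell remains in
training; those lines were not published. The same geometry inverts the
test-partition sensitivity ranking: dropping the near-uninformative day
input *improves* test RMSE (VSR < 1). These findings are reported as
computed; no parameter was adjusted to chase the published values.

## Numerical choices and edge cases

- Constant columns fail normalization loudly (division by zero).
- R² is undefined for zero-variance vectors and raises with a diagnostic.
- RBF at ridge = 0 verifies interpolation post-solve and raises a
  `LinAlgError` advising a nonzero ridge on (near-)duplicate centers.
- MLP restarts on non-finite losses with fresh derived seeds and fails
  after 10 consecutive non-finite attempts.
- Spread-selection ties break toward the larger h; VSR rank ties break in
  input order (melatonin, day, species, FC).
- All randomness flows through `numpy.random.default_rng(seed)`;
  every aggregate is a median over an explicit seed list.

## Problem sizes

Default study sizes: 96 rows, 20 split seeds for aggregate medians, 5 GA
seeds at population 100 / 200 generations for optimization summaries.
These sizes keep the full pipeline in the tens of seconds on one CPU
while leaving the reported medians stable to the third digit across seed
bases.
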
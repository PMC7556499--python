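# citrusann

Neural-network regression and multi-objective optimization of citrus
seedling morphology under melatonin treatment and drought stress.

## The problem

Exogenous melatonin (an indoleamine plant growth regulator, applied here as
a foliar spray at 0–150 μM) can mitigate drought damage in citrus, but its
effect is dose-dependent and interacts with drought severity, species, and
time. The underlying experiment measured five morphological responses —
number of leaves per plant, leaf length (cm), internode length (cm), crown
diameter (cm) and plant height (cm) — of Persian lime and Mexican lime
seedlings over a full factorial of melatonin dose (0/50/100/150 μM),
drought level (40/75/100 % of field capacity) and observation day
(15/30/45/60): 4 × 3 × 4 × 2 = 96 treatment combinations, shipped with the
package as a CSV fixture.

`citrusann` is for researchers in plant stress phenomics who want to

1. fit and compare three small regression networks on such factorial
   dose–response data,
2. search the continuous treatment space for the input combination that
   jointly maximizes all five responses, and
3. rank the inputs by importance.

## Models and methods

All models map the encoded factor vector **x** = (melatonin, day, species
∈ {−1, +1}, % FC), min–max normalized to [−1, 1], to a single normalized
response; metrics are always reported in original units.

**GRNN** (generalized regression neural network) — a Nadaraya–Watson
kernel smoother over the training points (X_b, T_b):

    ŷ(x) = Σ_b T_b K(x, X_b) / Σ_b K(x, X_b),
    K(x, X_b) = exp(−(‖x − X_b‖ · 0.8326 / h)²)

The 0.8326 ≈ √(ln 2) factor makes K = 0.5 at distance h, so the spread h
is the kernel half-width. h is chosen by leave-one-out cross-validation
(exact and cheap for a lazy learner).

**RBF network** — one Gaussian unit (same kernel) per training point plus
a bias; output weights solve a ridge-regularized linear least-squares
problem (exact interpolation at ridge → 0). Spread chosen by k-fold CV.

**MLP** — single hidden layer of logistic-sigmoid units with a linear
output, trained by full-batch L-BFGS with seeded restarts; the hidden-layer
size is picked by validation RMSE from the standard heuristics
{n, 2n, ⌈log₁₀ K⌉} plus midpoints.

Families are compared by R² (squared Pearson correlation), RMSE and mean
bias error MBE = mean(y − ŷ), as medians over seeded 70/30 train/test
splits.

**NSGA-II** — a from-scratch elitist multi-objective GA (fast
non-dominated sorting, crowding distance, roulette-wheel parent selection,
SBX crossover η=15, polynomial mutation η=20, discrete species gene)
maximizes the five GRNN-predicted responses over the design box
melatonin ∈ [0, 150], day ∈ [15, 60], FC ∈ [40, 100], species ∈ {P, M}.
The reported optimum is the *ideal point*: the front member closest (in
front-normalized Euclidean distance) to the vector of per-objective maxima.

**VSE / VSR sensitivity** — the variable sensitivity error of an input is
the test RMSE of a GRNN retrained from scratch without it; the variable
sensitivity ratio is VSE divided by the full model's test RMSE on the same
splits. Higher VSR ⇒ more important input.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and known limitations — in particular why test-partition metrics
on this 96-row table of treatment means are structurally lower than
training metrics.

## Worked example

```python
from citrusann import load_citrus_table, SurrogateSet, GAConfig, run_optimization

surrogates = SurrogateSet.fit(load_citrus_table())   # 5 GRNNs, LOO-tuned spreads
result = run_optimization(surrogates, GAConfig(pop_size=100, generations=200, seed=0))
for k, v in result.ideal.items():
    print(f"{k:22s} {v if isinstance(v, str) else round(v, 2)}")
```

prints

```
melatonin_uM           100.29
day                    60.0
species                mexican
fc_percent             100.0
pred_n_leaves          1053.93
pred_leaf_length_cm    8.97
pred_internode_cm      6.65
pred_crown_cm          2.77
pred_height_cm         348.4
```

i.e. the optimizer selects Mexican lime under full irrigation at ≈100 μM
melatonin, predicting ≈1054 leaves/plant and ≈348 cm height — the
well-watered, mid-high-dose corner where the measured maxima live.

The same stages are available from the shell:

```sh
citrusann compare     --out out/compare --n-seeds 20
citrusann optimize    --out out/opt --seed 0
citrusann sensitivity --out out/sens --n-seeds 20
citrusann simulate    --out out/sim --seed 1
citrusann validate    --out out/val --observed my_measurements.csv
```

Each command writes CSV/JSON artifacts plus a `manifest.json` recording
the resolved configuration and seeds.

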
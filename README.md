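# coasel — coati-optimization feature selection for EEG-style data

High-dimensional biomedical feature matrices — EEG motor-imagery features
in particular — are dominated by irrelevant and redundant columns that
degrade classifiers and slow inference. `coasel` selects compact feature
subsets with a **binary coati optimization algorithm (COA)** combined with
**opposition-based learning**, and also ships a constrained 0/1
(knapsack-style) selection variant, an EEG feature-extraction front-end,
synthetic benchmark generators with known ground truth, and evaluation
metrics.

## The method

A candidate subset of `d` features is a binary mask
`X = [x_1, …, x_d], x_j ∈ {0,1}`. A population of `N` masks ("coatis") is
evolved for up to `T` iterations, scored by the wrapper fitness

```
f(X) = 1 − Acc(X)
```

where `Acc(X)` is leave-one-out cross-validated accuracy of a 1-nearest-
neighbor (Euclidean) classifier on the masked matrix; the empty mask gets
the worst value 1.0. Each iteration:

1. **Leader selection** — the minimum-fitness coati `X* = argmin f(X_i)`
   becomes the dominant male.
2. **Territorial movement** — every other coati adopts each leader bit
   with switching probability `S = r1·(1 − r2·x_j)`, `r1, r2 ~ U(0,1)`
   drawn fresh per bit (no tunable movement coefficients).
3. **Opposition-based learning** — the bitwise complement `x̄_j = 1 − x_j`
   is evaluated and kept iff strictly better, probing unexplored regions.
4. **Elitist leader update** — the leader is never moved or opposed, so
   the best fitness is non-increasing across iterations.

The constrained variant maximizes total relevance `Σ s_j z_j` subject to a
cost budget `Σ c_j z_j ≤ B`, a latency budget `Σ r_j z_j ≤ R`, a
cardinality cap `Σ z_j ≤ k`, and a required-group quota `Σ g_j z_j ≥ Gmin`,
solved exactly by branch and bound (HiGHS) and validated against a
brute-force enumeration oracle.

## Worked example

The package bundles a hand-checkable 5×6 two-class matrix (labels
`[1,1,0,0,0]`):

```python
from coasel import CoatiSelectionModel, worked_example_fixture

model = CoatiSelectionModel(worked_example_fixture())
res = model.fit(n_coatis=3, n_iterations=50, seed=34)
print(res.summary())
```

```
Coati Feature Selection Results
==============================================
Samples                                      5
Features (d)                                 6
Population (N)                               3
Max iterations (T)                          50
Iterations run                              10
Seed                                        34
Distinct masks evaluated                     8
----------------------------------------------
Selected features                            3
Reduction rate                          0.5000
LOOCV accuracy                          1.0000
Fitness (1 - accuracy)                  0.0000
----------------------------------------------
Selected: f1, f3, f5
==============================================
```

The search selects features `f1, f3, f5` (mask `101010`): on those three
columns every sample's nearest neighbor shares its label, so LOOCV
accuracy is 1.0 and the fitness reaches its optimum 0.0 while discarding
half the features (reduction rate 0.5). `res.evaluate(folds="loo")`
returns the full metric report (accuracy, precision, recall, F1,
confusion counts) and `res.plot_convergence()` draws the best-fitness
trace.

A shell workflow is available via the `coa-select` CLI
(`run`, `lp`, `extract`, `synth`, `evaluate`), e.g.:

```sh
coa-select synth tabular --n 200 --d 30 --k 5 --effect 1.5 --seed 7 \
    --out F.csv --truth truth.json
coa-select run --features F.csv --label-column label --pop 20 --iters 50 \
    --seed 42 --out result.json
```

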
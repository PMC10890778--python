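# Methods

## Model and procedure

The package ranks the `d` features of a labeled matrix `X ∈ R^{n×d}` by an
embedded criterion built from three ingredients: the NCFS weight learner,
correlation-guided random subspaces, and a classifier-scored accumulation
of per-partition weights.

**NCFS.** With per-feature weights `w`, the weighted L1 distance
`d_w(x_i, x_j) = Σ_l w_l² |x_il − x_jl|` induces reference probabilities
`p_ij = κ(d_w(x_i,x_j)) / Σ_{k≠i} κ(d_w(x_i,x_k))`, `κ(z) = exp(−z/σ)`,
`p_ii = 0`. The objective `F(w) = Σ_i p_i − λ Σ_l w_l²`, with
`p_i = Σ_j 1[y_i = y_j] p_ij`, is the expected leave-one-out correctness of
a soft nearest-neighbor rule minus an L2 penalty; it is bounded above by
`n`. The analytic gradient,

```
∂F/∂w_l = 2 w_l [ (1/σ) Σ_i ( p_i Σ_j p_ij |x_il−x_jl|
                              − Σ_j 1[y_i=y_j] p_ij |x_il−x_jl| ) − λ ],
```

is ascended with an adaptive step: a step is accepted only if it increases
`F` (then the step grows by `step_up`), otherwise reverted (step shrinks by
`step_down`). The accepted-step objective trace is therefore strictly
increasing by construction. The gradient implementation is gated by a
central-finite-difference test on random instances.

Assumptions: samples are i.i.d. within class; features are comparably
scaled (enforced by z-scoring); the soft-neighbor radius σ is meaningful
after standardization. Weights are *not* clipped to nonnegative — both the
distance and the penalty are even in `w`, so sign carries no information
and the ranking uses the raw values.

**Correlation k-means.** Features (columns) are clustered under the
distance `1 − |pearson(f, a)|`, so correlated and anti-correlated columns
are treated as one collinear group. Centroids are updated as arithmetic
means of member columns; Pearson correlation is affine-invariant in each
argument, so the mean needs no re-standardization. Because the mean is not
the exact Fréchet mean of this metric, the objective `J` is not guaranteed
to decrease at the update step; the implementation records `J` on each
(centroids, nearest-assignment) pair and stops — reverting the last
update — if an iteration would increase it. Convergence is declared when
`|J_t − J_{t−1}| < η` (default η = 0.02) or after `max_iter = 300`
iterations. Each run restarts `n_init = 10` times from fresh random
centroid draws (k distinct feature columns, uniformly without replacement)
and keeps the lowest final `J`: a single init places two centroids in the
same collinear block often enough that Lloyd iteration alone cannot
reliably separate tight blocks. Empty clusters are repaired by reseeding
with the feature farthest from its own centroid.

A consequence of the raw-mean centroid update: rescaling or shifting a
feature column leaves its *distances* and its assignment against
single-column centroids unchanged, but leaks into later mean centroids
through that column's contribution. Affine invariance therefore holds
exactly at the distance level and at the first assignment, not across a
full multi-iteration run.

**Partitions.** A feature partition splits `{1..d}` into `s` non-empty
disjoint subspaces covering everything. The cluster-stratified builder
permutes each cluster and deals `⌊n_c/s⌋` contiguous members to every
subspace, placing each leftover in an independently uniform subspace; the
uniform builder deals a global permutation in consecutive blocks, with the
`d mod s` leftovers going one each to the first subspaces (deterministic
given the permutation). If stratification ever leaves a subspace empty —
possible only when every cluster is smaller than `s` — one feature is
moved from the largest subspace. Per-subspace NCFS weights are spliced
back to full length by their global index maps (an exact bijection,
round-trip tested).

**Partition weighting.** The spliced vector `w⁽ⁱ⁾` is min-max normalized
to `π⁽ⁱ⁾ ∈ [0,1]` (a constant vector maps to all 0.5, the midpoint of the
threshold range, so selection stays possible). Thresholds are drawn once
per iteration as `u = ½(1 + erf(v))`, `v = Lθ`, where `L` is the Cholesky
factor of the feature correlation matrix `R` and `θ` is iid standard
normal — so correlated features face correlated thresholds and tend to be
admitted or rejected together. Note `½(1 + erf(v))` is the CDF of a
normal with variance ½, deliberately implemented as written; the
standard-normal alternative is available via `cdf="gauss"`. `R` is
computed once per run (the data do not change across iterations) and is
singular whenever `d > n`, so factorization adds the smallest diagonal
jitter `ε ∈ {1e-8, 1e-7, …, 1e-2}` that succeeds. Features with
`π_k > u_k` (strict) form the evaluation set; `α` is the stratified 3-fold
CV accuracy of a 3-nearest-neighbor classifier on those columns (folds
seeded; resubstitution available via `alpha_eval="resub"`; an empty set
scores α = 0). CV is the default because resubstitution accuracy of a
1-to-3-NN rule is optimistically biased on wide data.

**Accumulation.** `w` starts at all-ones and accumulates
`w ← w + α_i w⁽ⁱ⁾` over `M` iterations (`kncfs`), or is the plain average
of the `M` spliced vectors (`rb-ncfs`), or a single full-space fit
(`ncfs`). The all-ones start is a constant offset that cannot change the
ordering; final ranking is by descending weight with ties broken by
ascending feature index for determinism.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `M` | 10 | feature partitions (accumulation iterations) |
| `s` | 10 | subspaces per partition |
| `k` | 10 | feature clusters |
| `sigma` | 1 | NCFS kernel width (distance units of z-scored data) |
| `lam` | 1 | NCFS L2 penalty coefficient |
| `initial_step`/`step_up`/`step_down` | 1.0 / 1.01 / 0.5 | adaptive ascent schedule |
| `tol`, `max_iter` (NCFS) | 1e-4, 100 | ascent stopping rule |
| `eta`, `max_iter` (k-means) | 0.02, 300 | clustering stopping rule |
| `n_init` | 10 | k-means restarts, best final J kept |
| `alpha_eval` | `cv3` | α protocol (`cv3` or `resub`) |
| `cdf` | `erf` | threshold transform (`erf` or `gauss`) |

`M`, `s`, `k` = 10 are sensible mid-range settings for matrices with a few
hundred to a few thousand features; `s` and `k` must not exceed `d`.

## Seeding and determinism

One master seed spawns an independent child stream per iteration, and
within an iteration separate streams for clustering initialization,
partition permutations, the threshold draw and the α folds. Changing `M`
never perturbs earlier iterations, and identical (input, config, seed)
reproduce byte-identical ranking and manifest files.

## Synthetic data

`make_dataset` emulates the study conditions without external downloads:
relevant features are class-conditional Gaussians with class means spread
`effect` standard deviations apart (default 2); noise features are iid
Normal(0, variance 5), label-independent; collinear blocks share one
latent Gaussian per block (`f_j = √ρ·g + √(1−ρ)·ε_j` gives within-block
pairwise correlation ρ). The default benchmark is n = 100 samples, 2
balanced classes, 5 relevant features and 50–500 noise features, scored by
the success rate: the fraction of the known-relevant features appearing in
the top-|relevant| ranks.

What this generator does *not* emulate: real expression data have heavy
tails, batch structure, correlated noise between relevant features, and
relevance that is conditional rather than marginal. Passing the synthetic
benchmark shows the pipeline separates marginal Gaussian signal from
independent noise at realistic dimensionality; it does not certify
performance on any particular real dataset, for which the CSV interface
and the `evaluate` subcommand exist.

## Numerical choices

- Reference probabilities shift each distance row by its off-diagonal
  minimum before exponentiation — mathematically identical (the shift
  cancels in the normalization) and finite for arbitrarily large
  distances.
- Zero-variance feature columns: standardization maps them to all-zero and
  flags them; correlation conventions give them `r = 0` against everything
  (distance 1, so they join clusters only via the tie rule) and `r = 1`
  with themselves.
- Ties in nearest-centroid assignment and in the final ranking go to the
  lowest index.
- The k-means trace records `J` evaluated on the returned
  (centroids, assignment) pair, so the final assignment is exactly the
  brute-force minimizer over assignments given the returned centroids.
- `fit_ncfs` with `max_iter = 0` returns the starting weights unchanged;
  a non-finite objective raises immediately with diagnostics.

## Limitations

- The α classifier is fixed to 3-NN; no joint learning of α and `w`.
- Subspace counts are global (`s` identical across partitions); subspaces
  never overlap.
- NCFS here is the exact O(n²d)-per-step form; no nearest-neighbor
  approximation or minibatching, so very large n is out of scope.
- Multi-label problems and automatic selection of `k` are not supported.
- The 10-restart k-means makes block recovery reliable on tight collinear
  blocks but is still a local search; pathological correlation structures
  can settle in local optima.
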
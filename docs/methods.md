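# Methods

## Model and estimation

`mtgsel` fits a joint logistic regression over m tasks, where the tasks are
independent without-replacement subsamples (rate η) of one training cohort.
The smooth loss is the per-task-averaged logistic negative log-likelihood;
the penalty is the ℓ2,1 norm over gene rows of the d×m weight matrix,
λ Σ_j ‖W_j·‖₂. Because the penalty couples the tasks row-wise, its proximal
operator zeroes whole rows, giving every gene a single in/out status shared
by all subsamples — the mechanism by which subsampling noise is averaged out
of the selection. Biases are unpenalized. The objective is convex; the
minimum value is unique and the reported panel is {j : ‖W_j·‖₂ > tol} with
tol = 1e−8 (the prox produces exact zeros, so the tolerance only absorbs
float noise).

A note on the penalty's algebraic form: written per task, Σ_k ‖W_k‖_{2,1}
would degenerate to a plain ℓ1 sum on vectors; the operative definition here
is the row-group form on the matrix, which is the one consistent with
block-wise row thresholding and with shared selection across tasks.

### Solver

Proximal gradient descent (ISTA) with a backtracking line search:

1. A = W − (1/γ)∇L(W); W′ = row-wise block soft-threshold of A at λ/γ;
   c′ = c − (1/γ)∇_c L.
2. Accept when L(W′,c′) ≤ L(W,c) + ⟨∇L, Δ⟩ + (γ/2)‖Δ‖² (the quadratic
   majorizer test over the joint (W, c) step); otherwise γ ← αγ and retry.
3. Stop when the relative objective decrease falls below `tol_rel` or at
   `max_iters`.

Defaults: γ₀ = 1, α = 2, tol_rel = 1e−6, max_iters = 1000, at most 50
backtracks per iteration. Under the acceptance rule the penalized objective
is non-increasing at every iteration and converges to the global minimum;
both properties are asserted in the test suite, together with agreement with
finite-difference gradients, a brute-force prox minimizer, a damped-Newton
logistic oracle (λ = 0, m = 1) and a long subgradient-descent run.

Two deliberate solver choices:

- **Step restart.** γ restarts each outer iteration at max(γ₀, γ_prev/α)
  rather than always at γ₀. The step can still re-grow between iterations,
  every accepted step still passes the majorization test (so all guarantees
  hold), and a typical iteration needs one or two loss evaluations instead
  of four or five.
- **Initialization** is always W = 0, c = 0: the problem is convex, so no
  random restarts are needed and the solver is seed-free. One visible
  consequence: λ_max is defined at the *optimal* intercepts, so when
  λ ≥ λ_max the weights can transiently leave zero while the intercepts
  travel to their optimum, returning to exact zeros at convergence.

Gradients and losses are evaluated through two BLAS GEMMs on the shared n×d
matrix (X·W gather, Xᵀ·scatter) rather than per-task products; per-iteration
cost is O(m·n·d) and the tests include a coarse linearity check of the
scaling in m, n and d.

### Task subsampling

Each task draws round(η·n) samples without replacement; tasks may overlap
("without replacement" holds within a task, not across tasks). Draws are
stratified by class via largest-remainder allocation (each class keeps at
least one slot), which guarantees no degenerate single-class task; an
unstratified mode with bounded redraws is available for fidelity to plain
uniform sampling. Defaults m = 8 (midpoint of the well-performing 6–10
band), η = 0.7.

### λ selection

Stratified 5-fold CV on a 20-point log grid from 1e−3·λ_max to λ_max,
computed on the training data so the null model is always a candidate. Task
subsets are redrawn inside each fold (fold training sets differ in size, so
reusing outer indices would be ill-defined); fits run from the largest λ
down with warm starts (a pure speed optimization — tests verify warm and
cold fits agree in objective to 1e−5). The chosen λ minimizes mean held-out
log-loss, ties broken toward the larger (sparser) λ; validation accuracy is
recorded but not used for the argmin. The final model refits on the full
training set at the chosen λ.

### Preprocessing and conventions

Genes are z-scored with training-set mean/SD (SD floor 1e−12) and the same
transform is applied to test data; regularized linear models are
scale-sensitive and a single λ across genes presumes comparable scales. A
flag disables standardization. Whether real microarray cohorts should
additionally be log-transformed is left to the user — the reader rejects
NaNs and performs no imputation or platform-specific normalization. Labels
are stored {0,1} with the lexicographically smaller class name mapped to 0,
converted once to {−1,+1} for the loss; prediction uses the strict rule
ŷ = 1 iff p̂ > τ (ties to class 0), τ = 0.5.

## Baselines

- **L1 / elastic net**: single-task logistic regression with
  λ·[mix·‖w‖₁ + (1−mix)/2·‖w‖₂²], solved by the same proximal engine with
  the elementwise elastic-net prox, λ chosen by the same 5-fold CV protocol.
  mix = 1 reproduces the lasso exactly.
- **ReliefF**: deterministic pass over all training instances, k = 10
  nearest hits/misses by Euclidean distance, per-gene differences normalized
  by the gene's training range (zero-range genes score 0).
- **mRMR**: 3 equal-frequency bins per gene, greedy MID criterion
  (relevance minus mean redundancy, both as mutual information on bin
  ranks — hence invariant to monotone transforms of expression). MID with
  coarse bins is the common default for microarray-scale data.
- Filters hand their top-n panel (n from {10..50}, default 50 in the
  recovery experiments) to a logistic classifier with a tiny ridge
  (λ₂ = 1e−6) for numerical stability; selection uses training data only,
  which the tests enforce by permuting test labels.

## Synthetic cohorts

The generator emulates high-dimension low-sample expression data: rows
i.i.d. N(0, Σ) with AR(1) correlation Σ_ab = ρ^{|a−b|} (ρ = 0.5), unit
marginals; 20 relevant genes planted at uniformly random positions (so the
correlation structure does not trivially cluster them) with
alternating-sign coefficients of magnitude 0.75; labels drawn from the
logistic model y ~ Bernoulli(σ(x·β)). The standard sizes S1–S6 cross
n ∈ {100, 200} with d ∈ {500, 1000, 2000}. Everything is a `SimulationConfig`
field, so the design can be changed without code changes.

What this emulates and what it does not: real expression data are
non-Gaussian, heteroscedastic, and have block- rather than banded
correlation; planted-truth recovery on this generator therefore calibrates
the *machinery* (optimization, CV, the selection rule, the harness), not
clinical performance.

**A structural caveat that matters when reading the numbers.** With equal
coefficient magnitudes, the marginal association between a relevant gene and
the label is bounded near β_j/‖β‖₂ = 1/√20 ≈ 0.22 *independently of the
effect size* (as effects grow, labels approach sign(x·β), which depends only
on the direction of β), while the sampling noise of that association at
n_train = 50 is ≈ 1/√50 ≈ 0.14; support recovery of 20 genes among 500 also
sits below the n ≳ 2k·log(d/k) ≈ 128 regime. Consequently, at the default
design the CV-selected model stays heavily regularized, panels are small
with few true positives, and test accuracy sits near chance — and
independent solvers (ridge and lasso logistic regression from scikit-learn)
behave identically on the same draws. The acceptance suite asserts
published-scale recovery values on this generator and those assertions fail
under this design; they are kept strict rather than loosened, because the
failure is informative about the design, not about the estimator. The
Bayes-oracle sanity check (a classifier built from the true β clears 0.75
accuracy) and the monotonicity of recovery in effect size still hold and are
tested.

## Experiment harness

Repeated stratified splits (fractions 0.5/0.6, 10 repeats by default);
within a repeat every method sees the same split, so comparisons are paired.
All randomness flows from one base seed: split r uses seed base+r, CV folds
and task draws derive from it deterministically, and two runs with equal
configs produce byte-identical tables. The ensemble-size sweep
(k = 2, 4, 6, 8, 10) shares splits across k. Problem sizes used by the test
suite and `scripts/acceptance.py`: the full S1 cohort (100×500) for the
recovery and sweep experiments, smaller programmatic cohorts elsewhere.

## Known limitations

- Binary classification only; no per-task λ; no FISTA acceleration or
  minibatching (cohorts of this scale do not need them).
- The filter gene-count grid caps at 50; published recovery tables for
  filters conventionally fix the count (50 here), and accuracy under other
  counts is exposed via `n_select`.
- Selection stability is encouraged across subsamples of *one* cohort;
  cross-cohort (batch-effect) stability is out of scope.
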
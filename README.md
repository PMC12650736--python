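# mtgsel — multi-task ensemble gene selection for tumor classification

Gene expression cohorts routinely carry thousands of genes and only tens of
samples, and in that regime the gene panels reported by standard selection
methods are notoriously unstable: refit on a slightly different subsample and
you get a different list. `mtgsel` implements an ensemble strategy that
attacks this directly: it draws *m* random subsamples of the training set,
treats each as a **task**, and fits all tasks jointly with logistic regression
under an ℓ2,1 row-group penalty, so a gene is kept only if it is useful
*consistently across subsamples*.

## The model

Let X ∈ ℝ^{n×d} be the expression matrix (samples × genes) and y ∈ {−1,+1}^n
the tumor labels. Each task k = 1..m is a without-replacement draw of a
fraction η (default 0.7) of the training samples. With W ∈ ℝ^{d×m} (column
W_k = task k's weights, row W_j· = gene j across tasks) and biases c ∈ ℝ^m,
the fitted objective is

    min_{W,c}  Σ_k (1/n_k) Σ_i log(1 + exp(−y_ik (x_ikᵀ W_k + c_k)))
               + λ Σ_{j=1..d} ‖W_j·‖₂ .

The ℓ2,1 penalty zeroes entire rows of W, so every gene is either in or out
of **all** tasks at once; the selected panel is {j : ‖W_j·‖₂ > 0}. The
problem is convex and is solved by proximal gradient descent (ISTA) with a
backtracking line search; the penalty's proximal operator is row-wise block
soft-thresholding. λ is chosen by stratified 5-fold cross-validation on a
log grid anchored at λ_max (the smallest λ whose solution is all-zero).
Prediction averages the m task logits and applies the logistic link:
p̂ = σ((1/m) Σ_k (XW_k + c_k)), with class 1 declared when p̂ > τ (τ = 0.5).

The package also ships the four standard comparison methods (L1 and
elastic-net penalized logistic regression, solved by the same proximal
engine; ReliefF and mRMR filters feeding a logistic classifier), a synthetic
cohort generator with planted relevant genes, and a repeated-split
experiment harness.

## Worked example

```python
import numpy as np
from mtgsel import (preset_config, simulate_dataset, split_train_test,
                    SplitSpec, fit_pipeline, selection_metrics)

sim = simulate_dataset(preset_config("S1", seed=1))   # n=100, d=500, 20 planted genes
train, test = split_train_test(sim.dataset, SplitSpec(0.5, seed=1))
model, selection, cv = fit_pipeline(train, m=8, eta=0.7, seed=1)

acc = (model.predict(test.matrix) == test.labels).mean()
n_sel, n_rec = selection_metrics(selection.selected, sim.truth)
print(f"lambda={cv.chosen_lambda:.4f}  selected={n_sel}  "
      f"recovered={n_rec}/20  test_acc={acc:.2f}")
```

prints

```
lambda=0.4307  selected=7  recovered=2/20  test_acc=0.52
```

i.e. on this cohort cross-validation keeps the penalty large, the panel has 7
genes of which 2 are truly relevant, and test accuracy is near chance — at
n_train = 50 with equal-magnitude planted coefficients the per-gene signal is
close to the detection floor (see `docs/methods.md` for why, and for what the
generator does and does not emulate).

The same pipeline is available from the shell:

```
mtgsel simulate --preset S1 --seed 1 --out-prefix scratch/s1
mtgsel fit --expr scratch/s1.expr.tsv --labels scratch/s1.labels.tsv \
       --m 8 --seed 1 --out-model scratch/model.json \
       --out-genes scratch/genes.tsv --out-metrics scratch/metrics.json
mtgsel predict --model scratch/model.json --expr scratch/s1.expr.tsv --out scratch/pred.csv
```

plus `cv`, `compare` (repeated-split method comparison) and `sweep-k`
(ensemble-size curve). Real cohorts are read from delimited text: an
expression table with one header row and one id column (either orientation)
and a two-column `sample_id<TAB>class` label file.

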
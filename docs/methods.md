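# Methods

## Overview

`advint` studies how adversarial training changes a single-cell cell-type
classifier along two axes: robustness (accuracy under gradient-sign
attacks) and interpretability (how well standard attribution methods
recover the genes that truly define each cell type). Because real tissues
come without a ground-truth key-gene list, the package ships a synthetic
expression generator with designated master-regulator genes per cell type;
the generator's exported truth list is the yardstick for every
interpretability claim.

## Synthetic data generator

The generator emulates the statistical structure of GRN-driven single-cell
simulators (type-specific master regulators, propagated regulatory
effects, overdispersed counts, dropout) without integrating stochastic
dynamics. Expression of gene *g* in a cell of type *t* is drawn as

    mu(t, g) = baseline                                (unregulated gene)
             = baseline * fold                         (key gene of t)
             = baseline * (1 + prop * effect * (fold - 1))  (target of a key gene of t)
    count ~ NegativeBinomial(mean = mu, var = mu + phi * mu^2)
    observed = count * Bernoulli(1 - dropout)

Defaults: 2700 cells in nine equal types, 1200 genes, 65 key genes (eight
types with 7, one with 9), each key gene regulating 5 disjoint targets with
effect +1, `baseline = 2` counts, `fold = 5`, `prop = 0.5`, `phi = 0.3`,
`dropout = 0.3`. The network topology and cell allocation are deliberately
simple and fully overridable through `GRNSpec`; the defaults are stand-ins
for a generating network we could not reproduce exactly. The noise level
was fixed once so that the default dataset sits in the high-90s held-out
accuracy regime reported for comparable simulated benchmarks (~98% with
the default classifier); harder or easier regimes are a config change
away. What the generator does **not** emulate: trajectories/pseudotime,
batch effects, cell-size covariates beyond library depth, and
transcriptional bursting dynamics. Conclusions from passing tests
therefore concern the method pipeline, not biological completeness of the
simulation.

Class imbalance is modelled by `subsample_cell_types`, which retains
`ceil((1 - fraction) * n)` cells of each named type — `ceil` so a type is
never silently emptied.

## Preprocessing

"Scaled, centered, log-normalized" is fixed as: depth-normalize each cell
to the median training library size, `log1p`, then center/scale each gene
to zero mean and unit variance. This is the only ordering in which all
three steps are standard practice. Normalization statistics are learned on
the training split only and applied unchanged to the test split, so no
leakage occurs. Zero-variance genes stay at zero and are flagged rather
than divided by zero.

Highly-variable-gene selection first removes genes with fewer than 30 total
raw counts, then ranks the survivors by the dispersion (variance/mean) of
their log1p depth-normalized values and keeps the top 2500; ties at the
boundary keep input gene order for determinism. On the 1200-gene default
simulation the HVG step is disabled (2500 > 1200 would be vacuous); it is
exercised on wider matrices. The 80/20 train/test split is stratified by
cell type — required for the imbalance experiment to keep rare types in
both partitions.

## Classifier

A fully connected network (default input → 256 ReLU → 128 ReLU → softmax)
trained with categorical cross-entropy and Adam (30 epochs, batch 64,
learning rate 1e-3). The implementation is a compact numpy MLP whose
backward pass is exposed: `gradient_loss` and `gradient_score` return the
exact derivative of the per-sample loss / pre-softmax class score with
respect to the input, the single contract that both the attacks and all
attribution methods consume. Gradients are verified against central finite
differences (1e-4 relative) in the test suite. The default architecture is
a stated choice, recoverable by the provided grid search over depth and
width (validation: stratified 10% of train; ties prefer fewer parameters).

## Attacks and adversarial training

FGSM: `x_adv = x + eps * sign(dL/dx)`, gradient taken at the true label.
PGD: iterated steps of size `alpha` (default `eps/4`, 10 iterations), each
iterate clipped to the l-infinity ball of radius `eps` around the original
cell; FGSM is exactly PGD with one step of size `eps`. Attacks operate in
the normalized feature space the model consumes, where `eps` is measured
in per-gene standard deviations; non-negativity clipping is available for
count-space use but off by default.

Adversarial training default is the *static* regime: train a warm-start
model, craft one adversarial copy of every training cell (doubling 2700
cells to 5400 in the full-data configuration), and retrain from scratch on
the combined set. A *per-epoch* regime (fresh adversarial batch against
the current weights before every epoch) is available; it hardens a model
against self-targeted attacks but generalizes poorly to perturbations
crafted against other models, which is not the comparison this pipeline
reports.

Robustness is evaluated under a fixed attack distribution: adversarial
copies of the held-out test cells are crafted against the standard-trained
model, and both models are scored on the same attacked data. This mirrors
a robustness comparison in which the attack is defined once per attack
level and the two training regimes face it side by side. A white-box sweep
(each model attacked through its own gradients) is available via
`epsilon_sweep(..., attack_model=None)`; white-box robustness of the
statically trained model is substantially lower, as expected.

Since visual inspection of embeddings is not a testable criterion, the
"does the attack preserve data structure" judgement is quantified as
neighborhood preservation: the mean Jaccard overlap of each cell's
k-nearest-neighbor set (Euclidean, k = 15) before vs after perturbation.
It is 1.0 for untouched data and decays toward the random-overlap level
`k/(n-1)` as structure dissolves; it decreases monotonically with the
attack level on the default data, and the attack level recommended by the
sweep is the smallest grid point whose attacked accuracy falls below half
the clean accuracy while preservation stays above 0.8. Note that raw
k-NN-identity overlap in 1200 dimensions is a strict criterion: moderate
attack levels that leave cluster-level structure intact already shuffle
individual neighbor identities, so the per-cell preservation values are
small in absolute terms and are best read comparatively across attack
levels.

## Attribution methods

All six methods attribute the **pre-softmax class score** (not the
probability), avoiding vanished gradients at confident predictions and
keeping methods comparable. Defaults: training-set mean baseline for
DeepLIFT and kernel SHAP; sampled training cells for expected gradients;
Gaussian local perturbations for LIME.

* **Saliency** — the input gradient of the class score, verbatim from the
  gradient contract.
* **Activation maximization** — projected gradient ascent of the class
  score over an l2 ball (radius 10 in normalized units, backtracking step
  size so the objective trace is non-decreasing); gene importance is
  `|x*|`. The ball radius bounds the synthetic input to the scale of real
  normalized cells.
* **DeepLIFT (rescale rule)** — each ReLU's derivative is replaced by the
  finite-difference multiplier between input and baseline
  pre-activations, falling back to the local gradient when the two
  coincide within 1e-7; contributions satisfy completeness to 1e-5.
* **Expected gradients** — Monte-Carlo average of gradient-at-interpolated
  -point times (x - baseline) over sampled baselines and uniform
  interpolation coefficients (default 100 samples).
* **Kernel SHAP** — weighted least squares over sampled feature
  coalitions with the Shapley kernel, masked genes set to the baseline;
  the completeness constraint is eliminated exactly. Exhaustive
  enumeration (d <= 20) reproduces exact Shapley values and is the test
  oracle. Default 2048 coalitions for 1200 genes.
* **LIME** — weighted ridge surrogate on 1000 Gaussian perturbations with
  exponential kernel width `0.75 * sqrt(d)`; sparsity by greedy weighted
  forward selection of 50 genes (incremental Cholesky, so selection is
  exact at each step).

Per-cell attributions are aggregated per cell type as the mean absolute
attribution over that type's correctly classified cells, computed against
the type's own output unit (falling back to all cells of a type that has
no correct predictions). The expensive estimators scale linearly in cells
explained, so the pipeline attributes a deterministic sample of 5
correctly classified exemplar cells per type by default; this is a
problem-size choice, adjustable via `cells_per_type`, and the recovery
results are stable across exemplar draws at the default effect sizes.

## Consensus and evaluation

The consensus importance score of (gene, type) is the number of methods
(0–6) ranking the gene in their top N = 20 for that type. Consensus
ranking breaks vote ties by the mean max-normalized score across methods,
then input gene order. Key-gene recovery counts the truth genes of each
type found in the top-20 list. The non-model baseline is one-vs-rest
two-sided Wilcoxon rank-sum tests per gene with Benjamini–Hochberg
correction within each cell type (per-contrast correction mirrors standard
one-vs-rest DGE practice); constant genes get p = 1. Overlap reports
intersect the consensus and DGE top-k lists per type.

## Numerical and reproducibility notes

All randomness flows from a single seed through named `SeedSequence`
substreams; every artifact of `run_full_experiment` is bitwise
reproducible and hashed into a manifest. Ranking ties anywhere
(dispersion, attribution scores, votes) are broken by input order via
stable sorts. Degenerate inputs are handled explicitly: zero-variance
genes flagged, zero-depth cells rejected, empty coalition regressions and
vanished LIME kernels raise informative errors, non-finite training loss
raises a divergence error naming the epoch.

## Known limitations

* The generator's independence of genes given type (beyond the designed
  regulatory fan-out) makes attribution easier than in real tissue with
  correlated programs; recovery counts here are an upper bound on what
  the same pipeline achieves on real data.
* Robustness conclusions are attack-specific (gradient-sign family) and
  protocol-specific (fixed attack distribution); certified or black-box
  robustness is out of scope.
* The DeepLIFT implementation covers affine + elementwise-ReLU networks
  (the packaged classifier), not arbitrary architectures.
* Differential-expression p-values on heavily tied sparse counts rely on
  the normal approximation with tie correction.
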
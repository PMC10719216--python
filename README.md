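# advint — adversarial training and interpretability for single-cell classifiers

`advint` is a tested pipeline for studying how **adversarial training**
changes a neural cell-type classifier trained on single-cell RNA-seq
expression — both its **robustness** to gradient-sign attacks and its
**interpretability**, measured as the recovery of ground-truth key genes
by standard feature-attribution methods. It is aimed at computational
biologists who want a controlled, fully reproducible environment for
these questions: a synthetic expression generator with designated
master-regulator genes provides the ground truth that real tissues lack.

## What it computes

* **Synthetic ground truth** — a cells × genes count matrix over
  $T$ cell types. Each type $t$ owns a set of key genes whose mean is
  elevated by a fold factor and propagates a fraction of that elevation to
  target genes; counts are negative-binomial with Bernoulli dropout.
  Defaults: 2700 cells, 1200 genes, 9 types, 65 key genes.
* **Classifier** — an MLP $M$ (input → 256 ReLU → 128 ReLU → softmax)
  trained with categorical cross-entropy; exposes exact input gradients
  $\nabla_x L(M(x), y)$ and $\partial M_k(x)/\partial x$.
* **Attacks** — FGSM, $x^{adv} = x + \epsilon\,\mathrm{sign}(\nabla_x L)$,
  and PGD, its iterated variant projected onto the
  $\ell_\infty$ ball of radius $\epsilon$; attack-level sweeps report
  attacked accuracy and a k-NN neighborhood-preservation score per
  $\epsilon$.
* **Adversarial training** — augmenting the training split with one
  adversarial copy of every cell (2700 → 5400 at full scale) and
  retraining.
* **Attribution** — saliency maps, activation maximization, DeepLIFT
  (rescale rule), expected gradients, kernel SHAP and LIME, all against
  the pre-softmax class score; per-type scores are mean absolute
  attributions over correctly classified cells.
* **Consensus and evaluation** — the consensus importance score of a
  (gene, type) pair is the number of methods (0–6) ranking the gene in
  their top-20 for that type; recovery counts truth genes found per type.
  A one-vs-rest Wilcoxon rank-sum DGE with Benjamini–Hochberg correction
  is the non-model baseline.

See `docs/methods.md` for the full model description, parameter meanings
and limitations.

## Worked example

```python
import numpy as np
import advint
from advint.attacks import AttackConfig, adversarial_train, fgsm
from advint.consensus import consensus_importance, key_gene_recovery
from advint.interpret import attribution_suite
from advint.preprocess import LogScaleNormalizer, normalize_log_scale

# 1. simulate the default ground-truth dataset
data, truth = advint.simulate_dataset(advint.SimConfig(seed=1))

# 2. stratified 80/20 split, normalization fitted on train only
train_raw, test_raw = advint.split_train_test(data, 0.8, seed=1)
norm = LogScaleNormalizer().fit(np.asarray(train_raw.X))
train, _ = normalize_log_scale(train_raw, norm)
test, _ = normalize_log_scale(test_raw, norm)

# 3. standard vs adversarially trained classifier (FGSM, eps = 1.0)
std = advint.train_classifier(train, seed=1)
rob = adversarial_train(train, attack=AttackConfig(epsilon=1.0), seed=1)

X, y = np.asarray(test.X), test.obs["cell_type"].to_numpy().astype(str)
X_adv = fgsm(std, X, y, 1.0)   # attack crafted against the standard model
for name, model in (("standard", std), ("adversarial", rob)):
    clean = advint.evaluate(model, test).accuracy
    attacked = float(np.mean(model.predict(X_adv) == y))
    print(f"{name:12s} clean accuracy {clean:.3f}   attacked accuracy {attacked:.3f}")

# 4. six-method consensus vote and key-gene recovery (top 20 per type)
for name, model in (("standard", std), ("adversarial", rob)):
    mats = attribution_suite(model, train, seed=1)
    rep = key_gene_recovery(consensus_importance(mats, n=20), truth, n=20)
    print(f"{name:12s} key genes recovered: {rep.total_detected}/65")
```

Output:

```
standard     clean accuracy 0.980   attacked accuracy 0.000
adversarial  clean accuracy 0.980   attacked accuracy 0.950
standard     key genes recovered: 60/65
adversarial  key genes recovered: 62/65
```

Reading it: the standard classifier is accurate on clean cells but
collapses under an attack of level 1.0 (one standard deviation per gene);
the adversarially trained model keeps both clean accuracy and accuracy on
the attacked cells, and its attributions recover more of the 65 designated
key genes. The whole experiment — including the attack-level sweep, the
class-imbalance variant, DGE baseline and overlap reports — runs as one
call, `advint.run_full_experiment()`, or from the shell:

```bash
advint run --config experiment.yaml --out results/ --seed 1
```

Every artifact is written with a manifest of settings, seeds and content
hashes; reruns with the same config are bitwise identical.

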
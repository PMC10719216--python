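"""Gradient- and perturbation-based feature attribution.

Six methods score genes for their influence on a class of the trained
classifier: saliency maps, activation maximization, DeepLIFT (rescale
rule), expected gradients (the sampling scheme behind SHAP's gradient
explainer), kernel SHAP, and LIME. All attribute the **pre-softmax class
score**, which keeps gradients informative at confident predictions and
makes the methods comparable to one another.

Per-cell attributions are aggregated to a genes x cell-types
:class:`AttributionMatrix` by :func:`per_class_importance`: the mean
absolute attribution over each type's correctly classified cells, computed
against that type's output unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .classifier import CellTypeMLP, _get_xy
from .errors import DivergenceError, ParameterError
from .simdata import LABEL_KEY

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineSpec",
    "AttributionMatrix",
    "saliency",
    "activation_maximization",
    "deeplift_rescale",
    "expected_gradients",
    "kernel_shap",
    "lime_tabular",
    "per_class_importance",
    "attribution_suite",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("saliency", "actmax", "deeplift", "expgrad", "kernelshap", "lime")


@dataclass(frozen=True)
class BaselineSpec:
    """Reference input(s) that attributions are measured against."""

    kind: str = "training-mean"  # zeros | training-mean | sampled-references
    n_samples: int = 25

    def resolve(self, reference: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Materialize baseline rows from a pool of reference cells."""
        reference = np.atleast_2d(np.asarray(reference, dtype=np.float64))
        if reference.shape[0] == 0:
            raise ParameterError("baseline reference pool is empty")
        if self.kind == "zeros":
            return np.zeros((1, reference.shape[1]))
        if self.kind == "training-mean":
            return reference.mean(axis=0, keepdims=True)
        if self.kind == "sampled-references":
            idx = rng.integers(0, reference.shape[0], size=self.n_samples)
            return reference[idx]
        raise ParameterError(f"unknown baseline kind {self.kind!r}")


@dataclass
class AttributionMatrix:
    """Per-gene importance by cell type for one attribution method."""

    method: str
    scores: pd.DataFrame  # genes x cell types
    n_cells_aggregated: dict[str, int]
    baseline: str = ""

    def top_genes(self, cell_type: str, n: int) -> list[str]:
        """Top-n genes by descending score; ties keep input gene order."""
        col = self.scores[cell_type].to_numpy()
        order = np.argsort(-col, kind="stable")[:n]
        return [self.scores.index[i] for i in order]


# ----------------------------------------------------------------- saliency
def saliency(model: CellTypeMLP, x: np.ndarray, class_index: int) -> np.ndarray:
    """Gradient of the class score w.r.t. the input, per gene."""
    x2 = np.atleast_2d(np.asarray(x, dtype=np.float64))
    g = model.gradient_score(x2, class_index)
    return g[0] if np.ndim(x) == 1 else g


# ------------------------------------------------- activation maximization
def activation_maximization(
    model: CellTypeMLP,
    class_index: int,
    constraint_radius: float = 10.0,
    n_steps: int = 200,
    step_size: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Input that maximizes one class score over an l2 ball.

    Projected gradient ascent with backtracking: a step is only accepted if
    it does not decrease the objective, so the returned trace is monotone
    non-decreasing. Returns ``(x_star, objective_trace)``; per-gene
    importance is ``|x_star|``.
    """
    if constraint_radius <= 0:
        raise ParameterError("constraint_radius must be > 0")
    rng = np.random.default_rng(seed)
    d = model.n_features_in_

    def project(v: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(v)
        if norm > constraint_radius:
            v = v * (constraint_radius / norm)
        return v

    def objective(v: np.ndarray) -> float:
        return float(model.decision_function(v[None, :])[0, class_index])

    x = project(rng.normal(0.0, 0.01, size=d))
    obj = objective(x)
    if not np.isfinite(obj):
        raise DivergenceError("objective non-finite at initialization")
    trace = [obj]
    lr = step_size
    for _ in range(n_steps):
        g = model.gradient_score(x[None, :], class_index)[0]
        cand = project(x + lr * g)
        cand_obj = objective(cand)
        if not np.isfinite(cand_obj):
            raise DivergenceError("objective diverged during ascent")
        if cand_obj >= obj:
            x, obj = cand, cand_obj
            trace.append(obj)
        else:
            lr *= 0.5
            if lr < 1e-12:
                break
    return x, np.asarray(trace)


# ----------------------------------------------------------------- DeepLIFT
def deeplift_rescale(
    model: CellTypeMLP,
    x: np.ndarray,
    baseline: np.ndarray,
    class_index: int,
    tol: float = 1e-7,
) -> np.ndarray:
    """Rescale-rule contributions of each gene to one class score.

    Every ReLU's derivative is replaced by the finite-difference multiplier
    ``(f(z) - f(z')) / (z - z')`` between the input's and the baseline's
    pre-activations (falling back to the local gradient where the two
    coincide within ``tol``), and the resulting linear system is chained
    back to the input. Satisfies completeness: contributions sum to
    ``M(x) - M(x')`` up to floating point.
    """
    single = np.ndim(x) == 1
    X = np.atleast_2d(np.asarray(x, dtype=np.float64))
    ref = np.asarray(baseline, dtype=np.float64).reshape(1, -1)
    if ref.shape[1] != X.shape[1]:
        raise ParameterError("baseline length must match the number of genes")

    # forward passes keeping pre-activations of the hidden layers
    def forward_z(A: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        zs, acts = [], [A]
        a = A
        n = len(model.coefs_)
        for i, (W, b) in enumerate(zip(model.coefs_, model.intercepts_)):
            z = a @ W + b
            zs.append(z)
            a = z if i == n - 1 else np.maximum(z, 0.0)
            acts.append(a)
        return zs, acts

    zs_x, acts_x = forward_z(X)
    zs_r, acts_r = forward_z(ref)

    n_layers = len(model.coefs_)
    delta = np.zeros((X.shape[0], len(model.classes_)))
    delta[:, class_index] = 1.0
    for i in range(n_layers - 1, -1, -1):
        if i < n_layers - 1:
            dz = zs_x[i] - zs_r[i]
            da = acts_x[i + 1] - acts_r[i + 1]
            local = (zs_x[i] > 0).astype(np.float64)
            with np.errstate(divide="ignore", invalid="ignore"):
                mult = np.where(np.abs(dz) > tol, da / dz, local)
            delta = delta * mult
        delta = delta @ model.coefs_[i].T
    contrib = (X - ref) * delta
    return contrib[0] if single else contrib


# -------------------------------------------------------- expected gradients
def expected_gradients(
    model: CellTypeMLP,
    x: np.ndarray,
    baselines: np.ndarray,
    class_index: int,
    n_samples: int = 100,
    seed: int = 0,
    t_values: np.ndarray | None = None,
) -> np.ndarray:
    """Monte-Carlo SHAP-style scores along baseline->input paths.

    Each sample draws a baseline row and an interpolation coefficient
    ``t ~ U(0, 1)``, evaluates the class-score gradient at the interpolated
    point and multiplies it by ``x - x'``; the estimate is the sample mean.
    ``t_values`` fixes the interpolation points (for deterministic checks).
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    baselines = np.atleast_2d(np.asarray(baselines, dtype=np.float64))
    if baselines.shape[0] == 0:
        raise ParameterError("baseline pool is empty")
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, baselines.shape[0], size=n_samples)
    t = rng.random(n_samples) if t_values is None else np.broadcast_to(
        np.asarray(t_values, dtype=np.float64), (n_samples,)
    )
    refs = baselines[idx]
    points = refs + t[:, None] * (x[None, :] - refs)
    grads = model.gradient_score(points, class_index)
    return np.mean(grads * (x[None, :] - refs), axis=0)


# ---------------------------------------------------------------- kernel SHAP
def _shapley_kernel_weights(d: int, sizes: np.ndarray) -> np.ndarray:
    from scipy.special import comb

    return (d - 1) / (comb(d, sizes) * sizes * (d - sizes))


def kernel_shap(
    model_fn,
    x: np.ndarray,
    baseline: np.ndarray,
    n_coalitions: int = 2048,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Shapley value estimates by weighted least squares over coalitions.

    ``model_fn`` maps a batch of inputs to scalar outputs (here: one
    pre-softmax class score). Masked-out genes take the baseline's value.
    The completeness constraint ``sum(phi) = f(x) - f(x')`` is enforced
    exactly by eliminating one coordinate. With ``exhaustive=True`` all
    ``2^d - 2`` proper coalitions are enumerated with exact Shapley-kernel
    weights, which reproduces exact Shapley values.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    baseline = np.asarray(baseline, dtype=np.float64).reshape(-1)
    d = x.size
    if baseline.size != d:
        raise ParameterError("baseline length must match the number of genes")
    if d < 2:
        raise ParameterError("kernel SHAP needs at least 2 features")

    if exhaustive:
        if d > 20:
            raise ParameterError("exhaustive enumeration is limited to d <= 20")
        masks = (
            (np.arange(2**d)[:, None] >> np.arange(d)) & 1
        ).astype(np.float64)[1:-1]
        weights = _shapley_kernel_weights(d, masks.sum(axis=1))
    else:
        if n_coalitions < d + 2:
            raise ParameterError("n_coalitions must be at least n_genes + 2")
        rng = np.random.default_rng(seed)
        sizes = np.arange(1, d)
        p = (d - 1) / (sizes * (d - sizes))
        p /= p.sum()
        draw = rng.choice(sizes, size=n_coalitions, p=p)
        masks = np.zeros((n_coalitions, d))
        for i, s in enumerate(draw):
            masks[i, rng.choice(d, size=s, replace=False)] = 1.0
        weights = np.ones(n_coalitions)

    inputs = masks * x[None, :] + (1.0 - masks) * baseline[None, :]
    v = np.asarray(model_fn(inputs), dtype=np.float64).reshape(-1)
    v0 = float(np.asarray(model_fn(baseline[None, :])).reshape(-1)[0])
    fx = float(np.asarray(model_fn(x[None, :])).reshape(-1)[0])

    # eliminate the last coordinate via the completeness constraint
    A = masks[:, :-1] - masks[:, -1:]
    b = v - v0 - masks[:, -1] * (fx - v0)
    Aw = A * weights[:, None]
    G = A.T @ Aw
    G[np.diag_indices_from(G)] += 1e-10
    try:
        phi_head = np.linalg.solve(G, Aw.T @ b)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            "singular coalition regression; increase n_coalitions"
        ) from exc
    phi = np.empty(d)
    phi[:-1] = phi_head
    phi[-1] = (fx - v0) - phi_head.sum()
    return phi


# ----------------------------------------------------------------------- LIME
def lime_tabular(
    model_fn,
    x: np.ndarray,
    n_perturbations: int = 1000,
    kernel_width: float | None = None,
    n_features_kept: int = 50,
    ridge: float = 1.0,
    perturbation_scale: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Local ridge surrogate of ``model_fn`` around one cell.

    Gaussian perturbations of ``x`` are scored by the model, weighted by an
    exponential kernel ``exp(-||z - x||^2 / width^2)`` (default width
    ``0.75 * sqrt(d)``), and a sparse weighted ridge surrogate is fitted:
    ``n_features_kept`` genes are chosen by greedy weighted forward
    selection, then their coefficients are returned in a full-length vector
    (zeros elsewhere).
    """
    if n_perturbations < 10:
        raise ParameterError("n_perturbations must be >= 10")
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    d = x.size
    kw = 0.75 * np.sqrt(d) if kernel_width is None else kernel_width
    if kw <= 0:
        raise ParameterError("kernel_width must be > 0")
    k = min(n_features_kept, d)

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, perturbation_scale, size=(n_perturbations, d))
    Z = x[None, :] + noise
    y = np.asarray(model_fn(Z), dtype=np.float64).reshape(-1)
    dist2 = np.sum(noise**2, axis=1)
    w = np.exp(-dist2 / kw**2)
    if w.sum() <= 0 or not np.isfinite(w.sum()):
        raise ParameterError("kernel weights vanished; increase kernel_width")

    # center in the weighted sense so no intercept column is needed
    wsum = w.sum()
    Zc = Z - (w @ Z) / wsum
    yc = y - (w @ y) / wsum
    G = Zc.T @ (Zc * w[:, None])  # weighted Gram, d x d
    c = Zc.T @ (yc * w)

    # greedy forward selection with incremental Cholesky of G_SS + ridge*I
    from scipy.linalg import solve_triangular

    selected: list[int] = []
    L = np.zeros((k, k))
    csel = np.zeros(k)
    remaining = np.ones(d, dtype=bool)
    for _ in range(k):
        s = len(selected)
        cand = np.flatnonzero(remaining)
        if s:
            U = solve_triangular(
                L[:s, :s], G[np.ix_(selected, cand)], lower=True
            )  # s x m
            t = solve_triangular(L[:s, :s], csel[:s], lower=True)
            denom = G[cand, cand] + ridge - np.sum(U**2, axis=0)
            num = c[cand] - U.T @ t
        else:
            U = None
            denom = G[cand, cand] + ridge
            num = c[cand]
        denom = np.clip(denom, 1e-12, None)
        gains = num**2 / denom
        j_local = int(np.argmax(gains))
        j = int(cand[j_local])
        # append row to the Cholesky factor
        if s:
            L[s, :s] = U[:, j_local]
        L[s, s] = np.sqrt(denom[j_local])
        csel[s] = c[j]
        selected.append(j)
        remaining[j] = False

    Msel = G[np.ix_(selected, selected)] + ridge * np.eye(k)
    beta = np.linalg.solve(Msel, c[selected])
    coef = np.zeros(d)
    coef[selected] = beta
    return coef


# ------------------------------------------------------------- aggregation
def per_class_importance(
    per_cell_scores: np.ndarray,
    labels: np.ndarray,
    correct: np.ndarray,
    gene_ids,
    class_names,
    method: str = "",
    baseline: str = "",
) -> AttributionMatrix:
    """Aggregate per-cell attributions to a genes x cell-types matrix.

    ``per_cell_scores[i]`` must be the attribution of cell ``i`` toward its
    own labelled class. The score of (gene, type) is the mean absolute
    attribution over the type's correctly classified cells; a class with no
    correct cell falls back to all of its cells (with a warning).
    """
    per_cell_scores = np.asarray(per_cell_scores, dtype=np.float64)
    labels = np.asarray(labels)
    correct = np.asarray(correct, dtype=bool)
    cols = {}
    counts = {}
    for cls in class_names:
        mask = (labels == cls) & correct
        if not mask.any():
            logger.warning(
                "no correctly classified cells of type %s; using all cells", cls
            )
            mask = labels == cls
        cols[cls] = np.abs(per_cell_scores[mask]).mean(axis=0)
        counts[str(cls)] = int(mask.sum())
    frame = pd.DataFrame(cols, index=list(gene_ids))
    return AttributionMatrix(
        method=method, scores=frame, n_cells_aggregated=counts, baseline=baseline
    )


# ------------------------------------------------------------ method suite
def attribution_suite(
    model: CellTypeMLP,
    data: ad.AnnData,
    reference: ad.AnnData | None = None,
    methods=DEFAULT_METHODS,
    cells_per_type: int = 5,
    n_coalitions: int = 2048,
    eg_samples: int = 100,
    lime_perturbations: int = 1000,
    lime_features_kept: int = 50,
    actmax_radius: float = 10.0,
    seed: int = 0,
) -> dict[str, AttributionMatrix]:
    """Run the requested attribution methods over a labeled dataset.

    Per-cell methods are evaluated on up to ``cells_per_type`` correctly
    classified exemplar cells per type (chosen deterministically from the
    seed) — the expensive estimators (kernel SHAP, LIME) scale linearly in
    the number of cells explained. ``reference`` (default: ``data``)
    provides the baseline pool.
    """
    X, y = _get_xy(data)
    ref = X if reference is None else np.asarray(reference.X, dtype=np.float64)
    gene_ids = list(data.var_names)
    class_names = [str(c) for c in model.classes_]
    pred = model.predict(X)
    correct_all = pred == y
    rng = np.random.default_rng(seed)

    # exemplar cells: correctly classified where possible
    chosen: list[int] = []
    for cls in class_names:
        pool = np.flatnonzero((y == cls) & correct_all)
        if pool.size == 0:
            pool = np.flatnonzero(y == cls)
        take = min(cells_per_type, pool.size)
        chosen.extend(rng.choice(pool, size=take, replace=False))
    chosen_arr = np.sort(np.asarray(chosen, dtype=int))
    Xc, yc = X[chosen_arr], y[chosen_arr]
    correct_c = correct_all[chosen_arr]
    cls_index = {c: i for i, c in enumerate(class_names)}
    y_idx = np.array([cls_index[v] for v in yc])

    mean_baseline = ref.mean(axis=0)
    results: dict[str, AttributionMatrix] = {}

    def aggregate(scores: np.ndarray, name: str, baseline: str) -> AttributionMatrix:
        return per_class_importance(
            scores, yc, correct_c, gene_ids, class_names, method=name, baseline=baseline
        )

    for method in methods:
        if method == "saliency":
            scores = np.stack(
                [model.gradient_score(Xc[i : i + 1], y_idx[i])[0] for i in range(len(yc))]
            )
            results[method] = aggregate(scores, method, "none")
        elif method == "actmax":
            cols = {}
            for cls in class_names:
                x_star, _ = activation_maximization(
                    model,
                    cls_index[cls],
                    constraint_radius=actmax_radius,
                    seed=int(rng.integers(2**31)),
                )
                cols[cls] = np.abs(x_star)
            frame = pd.DataFrame(cols, index=gene_ids)
            results[method] = AttributionMatrix(
                method=method,
                scores=frame,
                n_cells_aggregated={c: 0 for c in class_names},
                baseline="none",
            )
        elif method == "deeplift":
            scores = np.stack(
                [
                    deeplift_rescale(model, Xc[i], mean_baseline, y_idx[i])
                    for i in range(len(yc))
                ]
            )
            results[method] = aggregate(scores, method, "training-mean")
        elif method == "expgrad":
            scores = np.stack(
                [
                    expected_gradients(
                        model,
                        Xc[i],
                        ref,
                        y_idx[i],
                        n_samples=eg_samples,
                        seed=int(rng.integers(2**31)),
                    )
                    for i in range(len(yc))
                ]
            )
            results[method] = aggregate(scores, method, "sampled-references")
        elif method == "kernelshap":
            scores = np.stack(
                [
                    kernel_shap(
                        lambda Z, k=y_idx[i]: model.decision_function(Z)[:, k],
                        Xc[i],
                        mean_baseline,
                        n_coalitions=n_coalitions,
                        seed=int(rng.integers(2**31)),
                    )
                    for i in range(len(yc))
                ]
            )
            results[method] = aggregate(scores, method, "training-mean")
        elif method == "lime":
            scores = np.stack(
                [
                    lime_tabular(
                        lambda Z, k=y_idx[i]: model.decision_function(Z)[:, k],
                        Xc[i],
                        n_perturbations=lime_perturbations,
                        n_features_kept=lime_features_kept,
                        seed=int(rng.integers(2**31)),
                    )
                    for i in range(len(yc))
                ]
            )
            results[method] = aggregate(scores, method, "gaussian-local")
        else:
            raise ParameterError(f"unknown attribution method {method!r}")
    return results
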
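"""Normalization, highly-variable-gene selection and train/test splitting.

The numerical workhorses are two scikit-learn style transformers operating
on plain ``cells x genes`` arrays:

* :class:`LogScaleNormalizer` — depth-normalize to the median library size
  of the fitting data, ``log1p``, then center/scale each gene to zero mean
  and unit variance (statistics learned on the fitting data only, so test
  data can be transformed without leakage).
* :class:`HVGSelector` — drop genes with fewer than ``min_counts`` total raw
  counts, rank the remainder by the dispersion (variance/mean) of their
  log1p depth-normalized values and keep the ``n_top`` most dispersed.

``normalize_log_scale`` / ``select_hvg`` / ``split_train_test`` wrap them
for :class:`~anndata.AnnData` pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ParameterError
from .simdata import LABEL_KEY

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "LogScaleNormalizer",
    "HVGSelector",
    "normalize_log_scale",
    "select_hvg",
    "split_train_test",
]


@dataclass
class PreprocessReport:
    """Bookkeeping emitted by the preprocessing operations."""

    n_genes_in: int
    n_genes_passing: int
    n_genes_retained: int
    retained_index: list[str] = field(default_factory=list)
    gene_mean: np.ndarray | None = None
    gene_sd: np.ndarray | None = None
    zero_variance_genes: list[str] = field(default_factory=list)


def _depth_normalize(X: np.ndarray, target_depth: float) -> np.ndarray:
    depths = X.sum(axis=1)
    if np.any(depths <= 0):
        raise ParameterError("cells with zero total counts cannot be depth-normalized")
    return X * (target_depth / depths)[:, None]


class LogScaleNormalizer(TransformerMixin, BaseEstimator):
    """Depth-normalize -> log1p -> per-gene standardization.

    Zero-variance genes (constant after log transform) are left at zero
    rather than divided by zero and are reported via ``zero_variance_mask_``.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        if X.min() < 0:
            raise ParameterError("raw expression values must be non-negative")
        self.median_depth_ = float(np.median(X.sum(axis=1)))
        L = np.log1p(_depth_normalize(X, self.median_depth_))
        self.gene_mean_ = L.mean(axis=0)
        self.gene_sd_ = L.std(axis=0)
        self.zero_variance_mask_ = self.gene_sd_ == 0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "gene_mean_")
        X = check_array(X, dtype=np.float64)
        if X.min() < 0:
            raise ParameterError("raw expression values must be non-negative")
        L = np.log1p(_depth_normalize(X, self.median_depth_))
        sd = np.where(self.zero_variance_mask_, 1.0, self.gene_sd_)
        return (L - self.gene_mean_) / sd


class HVGSelector(TransformerMixin, BaseEstimator):
    """Minimum-count filter followed by dispersion ranking on raw counts.

    Parameters
    ----------
    n_top : number of genes to retain (all qualifying genes if fewer pass).
    min_counts : minimum total raw counts for a gene to be considered.

    The filter runs strictly before the ranking, so a highly dispersed gene
    below the count floor is never retained. Ties at the selection boundary
    are broken by input gene order.
    """

    def __init__(self, n_top: int = 2500, min_counts: int = 30):
        self.n_top = n_top
        self.min_counts = min_counts

    def fit(self, X, y=None):
        if self.n_top <= 0:
            raise ParameterError("n_top must be positive")
        X = check_array(X, dtype=np.float64)
        total = X.sum(axis=0)
        passing = total >= self.min_counts
        L = np.log1p(_depth_normalize(X, float(np.median(X.sum(axis=1)))))
        mean = L.mean(axis=0)
        var = L.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mean > 0, var / mean, 0.0)
        disp = np.where(passing, disp, -np.inf)

        n_pass = int(passing.sum())
        n_keep = min(self.n_top, n_pass)
        if n_pass < self.n_top:
            logger.warning(
                "only %d genes pass min_counts=%d; retaining all of them "
                "(n_top=%d)", n_pass, self.min_counts, self.n_top,
            )
        # stable argsort on descending dispersion keeps input order on ties
        order = np.argsort(-disp, kind="stable")[:n_keep]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[np.sort(order)] = True
        self.dispersion_ = disp
        self.n_passing_ = n_pass
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, dtype=np.float64)
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


def normalize_log_scale(
    adata: ad.AnnData, normalizer: LogScaleNormalizer | None = None
) -> tuple[ad.AnnData, PreprocessReport]:
    """Standardized log expression; fits on ``adata`` unless given a
    pre-fitted normalizer (use that for leak-free test-set transforms)."""
    X = np.asarray(adata.X, dtype=np.float64)
    if normalizer is None:
        normalizer = LogScaleNormalizer().fit(X)
    out = adata.copy()
    out.X = normalizer.transform(X)
    flagged = list(np.asarray(adata.var_names)[normalizer.zero_variance_mask_])
    report = PreprocessReport(
        n_genes_in=adata.n_vars,
        n_genes_passing=adata.n_vars,
        n_genes_retained=adata.n_vars,
        retained_index=list(adata.var_names),
        gene_mean=normalizer.gene_mean_,
        gene_sd=normalizer.gene_sd_,
        zero_variance_genes=flagged,
    )
    return out, report


def select_hvg(
    adata: ad.AnnData, n_top: int = 2500, min_counts: int = 30
) -> tuple[ad.AnnData, PreprocessReport]:
    """Retain the top highly variable genes of a raw count matrix."""
    selector = HVGSelector(n_top=n_top, min_counts=min_counts).fit(
        np.asarray(adata.X, dtype=np.float64)
    )
    out = adata[:, selector.get_support()].copy()
    report = PreprocessReport(
        n_genes_in=adata.n_vars,
        n_genes_passing=selector.n_passing_,
        n_genes_retained=out.n_vars,
        retained_index=list(out.var_names),
    )
    return out, report


def split_train_test(
    adata: ad.AnnData, train_fraction: float = 0.8, seed: int = 0
) -> tuple[ad.AnnData, ad.AnnData]:
    """Disjoint, exhaustive, label-stratified partition of the cells."""
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must lie strictly between 0 and 1")
    labels = adata.obs[LABEL_KEY].to_numpy()
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ParameterError("every cell type needs at least 2 cells to stratify")
    idx_train, idx_test = train_test_split(
        np.arange(adata.n_obs),
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
    )
    return adata[np.sort(idx_train)].copy(), adata[np.sort(idx_test)].copy()
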
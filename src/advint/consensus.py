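"""Consensus importance voting, key-gene recovery and the DGE baseline.

The consensus importance score of a (gene, cell type) pair is the number of
attribution methods that place the gene in their top-N list for that type
(0..6 with the full method suite). Recovery is scored against the
simulator's ground-truth key-gene list; a one-vs-rest Wilcoxon rank-sum
differential-expression analysis with Benjamini–Hochberg correction serves
as the non-model baseline ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import DimensionError, ParameterError
from .interpret import AttributionMatrix
from .simdata import LABEL_KEY

__all__ = [
    "ConsensusTable",
    "RecoveryReport",
    "consensus_importance",
    "key_gene_recovery",
    "wilcoxon_dge",
    "dge_top_genes",
    "overlap_report",
]


@dataclass
class ConsensusTable:
    """Vote counts per (gene, cell type) across attribution methods."""

    votes: pd.DataFrame  # genes x cell types, integers 0..n_methods
    n: int
    methods: list[str]
    mean_normalized_score: pd.DataFrame  # tie-break ranking aid

    def top_genes(self, cell_type: str, n: int) -> list[str]:
        """Top-n genes by votes; ties broken by mean normalized score,
        then input gene order."""
        votes = self.votes[cell_type].to_numpy()
        tiebreak = self.mean_normalized_score[cell_type].to_numpy()
        order = np.lexsort((np.arange(votes.size), -tiebreak, -votes))[:n]
        return [self.votes.index[i] for i in order]


def consensus_importance(
    matrices: dict[str, AttributionMatrix] | list[AttributionMatrix],
    n: int = 20,
) -> ConsensusTable:
    """Count, per (gene, type), how many methods rank the gene top-n."""
    if isinstance(matrices, dict):
        items = list(matrices.values())
    else:
        items = list(matrices)
    if not items:
        raise ParameterError("need at least one attribution matrix")
    index = items[0].scores.index
    columns = items[0].scores.columns
    for m in items[1:]:
        if not m.scores.index.equals(index) or not m.scores.columns.equals(columns):
            raise DimensionError(
                f"attribution matrix {m.method!r} has a mismatched gene/type index"
            )

    votes = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    norm_sum = pd.DataFrame(0.0, index=index, columns=columns)
    for m in items:
        for ct in columns:
            for g in m.top_genes(ct, n):
                votes.loc[g, ct] += 1
        scores = m.scores.abs()
        peak = scores.max(axis=0).replace(0, 1.0)
        norm_sum += scores / peak
    return ConsensusTable(
        votes=votes,
        n=n,
        methods=[m.method for m in items],
        mean_normalized_score=norm_sum / len(items),
    )


@dataclass
class RecoveryReport:
    """Key genes detected in the top-N ranking, per cell type."""

    per_type: pd.DataFrame  # cell_type, detected, total
    n: int
    method: str
    condition: str

    @property
    def total_detected(self) -> int:
        return int(self.per_type["detected"].sum())


def key_gene_recovery(
    ranking: ConsensusTable | AttributionMatrix,
    truth: pd.DataFrame,
    n: int = 20,
    condition: str = "",
) -> RecoveryReport:
    """Count ground-truth key genes found in each type's top-n list."""
    if isinstance(ranking, ConsensusTable):
        columns = ranking.votes.columns
        index = ranking.votes.index
        method = "consensus"
    else:
        columns = ranking.scores.columns
        index = ranking.scores.index
        method = ranking.method
    missing = set(truth["gene"]) - set(index)
    if missing:
        raise ParameterError(f"truth genes absent from the ranking index: {sorted(missing)[:5]}")

    rows = []
    for ct in columns:
        truth_genes = set(truth.loc[truth["cell_type"] == ct, "gene"])
        top = set(ranking.top_genes(ct, n))
        rows.append(
            {
                "cell_type": ct,
                "detected": len(top & truth_genes),
                "total": len(truth_genes),
            }
        )
    return RecoveryReport(
        per_type=pd.DataFrame(rows), n=n, method=method, condition=condition
    )


def wilcoxon_dge(data: ad.AnnData, alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum tests per gene and type.

    P-values are Benjamini–Hochberg adjusted within each cell type;
    ``significant`` flags adjusted p below ``alpha``. Constant genes (all
    ties) are assigned p = 1.
    """
    X = np.asarray(data.X, dtype=np.float64)
    labels = data.obs[LABEL_KEY].to_numpy().astype(str)
    genes = list(data.var_names)
    frames = []
    for ct in pd.unique(labels):
        in_group = labels == ct
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            raise ParameterError(f"cell type {ct} needs >= 2 cells on both sides")
        a, b = X[in_group], X[~in_group]
        stat, p = mannwhitneyu(a, b, axis=0, alternative="two-sided")
        constant = (X.max(axis=0) - X.min(axis=0)) == 0
        p = np.where(constant, 1.0, p)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cell_type": ct,
                    "statistic": stat,
                    "p_value": p,
                    "p_adjusted": p_adj,
                    "significant": p_adj < alpha,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def dge_top_genes(dge: pd.DataFrame, cell_type: str, n: int) -> list[str]:
    """Top-n genes of one type by ascending adjusted then raw p-value."""
    sub = dge[dge["cell_type"] == cell_type]
    sub = sub.sort_values(["p_adjusted", "p_value"], kind="stable")
    return sub["gene"].head(n).tolist()


def overlap_report(
    consensus_top: dict[str, list[str]],
    dge_top: dict[str, list[str]],
    k: int,
    n_genes: int | None = None,
) -> pd.DataFrame:
    """Per-type intersection of model-derived and DGE-derived top-k lists."""
    if n_genes is not None and k > n_genes:
        raise ParameterError("k cannot exceed the number of genes")
    rows = []
    for ct in consensus_top:
        a, b = set(consensus_top[ct][:k]), set(dge_top[ct][:k])
        rows.append(
            {
                "cell_type": ct,
                "overlap": len(a & b),
                "consensus_only": sorted(a - b),
                "dge_only": sorted(b - a),
            }
        )
    return pd.DataFrame(rows)
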
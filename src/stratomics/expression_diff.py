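"""Cross-platform differential expression via within-sample rank transforms.

Because the two cohorts are profiled on different platforms, absolute
normalized expression is not comparable across them.  Each sample's values
are therefore replaced by their within-sample average ranks (rank 1 =
lowest; ties share the average rank), which are invariant under any
strictly monotone per-sample distortion — the property that makes the
between-cohort Mann-Whitney tests platform-robust.  Effect size
(log2 fold change) is still computed on the original normalized values,
with a pseudocount, because ranks carry no magnitude; a DEG must clear
both the adjusted-p and the |log2FC| threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix
from .stats import bh_adjust, mann_whitney_u

__all__ = [
    "filter_low_expression",
    "rank_transform",
    "test_differential_expression",
]


def filter_low_expression(
    matrix: ExpressionMatrix,
    threshold: float = 10.0,
    mode: str = "both_cohorts",
) -> ExpressionMatrix:
    """Drop genes with low mean normalized expression.

    ``both_cohorts`` removes a gene only when its mean is strictly below the
    threshold in *both* cohorts (kept if high in at least one);
    ``pooled`` uses the pooled mean.
    """
    labels = matrix.cohort_labels
    if mode == "both_cohorts":
        keep = pd.Series(False, index=matrix.values.index)
        for cohort in labels.unique():
            cols = labels[labels == cohort].index
            keep |= matrix.values[cols].mean(axis=1) >= threshold
    elif mode == "pooled":
        keep = matrix.values.mean(axis=1) >= threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ExpressionMatrix(values=matrix.values.loc[keep], cohort_labels=labels)


def rank_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Within-sample average ranks (ascending; ties -> average rank)."""
    return matrix.values.rank(axis=0, method="average")


def test_differential_expression(
    ranks: pd.DataFrame,
    original: ExpressionMatrix,
    p_threshold: float = 0.01,
    lfc_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney on ranks with dual DEG thresholds.

    BH adjustment spans the filtered gene family.  log2FC is
    log2((mean_A + pseudocount) / (mean_B + pseudocount)) on the original
    normalized values, cohort A over cohort B in sorted label order.
    """
    if not ranks.index.equals(original.values.index):
        raise ValueError("ranks and original matrix must share the same genes")
    if list(ranks.columns) != list(original.values.columns):
        raise ValueError("ranks and original matrix must share the same samples")
    labels = original.cohort_labels
    cohorts = sorted(labels.unique())
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {cohorts}")
    ca, cb = cohorts
    cols_a = labels[labels == ca].index
    cols_b = labels[labels == cb].index

    rank_a = ranks[cols_a].values
    rank_b = ranks[cols_b].values
    mean_a = original.values[cols_a].mean(axis=1).values
    mean_b = original.values[cols_b].mean(axis=1).values
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    pvals = np.empty(len(ranks.index))
    stats = np.empty(len(ranks.index))
    for i in range(len(ranks.index)):
        r = mann_whitney_u(rank_a[i], rank_b[i], mode="normal")
        pvals[i] = r.p_value
        stats[i] = r.statistic
    q = bh_adjust(pvals)
    df = pd.DataFrame(
        {
            f"mean_{ca}": mean_a,
            f"mean_{cb}": mean_b,
            "log2_fold_change": lfc,
            "u_statistic": stats,
            "p_value": pvals,
            "q_value": q,
        },
        index=ranks.index,
    )
    df["deg"] = (df["q_value"] < p_threshold) & (df["log2_fold_change"].abs() >= lfc_threshold)
    df["direction"] = np.where(df["log2_fold_change"] > 0, f"up_{ca}", np.where(df["log2_fold_change"] < 0, f"up_{cb}", ""))
    return df


def deg_partition(results: pd.DataFrame) -> dict[str, list[str]]:
    """Split DEGs into the up-in-A and up-in-B gene lists."""
    out: dict[str, list[str]] = {}
    degs = results[results["deg"]]
    for direction, sub in degs.groupby("direction"):
        out[direction] = sorted(sub.index)
    return out
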
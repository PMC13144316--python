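"""Gene-level mutation-frequency comparison between two cohorts.

A binary gene x sample indicator matrix is built from filtered variants
(1 = the sample carries at least one retained protein-altering mutation in
the gene).  Each gene is tested with a two-sided Fisher exact test on the
2x2 table (mutated vs not x cohort), p-values are Benjamini-Hochberg
adjusted, and discoveries are called at an FDR threshold (default 0.1).
Genes never mutated in either cohort are excluded from the testing family
(they carry p = 1 by construction and only dilute rank) and listed
separately; a config switch restores the all-genes family.

A within-cohort bootstrap quantifies the stability of each gene's log odds
ratio: columns are resampled with replacement independently inside each
cohort, preserving cohort sizes, and the fraction of resamples whose
log-OR sign matches the point estimate is reported as directional
consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import VariantRecord
from .stats import ContingencyTable2x2, bh_adjust, fisher_exact_two_sided

__all__ = [
    "MutationMatrix",
    "BootstrapStability",
    "build_mutation_matrix",
    "test_gene_frequencies",
    "bootstrap_log_or",
    "build_oncotable",
]


@dataclass
class MutationMatrix:
    """Binary mutation indicator (genes x samples) with cohort labels."""

    indicator: pd.DataFrame
    cohort_labels: pd.Series

    def __post_init__(self) -> None:
        vals = set(np.unique(self.indicator.values))
        if not vals <= {0, 1}:
            raise ValueError("indicator entries must be 0/1")
        self.cohort_labels = self.cohort_labels.loc[list(self.indicator.columns)]

    def cohort_columns(self, label: str) -> pd.DataFrame:
        return self.indicator.loc[:, self.cohort_labels[self.cohort_labels == label].index]


@dataclass(frozen=True)
class BootstrapStability:
    gene: str
    n_resamples: int
    log_or: float
    resample_mean: float
    resample_sd: float
    directional_consistency: float


def build_mutation_matrix(
    variants: Sequence[VariantRecord],
    rosters: Mapping[str, Sequence[str]],
    panel: Sequence[str],
) -> MutationMatrix:
    """Collapse variants to a gene x sample 0/1 matrix over full rosters.

    ``rosters`` maps cohort label -> complete sample list, so samples with
    no retained variants appear as all-zero columns.
    """
    samples: list[str] = []
    labels: dict[str, str] = {}
    for cohort, ids in rosters.items():
        for s in ids:
            if s in labels:
                raise ValueError(f"sample {s!r} listed in more than one roster")
            labels[s] = cohort
            samples.append(s)
    indicator = pd.DataFrame(0, index=list(panel), columns=samples, dtype=np.int8)
    for v in variants:
        if v.sample_id not in labels:
            raise ValueError(f"variant sample {v.sample_id!r} not on any roster")
        if v.gene in indicator.index:
            indicator.loc[v.gene, v.sample_id] = 1
    return MutationMatrix(indicator=indicator, cohort_labels=pd.Series(labels))


class _FisherCache:
    """Memoized Fisher p/OR keyed by the full 2x2 tuple.

    Cohort sizes are fixed across the per-gene scan, so the number of
    distinct tables is small and caching removes almost all recomputation.
    """

    def __init__(self) -> None:
        self._cache: dict[tuple[int, int, int, int], tuple[float, float]] = {}

    def __call__(self, a: int, b: int, c: int, d: int) -> tuple[float, float]:
        key = (a, b, c, d)
        if key not in self._cache:
            r = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            self._cache[key] = (r.p_value, r.odds_ratio)
        return self._cache[key]


def test_gene_frequencies(
    matrix: MutationMatrix,
    fdr_threshold: float = 0.1,
    family: str = "mutated",
) -> pd.DataFrame:
    """Per-gene Fisher tests with BH adjustment across the testing family.

    ``family='mutated'`` (default) adjusts across panel genes with at least
    one mutated sample overall; ``'all'`` adjusts across the whole panel.
    Returns a DataFrame indexed by gene with counts, frequencies, odds
    ratio, p, q, the significance flag and the enriched cohort; untested
    (never-mutated) genes carry ``tested=False``.
    """
    cohorts = sorted(matrix.cohort_labels.unique())
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {cohorts}")
    ca, cb = cohorts
    block_a = matrix.cohort_columns(ca).values
    block_b = matrix.cohort_columns(cb).values
    n_a, n_b = block_a.shape[1], block_b.shape[1]
    mut_a = block_a.sum(axis=1)
    mut_b = block_b.sum(axis=1)

    fisher = _FisherCache()
    rows = []
    for gene, a, c in zip(matrix.indicator.index, mut_a, mut_b):
        a, c = int(a), int(c)
        tested = (a + c) > 0 or family == "all"
        p, or_ = fisher(a, n_a - a, c, n_b - c) if tested else (1.0, math.nan)
        rows.append(
            {
                "gene": gene,
                f"mutated_{ca}": a,
                f"total_{ca}": n_a,
                f"mutated_{cb}": c,
                f"total_{cb}": n_b,
                f"frequency_{ca}": a / n_a,
                f"frequency_{cb}": c / n_b,
                "odds_ratio": or_,
                "p_value": p,
                "tested": tested,
            }
        )
    df = pd.DataFrame(rows).set_index("gene")
    df["q_value"] = np.nan
    tested_mask = df["tested"].values
    df.loc[tested_mask, "q_value"] = bh_adjust(df.loc[tested_mask, "p_value"].values)
    df["significant"] = (df["q_value"] < fdr_threshold).fillna(False)
    freq_a = df[f"frequency_{ca}"]
    freq_b = df[f"frequency_{cb}"]
    df["enriched_cohort"] = np.where(freq_a > freq_b, ca, np.where(freq_b > freq_a, cb, ""))
    return df


def bootstrap_log_or(
    matrix: MutationMatrix,
    gene: str,
    n_resamples: int = 5000,
    seed: int | None = None,
) -> BootstrapStability:
    """Within-cohort bootstrap of a gene's log odds ratio.

    Haldane-Anscombe smoothing (+0.5 on all four cells) is applied to a
    resample only when it produces a zero cell, so estimates on
    well-populated tables are untouched.  The point estimate uses the same
    rule.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if gene not in matrix.indicator.index:
        raise ValueError(f"gene {gene!r} not in matrix")
    rng = np.random.default_rng(seed)
    cohorts = sorted(matrix.cohort_labels.unique())
    vecs = [matrix.cohort_columns(c).loc[gene].values.astype(np.int64) for c in cohorts]

    def smoothed_log_or(a: float, b: float, c: float, d: float) -> float:
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return math.log((a * d) / (b * c))

    n1, n2 = len(vecs[0]), len(vecs[1])
    a0, c0 = int(vecs[0].sum()), int(vecs[1].sum())
    point = smoothed_log_or(a0, n1 - a0, c0, n2 - c0)

    # column resampling within each cohort; for one gene this is equivalent
    # to resampling its 0/1 entries
    idx1 = rng.integers(0, n1, size=(n_resamples, n1))
    idx2 = rng.integers(0, n2, size=(n_resamples, n2))
    a = vecs[0][idx1].sum(axis=1).astype(float)
    c = vecs[1][idx2].sum(axis=1).astype(float)
    b = n1 - a
    d = n2 - c
    zero = (np.minimum.reduce([a, b, c, d]) == 0)
    a = np.where(zero, a + 0.5, a)
    b = np.where(zero, b + 0.5, b)
    c = np.where(zero, c + 0.5, c)
    d = np.where(zero, d + 0.5, d)
    lors = np.log((a * d) / (b * c))
    if point != 0:
        consistency = float(np.mean(np.sign(lors) == np.sign(point)))
    else:
        # a zero point estimate has no direction; report the fraction of
        # non-negative resamples, ~0.5 under a symmetric null
        consistency = float(np.mean(lors >= 0))
    return BootstrapStability(
        gene=gene,
        n_resamples=n_resamples,
        log_or=point,
        resample_mean=float(lors.mean()),
        resample_sd=float(lors.std(ddof=1)) if n_resamples > 1 else 0.0,
        directional_consistency=consistency,
    )


def build_oncotable(variants: Sequence[VariantRecord], matrix: MutationMatrix) -> pd.DataFrame:
    """Deterministic gene x sample table of mutation classification labels.

    Multiple hits in one gene/sample are joined by ';' in sorted order;
    unmutated cells are empty.  This is the tabular stand-in for an
    oncoplot.
    """
    cells: dict[tuple[str, str], list[str]] = {}
    for v in variants:
        if v.gene in matrix.indicator.index and v.sample_id in matrix.indicator.columns:
            cells.setdefault((v.gene, v.sample_id), []).append(v.classification)
    out = pd.DataFrame("", index=matrix.indicator.index, columns=matrix.indicator.columns, dtype=object)
    for (gene, sample), classes in cells.items():
        out.loc[gene, sample] = ";".join(sorted(classes))
    return out
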
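"""Hypergeometric over-representation analysis and the integrative matrix.

One engine serves any query gene set against any GMT collection within a
stated universe (GO BP vs KEGG is purely which GMT is supplied).  The
integrative view combines per-layer ORA results — one column per omic
layer (mutation, DEG up per cohort, CNV gain/loss per cohort) — into a
pathway x layer matrix of -log10(q), with empty cells where a layer's
query does not overlap the pathway at all, stars at q < 0.05, and rows
ranked by the number of significantly enriched layers (ties alphabetical).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Mapping

import math

import numpy as np
import pandas as pd

from .core_io import GeneSetCollection
from .stats import bh_adjust, hypergeom_upper_tail

__all__ = ["run_ora", "build_integrative_matrix", "IntegrativeMatrix"]

DEFAULT_LAYERS = (
    "Mutation_NA",
    "DEG_Up_NA",
    "DEG_Up_White",
    "CNV_Gain_NA",
    "CNV_Loss_NA",
    "CNV_Gain_White",
    "CNV_Loss_White",
)


def run_ora(
    query: Collection[str],
    collection: GeneSetCollection,
    universe: Collection[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail ORA of a query set against a collection.

    Query genes outside the universe are dropped with a warning count;
    each pathway is intersected with the universe, and only pathways with
    at least one universe gene enter the BH family.  Returns a DataFrame
    sorted by q then name.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    if not query:
        raise ValueError("query must be non-empty")
    dropped = query - universe
    query &= universe
    if not query:
        raise ValueError("no query genes remain inside the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for name, members in collection:
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        overlap = sorted(query & in_universe)
        k = len(overlap)
        p = hypergeom_upper_tail(N, K, n, k) if k > 0 else 1.0
        rows.append(
            {
                "pathway": name,
                "universe_size": N,
                "pathway_size": K,
                "query_size": n,
                "overlap": k,
                "overlap_genes": ";".join(overlap),
                "p_value": p,
                "dropped_query_genes": len(dropped),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q_value"] = bh_adjust(df["p_value"].values)
    df["significant"] = df["q_value"] < fdr_threshold
    return df.sort_values(["q_value", "pathway"], kind="mergesort").set_index("pathway")


@dataclass
class IntegrativeMatrix:
    """Pathway x layer matrix of -log10(q) with stars and the ranking rule."""

    scores: pd.DataFrame  # NaN = no overlap (empty cell)
    stars: pd.DataFrame  # bool, q < threshold
    n_significant_layers: pd.Series

    def to_table(self) -> pd.DataFrame:
        """Flat TSV-ready table: score columns plus star columns."""
        out = self.scores.copy()
        for layer in self.stars.columns:
            out[f"{layer}_significant"] = self.stars[layer]
        out["n_significant_layers"] = self.n_significant_layers
        return out


def build_integrative_matrix(
    layer_results: Mapping[str, pd.DataFrame],
    fdr_threshold: float = 0.05,
) -> IntegrativeMatrix:
    """Assemble per-layer ORA results into the ranked pathway x layer matrix.

    ``layer_results`` maps layer name -> :func:`run_ora` output.  Cells with
    zero overlap stay empty (NaN) rather than scoring 0; rows are ordered
    by descending count of significant layers, ties alphabetical by
    pathway.
    """
    names = list(layer_results)
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names")
    pathways = sorted({p for res in layer_results.values() for p in res.index})
    scores = pd.DataFrame(np.nan, index=pathways, columns=names)
    stars = pd.DataFrame(False, index=pathways, columns=names)
    for layer, res in layer_results.items():
        for pathway, row in res.iterrows():
            if row["overlap"] == 0:
                continue  # empty cell
            q = float(row["q_value"])
            scores.loc[pathway, layer] = -math.log10(q) if q > 0 else math.inf
            stars.loc[pathway, layer] = bool(row["q_value"] < fdr_threshold)
    n_sig = stars.sum(axis=1).astype(int)
    order = sorted(pathways, key=lambda p: (-n_sig[p], p))
    return IntegrativeMatrix(
        scores=scores.loc[order],
        stars=stars.loc[order],
        n_significant_layers=n_sig.loc[order],
    )
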
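"""Copy-number comparison between cohorts.

Segment-level calls are lifted to per-gene statuses by interval overlap
(half-open, >= 1 bp).  A gene overlapped in one sample by segments with
conflicting states becomes *invalid* and is excluded from that gene's
denominator; the default conflict mode invalidates only gain+loss
conflicts (an alteration co-occurring with neutral keeps the alteration),
while strict mode invalidates any two distinct states.  Genes with no
overlapping segment are *missing*.

Cohorts may enter at different granularity — one as segments, the other as
a pre-called gene-level table — and are normalized to the same gene x
sample status table before testing.  Per-gene event frequencies (gain,
loss, or the combined "change" = gain-or-loss) are compared with Fisher
exact tests over valid samples only, BH-adjusted at FDR 0.05.  Statuses
are also collapsed to chromosome arms (a sample's arm is flagged when at
least one panel gene on it carries the event; genes map to arms by
midpoint) for arm-level tests and per-sample burden comparison by
Wilcoxon rank-sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CnvSegment, GenomeAnnotation
from .stats import ContingencyTable2x2, bh_adjust, fisher_exact_two_sided, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCnvTable",
    "ArmCnvTable",
    "assign_gene_status",
    "from_gene_level",
    "combine_cohorts",
    "test_cnv_frequencies",
    "collapse_to_arms",
    "test_arm_frequencies",
    "compare_burden",
]

STATES = ("gain", "loss", "neutral", "invalid", "missing")
EVENTS = ("gain", "loss", "change")


@dataclass
class GeneCnvTable:
    """Per-gene CNV status (genes x samples) with cohort labels and provenance."""

    status: pd.DataFrame
    cohort_labels: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.status.values)) - set(STATES)
        if bad:
            raise ValueError(f"unknown CNV status label(s): {sorted(bad)}")
        self.cohort_labels = self.cohort_labels.loc[list(self.status.columns)]


@dataclass
class ArmCnvTable:
    """Per-sample arm-level gain/loss flags and burdens."""

    gain_flags: pd.DataFrame  # arms x samples, bool
    loss_flags: pd.DataFrame
    cohort_labels: pd.Series

    @property
    def burden(self) -> pd.DataFrame:
        """Per-sample counts of arms gained / lost."""
        return pd.DataFrame(
            {
                "n_arms_gained": self.gain_flags.sum(axis=0).astype(int),
                "n_arms_lost": self.loss_flags.sum(axis=0).astype(int),
                "cohort": self.cohort_labels,
            }
        )


def assign_gene_status(
    segments: Sequence[CnvSegment],
    annotation: GenomeAnnotation,
    samples: Sequence[str],
    cohort: str,
    conflict_mode: str = "gain_loss_only",
) -> GeneCnvTable:
    """Lift segment calls to per-gene statuses for one cohort.

    ``samples`` is the full roster: a rostered sample with no segments gets
    all-missing statuses rather than being dropped.
    """
    if conflict_mode not in ("gain_loss_only", "strict"):
        raise ValueError(f"unknown conflict_mode {conflict_mode!r}")
    by_sample_chrom: dict[tuple[str, str], list[CnvSegment]] = {}
    for seg in segments:
        if seg.sample_id not in set(samples):
            raise ValueError(f"segment sample {seg.sample_id!r} not on roster")
        by_sample_chrom.setdefault((seg.sample_id, seg.chromosome), []).append(seg)

    genes = annotation.genes.loc[list(annotation.panel)]
    status = pd.DataFrame("missing", index=genes.index, columns=list(samples), dtype=object)
    for sample in samples:
        for chrom, sub in genes.groupby("chromosome", sort=False):
            segs = by_sample_chrom.get((sample, chrom), [])
            if not segs:
                continue
            starts = np.array([s.start for s in segs])
            ends = np.array([s.end for s in segs])
            states = np.array([s.state for s in segs])
            for gene, g in sub.iterrows():
                overlap = (starts < g["end"]) & (ends > g["start"])
                if not overlap.any():
                    continue
                status.loc[gene, sample] = _resolve(set(states[overlap]), conflict_mode)
    labels = pd.Series(cohort, index=list(samples))
    return GeneCnvTable(status=status, cohort_labels=labels, provenance={cohort: f"segments/{conflict_mode}"})


def _resolve(states: set[str], conflict_mode: str) -> str:
    if len(states) == 1:
        return next(iter(states))
    if conflict_mode == "strict":
        return "invalid"
    if "gain" in states and "loss" in states:
        return "invalid"
    # alteration + neutral: the alteration wins
    return "gain" if "gain" in states else "loss"


def from_gene_level(
    status: pd.DataFrame,
    annotation: GenomeAnnotation,
    cohort: str,
    source: str = "gene_level",
) -> GeneCnvTable:
    """Wrap a pre-called gene-level status table, restricted to the panel.

    Panel genes absent from the table are filled as missing.
    """
    panel = list(annotation.panel)
    out = status.reindex(panel).fillna("missing")
    labels = pd.Series(cohort, index=list(out.columns))
    return GeneCnvTable(status=out, cohort_labels=labels, provenance={cohort: source})


def combine_cohorts(a: GeneCnvTable, b: GeneCnvTable) -> GeneCnvTable:
    """Join two single-cohort tables on their (identical) gene index."""
    if not a.status.index.equals(b.status.index):
        raise ValueError("cohort tables must share the same gene index")
    return GeneCnvTable(
        status=pd.concat([a.status, b.status], axis=1),
        cohort_labels=pd.concat([a.cohort_labels, b.cohort_labels]),
        provenance={**a.provenance, **b.provenance},
    )


def _event_mask(status: pd.DataFrame, event: str) -> pd.DataFrame:
    if event == "gain":
        return status == "gain"
    if event == "loss":
        return status == "loss"
    if event == "change":
        return (status == "gain") | (status == "loss")
    raise ValueError(f"unknown event {event!r}; expected one of {EVENTS}")


def test_cnv_frequencies(
    table: GeneCnvTable,
    event: str,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Fisher tests of event frequency among valid samples.

    Valid = status in {gain, loss, neutral}; invalid and missing samples are
    excluded from the denominator.  Genes lacking a valid sample in either
    cohort are skipped with a reason.  Infinite/zero odds ratios are kept
    exact in the table and flagged for presentation-time truncation.
    """
    cohorts = sorted(table.cohort_labels.unique())
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {cohorts}")
    ca, cb = cohorts
    cols_a = table.cohort_labels[table.cohort_labels == ca].index
    cols_b = table.cohort_labels[table.cohort_labels == cb].index
    valid = table.status.isin(["gain", "loss", "neutral"])
    ev = _event_mask(table.status, event)

    va = valid[cols_a].sum(axis=1).astype(int)
    vb = valid[cols_b].sum(axis=1).astype(int)
    ea = (ev[cols_a] & valid[cols_a]).sum(axis=1).astype(int)
    eb = (ev[cols_b] & valid[cols_b]).sum(axis=1).astype(int)

    from .mutation_diff import _FisherCache

    fisher = _FisherCache()
    rows = []
    for gene in table.status.index:
        a, n1, c, n2 = int(ea[gene]), int(va[gene]), int(eb[gene]), int(vb[gene])
        if n1 == 0 or n2 == 0:
            rows.append(
                {
                    "gene": gene, "event": event,
                    f"events_{ca}": a, f"valid_{ca}": n1,
                    f"events_{cb}": c, f"valid_{cb}": n2,
                    f"frequency_{ca}": math.nan, f"frequency_{cb}": math.nan,
                    "odds_ratio": math.nan, "p_value": math.nan,
                    "tested": False, "skip_reason": "no valid samples in one cohort",
                }
            )
            continue
        p, or_ = fisher(a, n1 - a, c, n2 - c)
        rows.append(
            {
                "gene": gene, "event": event,
                f"events_{ca}": a, f"valid_{ca}": n1,
                f"events_{cb}": c, f"valid_{cb}": n2,
                f"frequency_{ca}": a / n1, f"frequency_{cb}": c / n2,
                "odds_ratio": or_, "p_value": p,
                "tested": True, "skip_reason": "",
            }
        )
    df = pd.DataFrame(rows).set_index("gene")
    df["q_value"] = np.nan
    tested = df["tested"].values
    if tested.any():
        df.loc[tested, "q_value"] = bh_adjust(df.loc[tested, "p_value"].values)
    df["significant"] = (df["q_value"] < fdr_threshold).fillna(False)
    fa, fb = df[f"frequency_{ca}"], df[f"frequency_{cb}"]
    df["enriched_cohort"] = np.where(fa > fb, ca, np.where(fb > fa, cb, ""))
    with np.errstate(divide="ignore"):
        df["log2_odds_ratio"] = np.log2(df["odds_ratio"].astype(float))
    df["or_truncated"] = ~np.isfinite(df["log2_odds_ratio"])
    return df


def collapse_to_arms(table: GeneCnvTable, annotation: GenomeAnnotation) -> ArmCnvTable:
    """Aggregate gene statuses to chromosome-arm flags per sample.

    A sample's arm is flagged gained (lost) when at least one panel gene
    assigned to that arm — by gene midpoint — has status gain (loss).
    Genes whose midpoint falls outside every arm interval are left
    unassigned with a warning.
    """
    arm_of_gene: dict[str, str] = {}
    unassigned = 0
    genes = annotation.genes.loc[list(annotation.panel)]
    for gene, g in genes.iterrows():
        mid = (int(g["start"]) + int(g["end"])) // 2
        arm = annotation.arm_of(g["chromosome"], mid)
        if arm is None:
            unassigned += 1
            logger.warning("gene %s midpoint outside all arm intervals; unassigned", gene)
            continue
        arm_of_gene[gene] = arm
    if unassigned:
        logger.warning("collapse_to_arms: %d gene(s) unassigned to an arm", unassigned)

    arms = annotation.arm_labels
    samples = list(table.status.columns)
    gain = pd.DataFrame(False, index=arms, columns=samples)
    loss = pd.DataFrame(False, index=arms, columns=samples)
    arm_series = pd.Series(arm_of_gene)
    for arm in arms:
        members = arm_series.index[arm_series == arm]
        if len(members) == 0:
            continue
        sub = table.status.loc[members]
        gain.loc[arm] = (sub == "gain").any(axis=0)
        loss.loc[arm] = (sub == "loss").any(axis=0)
    return ArmCnvTable(gain_flags=gain, loss_flags=loss, cohort_labels=table.cohort_labels)


def test_arm_frequencies(armtable: ArmCnvTable, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-arm Fisher tests for gains and losses separately, BH within event."""
    cohorts = sorted(armtable.cohort_labels.unique())
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {cohorts}")
    ca, cb = cohorts
    cols_a = armtable.cohort_labels[armtable.cohort_labels == ca].index
    cols_b = armtable.cohort_labels[armtable.cohort_labels == cb].index
    frames = []
    for event, flags in (("gain", armtable.gain_flags), ("loss", armtable.loss_flags)):
        n1, n2 = len(cols_a), len(cols_b)
        rows = []
        for arm in flags.index:
            a = int(flags.loc[arm, cols_a].sum())
            c = int(flags.loc[arm, cols_b].sum())
            r = fisher_exact_two_sided(ContingencyTable2x2(a, n1 - a, c, n2 - c))
            rows.append(
                {
                    "arm": arm, "event": event,
                    f"events_{ca}": a, f"total_{ca}": n1,
                    f"events_{cb}": c, f"total_{cb}": n2,
                    f"frequency_{ca}": a / n1, f"frequency_{cb}": c / n2,
                    "odds_ratio": r.odds_ratio, "p_value": r.p_value,
                }
            )
        df = pd.DataFrame(rows)
        df["q_value"] = bh_adjust(df["p_value"].values)
        df["significant"] = df["q_value"] < fdr_threshold
        fa, fb = df[f"frequency_{ca}"], df[f"frequency_{cb}"]
        df["enriched_cohort"] = np.where(fa > fb, ca, np.where(fb > fa, cb, ""))
        frames.append(df)
    return pd.concat(frames, ignore_index=True).set_index(["event", "arm"])


def compare_burden(armtable: ArmCnvTable) -> pd.DataFrame:
    """Per-cohort mean arms gained/lost with two-sided Wilcoxon p-values."""
    burden = armtable.burden
    cohorts = sorted(armtable.cohort_labels.unique())
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {cohorts}")
    ca, cb = cohorts
    rows = []
    for event, col in (("gain", "n_arms_gained"), ("loss", "n_arms_lost")):
        x = burden.loc[burden["cohort"] == ca, col].values.astype(float)
        y = burden.loc[burden["cohort"] == cb, col].values.astype(float)
        r = wilcoxon_rank_sum(x, y, mode="normal")
        rows.append(
            {
                "event": event,
                f"mean_{ca}": float(x.mean()),
                f"mean_{cb}": float(y.mean()),
                "statistic": r.statistic,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("event")
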
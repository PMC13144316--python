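"""Somatic-variant filtering cascade.

Three sequential filters produce the analysis-ready call set:

1. population allele frequency — drop variants with popmax AF strictly
   greater than the threshold (default 0.0005); variants with no AF
   annotation are retained (absence of evidence of commonness) and counted;
2. protein-altering consequence — keep missense, nonsense, frameshift and
   in-frame indels, splice-site and translation-start changes; drop silent,
   UTR, intronic, flanking and other non-coding classes;
3. panel restriction — keep only genes on the targeted panel.

The filters commute on the retained set; the per-stage attrition counts in
the report depend on the order, which follows the cascade above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Sequence

from .core_io import PROTEIN_ALTERING, VariantRecord

__all__ = [
    "FilterReport",
    "filter_population_af",
    "filter_protein_altering",
    "filter_panel",
    "run_filter_cascade",
]

DEFAULT_AF_THRESHOLD = 0.0005


@dataclass
class FilterReport:
    """Per-stage attrition bookkeeping for one cohort's cascade run."""

    n_input: int = 0
    removed_population_af: int = 0
    removed_non_protein_altering: int = 0
    removed_off_panel: int = 0
    retained: int = 0
    missing_af_retained: int = 0

    def validate(self) -> None:
        total = (
            self.removed_population_af
            + self.removed_non_protein_altering
            + self.removed_off_panel
            + self.retained
        )
        if total != self.n_input:
            raise AssertionError(f"stage counts {total} != input count {self.n_input}")


def filter_population_af(
    variants: Sequence[VariantRecord], threshold: float = DEFAULT_AF_THRESHOLD
) -> list[VariantRecord]:
    """Drop likely-germline variants common in any reference subpopulation.

    Removal requires popmax AF *strictly greater* than the threshold, so a
    variant at exactly the threshold is retained.  Records with no AF
    annotation pass.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return [v for v in variants if v.popmax_af is None or v.popmax_af <= threshold]


def filter_protein_altering(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep only variants whose consequence alters the protein product."""
    return [v for v in variants if v.classification in PROTEIN_ALTERING]


def filter_panel(variants: Sequence[VariantRecord], panel: Collection[str]) -> list[VariantRecord]:
    """Keep only variants in genes on the targeted panel."""
    panel = set(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    return [v for v in variants if v.gene in panel]


def run_filter_cascade(
    variants: Sequence[VariantRecord],
    panel: Collection[str],
    af_threshold: float = DEFAULT_AF_THRESHOLD,
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply AF -> protein-altering -> panel filters and report attrition."""
    report = FilterReport(n_input=len(variants))
    report.missing_af_retained = sum(1 for v in variants if v.popmax_af is None)
    after_af = filter_population_af(variants, af_threshold)
    report.removed_population_af = len(variants) - len(after_af)
    after_pa = filter_protein_altering(after_af)
    report.removed_non_protein_altering = len(after_af) - len(after_pa)
    retained = filter_panel(after_pa, panel)
    report.removed_off_panel = len(after_pa) - len(retained)
    report.retained = len(retained)
    report.validate()
    return retained, report
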
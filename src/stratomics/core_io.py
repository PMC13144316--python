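"""Readers and writers for every external format the pipeline touches.

All genomic intervals are normalized to 0-based half-open coordinates at
ingestion (MAF positions, which are 1-based inclusive, are converted at the
boundary and converted back on write).  Chromosome names are normalized by
stripping a leading ``chr``; mitochondrial and non-standard contigs are
dropped with a logged count.

The variant-classification vocabulary is controlled; the mapping from MAF
``Variant_Classification`` strings to it ships as a packaged data table
(``data/variant_class_map.tsv``) so new MAF dialects are configuration, not
code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "RowError",
    "GenomeAnnotation",
    "VariantRecord",
    "CnvSegment",
    "ExpressionMatrix",
    "GeneSetCollection",
    "SBS96_CLASSES",
    "VALID_CLASSIFICATIONS",
    "PROTEIN_ALTERING",
    "read_maf",
    "write_maf",
    "read_seg",
    "write_seg",
    "read_cytoband_arms",
    "read_panel_bed",
    "write_panel_bed",
    "read_gmt",
    "write_gmt",
    "read_signature_reference",
    "write_signature_reference",
    "read_expression",
    "write_expression",
    "read_cohort_labels",
    "write_cohort_labels",
    "read_gene_cnv_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class RowError(FormatError):
    """A specific data row is malformed; message carries the line number."""


# ---------------------------------------------------------------------------
# controlled vocabularies

#: substitution classes in COSMIC SBS96 order
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: the 96 trinucleotide mutation classes, grouped by substitution then by
#: 5' and 3' flanking base alphabetically — the COSMIC column convention
SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in _SUBSTITUTIONS for five in _BASES for three in _BASES
)

VALID_CLASSIFICATIONS: frozenset[str] = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_ins",
        "frameshift_del",
        "inframe_ins",
        "inframe_del",
        "splice_site",
        "translation_start_site",
        "silent",
        "utr3",
        "utr5",
        "intron",
        "flank",
        "other",
    }
)

#: classifications retained by the protein-altering filter
PROTEIN_ALTERING: frozenset[str] = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_ins",
        "frameshift_del",
        "inframe_ins",
        "inframe_del",
        "splice_site",
        "translation_start_site",
    }
)

#: gnomAD-style population AF columns scanned by default ("any subpopulation")
DEFAULT_AF_COLUMNS: tuple[str, ...] = (
    "gnomAD_AF",
    "gnomAD_AFR_AF",
    "gnomAD_AMR_AF",
    "gnomAD_ASJ_AF",
    "gnomAD_EAS_AF",
    "gnomAD_FIN_AF",
    "gnomAD_NFE_AF",
    "gnomAD_OTH_AF",
    "gnomAD_SAS_AF",
)

_STANDARD_CHROMS = frozenset(str(i) for i in range(1, 23)) | {"X", "Y"}


def normalize_chromosome(chrom: str) -> str | None:
    """Strip a leading ``chr``; return None for MT/alt/random contigs."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in _STANDARD_CHROMS:
        return c
    return None


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call in a single tumor sample."""

    sample_id: str
    gene: str
    classification: str
    chromosome: str
    position: int  # 0-based position of the first reference base
    ref_allele: str
    alt_allele: str
    popmax_af: float | None = None
    trinucleotide_context: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position for {self.gene}")
        if self.classification not in VALID_CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.popmax_af is not None and not (0.0 <= self.popmax_af <= 1.0):
            raise ValueError(f"popmax_af outside [0,1]: {self.popmax_af}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _BASES
            and self.alt_allele in _BASES
            and self.ref_allele != self.alt_allele
        )


@dataclass(frozen=True)
class CnvSegment:
    """A copy-number segment call with a categorical state."""

    sample_id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    state: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if self.state not in ("gain", "loss", "neutral"):
            raise ValueError(f"state must be gain/loss/neutral, got {self.state!r}")


@dataclass
class ExpressionMatrix:
    """Normalized expression values (gene x sample) plus cohort labels."""

    values: pd.DataFrame
    cohort_labels: pd.Series

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        missing = set(self.values.columns) - set(self.cohort_labels.index)
        if missing:
            raise ValueError(f"samples without a cohort label: {sorted(missing)[:5]}")
        self.cohort_labels = self.cohort_labels.loc[list(self.values.columns)]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GenomeAnnotation:
    """Panel gene coordinates and chromosome-arm boundaries.

    ``genes``: DataFrame indexed by gene symbol with columns
    chromosome/start/end (0-based half-open).  ``arms``: DataFrame with
    columns chromosome/arm/start/end.  ``panel``: ordered gene symbols.
    """

    genes: pd.DataFrame
    arms: pd.DataFrame
    panel: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.genes.index.has_duplicates:
            raise ValueError("gene symbols must be unique")
        missing = [g for g in self.panel if g not in self.genes.index]
        if missing:
            raise ValueError(f"panel genes without coordinates: {missing[:5]}")

    def arm_of(self, chromosome: str, midpoint: int) -> str | None:
        """Arm label ('1p', '8q', ...) containing a position, else None."""
        sub = self.arms[self.arms["chromosome"] == chromosome]
        for _, row in sub.iterrows():
            if row["start"] <= midpoint < row["end"]:
                return f"{chromosome}{row['arm']}"
        return None

    @property
    def arm_labels(self) -> list[str]:
        return [f"{r.chromosome}{r.arm}" for r in self.arms.itertuples()]


# ---------------------------------------------------------------------------
# MAF

_MAF_REQUIRED = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)

CONTEXT_COLUMN = "Trinucleotide_Context"


def load_variant_class_map() -> dict[str, str]:
    """The packaged MAF classification -> controlled vocabulary table."""
    with resources.files("stratomics.data").joinpath("variant_class_map.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["maf_classification"], df["classification"]))


def _canonical_maf_names() -> dict[str, str]:
    """First MAF spelling listed for each vocabulary entry (used on write)."""
    out: dict[str, str] = {}
    for maf_name, vocab in load_variant_class_map().items():
        out.setdefault(vocab, maf_name)
    out.setdefault("other", "Targeted_Region")
    return out


def read_maf(
    path: str | Path,
    af_columns: Sequence[str] = DEFAULT_AF_COLUMNS,
    class_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Parse a MAF file into :class:`VariantRecord` objects.

    ``popmax_af`` is the maximum over the configured AF columns present in
    the file ("any subpopulation" semantics); absent if all are missing.
    Rows on mitochondrial or alt contigs are dropped with a logged count.
    """
    if class_map is None:
        class_map = load_variant_class_map()
    n_leading_comments = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_leading_comments += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"MAF {path} missing mandatory column(s): {', '.join(missing)}")
    present_af = [c for c in af_columns if c in df.columns]
    records: list[VariantRecord] = []
    dropped_contigs = 0
    for i, row in enumerate(df.itertuples(index=False), start=n_leading_comments + 2):
        row = row._asdict()
        chrom = normalize_chromosome(row["Chromosome"])
        if chrom is None:
            dropped_contigs += 1
            continue
        try:
            pos1 = int(row["Start_Position"])
        except ValueError:
            raise RowError(f"{path} line {i}: unparsable Start_Position {row['Start_Position']!r}")
        if pos1 < 1:
            raise RowError(f"{path} line {i}: Start_Position must be >= 1")
        afs = []
        for c in present_af:
            v = row[c]
            if v not in ("", ".", "NA", "nan"):
                afs.append(float(v))
        context = row.get(CONTEXT_COLUMN) or None
        records.append(
            VariantRecord(
                sample_id=row["Tumor_Sample_Barcode"],
                gene=row["Hugo_Symbol"],
                classification=class_map.get(row["Variant_Classification"], "other"),
                chromosome=chrom,
                position=pos1 - 1,
                ref_allele=row["Reference_Allele"],
                alt_allele=row["Tumor_Seq_Allele2"],
                popmax_af=max(afs) if afs else None,
                trinucleotide_context=context,
            )
        )
    if dropped_contigs:
        logger.info("read_maf(%s): dropped %d rows on non-standard contigs", path, dropped_contigs)
    return records


def write_maf(records: Iterable[VariantRecord], path: str | Path, af_column: str = "gnomAD_AF") -> None:
    """Write records as a minimal MAF (1-based positions restored)."""
    rev = _canonical_maf_names()
    rows = [
        {
            "Hugo_Symbol": r.gene,
            "Tumor_Sample_Barcode": r.sample_id,
            "Variant_Classification": rev[r.classification],
            "Chromosome": r.chromosome,
            "Start_Position": r.position + 1,
            "Reference_Allele": r.ref_allele,
            "Tumor_Seq_Allele2": r.alt_allele,
            af_column: "" if r.popmax_af is None else repr(r.popmax_af),
            CONTEXT_COLUMN: r.trinucleotide_context or "",
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(_MAF_REQUIRED) + [af_column, CONTEXT_COLUMN])
    df = df.sort_values(["Tumor_Sample_Barcode", "Chromosome", "Start_Position", "Hugo_Symbol"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG

_SEG_COLUMNS = ("sample", "chromosome", "start", "end", "state")


def read_seg(path: str | Path, one_based: bool = True) -> list[CnvSegment]:
    """Read segment-level CNV calls; coordinates normalized to 0-based half-open.

    ``one_based=True`` declares the file's intervals 1-based inclusive
    (the common SEG convention); ``False`` means already half-open.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SEG {path} missing column(s): {', '.join(missing)}")
    segments: list[CnvSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        chrom = normalize_chromosome(row.chromosome)
        if chrom is None:
            continue
        state = str(row.state)
        if state not in ("gain", "loss", "neutral"):
            raise RowError(f"{path} line {i}: state {state!r} not in (gain, loss, neutral)")
        start = int(row.start) - (1 if one_based else 0)
        end = int(row.end)
        if start >= end:
            raise RowError(f"{path} line {i}: empty interval after normalization [{start}, {end})")
        segments.append(CnvSegment(str(row.sample), chrom, start, end, state))
    return segments


def write_seg(segments: Iterable[CnvSegment], path: str | Path, one_based: bool = True) -> None:
    rows = [
        {
            "sample": s.sample_id,
            "chromosome": s.chromosome,
            "start": s.start + (1 if one_based else 0),
            "end": s.end,
            "state": s.state,
        }
        for s in segments
    ]
    df = pd.DataFrame(rows, columns=list(_SEG_COLUMNS))
    df = df.sort_values(["sample", "chromosome", "start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cytoband arms / panel BED


def read_cytoband_arms(path: str | Path) -> pd.DataFrame:
    """Collapse UCSC cytoBand rows into one p and one q interval per chromosome.

    Bands whose name starts with ``p`` (including acen/gvar stains) belong
    to the p arm, likewise for q.  A chromosome lacking one arm emits a
    warning and only the present arm.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "band", "stain"],
        dtype={"chromosome": str, "band": str},
    )
    rows = []
    for chrom_raw, sub in df.groupby("chromosome", sort=False):
        chrom = normalize_chromosome(chrom_raw)
        if chrom is None:
            continue
        for arm in ("p", "q"):
            bands = sub[sub["band"].str.startswith(arm)]
            if bands.empty:
                logger.warning("cytoband %s: chromosome %s has no %s bands; arm omitted", path, chrom, arm)
                continue
            rows.append(
                {"chromosome": chrom, "arm": arm, "start": int(bands["start"].min()), "end": int(bands["end"].max())}
            )
    out = pd.DataFrame(rows, columns=["chromosome", "arm", "start", "end"])
    return out.sort_values(["chromosome", "arm"], kind="mergesort", key=_chrom_sort_key).reset_index(drop=True)


def _chrom_sort_key(col: pd.Series) -> pd.Series:
    if col.name != "chromosome":
        return col
    order = {c: i for i, c in enumerate([str(i) for i in range(1, 23)] + ["X", "Y"])}
    return col.map(order)


def read_panel_bed(path: str | Path) -> pd.DataFrame:
    """Panel gene coordinates from BED (chrom, start, end, gene symbol)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chromosome", "start", "end", "gene"], dtype={"chromosome": str, "gene": str},
    )
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    df = df.dropna(subset=["chromosome"])
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].unique().tolist()
        raise FormatError(f"panel BED {path}: duplicate gene symbol(s) {dupes[:5]}")
    out = df.set_index("gene")[["chromosome", "start", "end"]]
    out[["start", "end"]] = out[["start", "end"]].astype(int)
    return out


def write_panel_bed(genes: pd.DataFrame, path: str | Path) -> None:
    df = genes.reset_index().rename(columns={"index": "gene"})
    df = df[["chromosome", "start", "end", "gene"]]
    df = df.sort_values(["chromosome", "start", "gene"], kind="mergesort", key=_chrom_sort_key)
    df.to_csv(path, sep="\t", header=False, index=False)


def build_annotation(panel_genes: pd.DataFrame, arms: pd.DataFrame) -> GenomeAnnotation:
    """Assemble a :class:`GenomeAnnotation` from BED genes and cytoband arms."""
    return GenomeAnnotation(genes=panel_genes, arms=arms, panel=tuple(panel_genes.index))


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RowError(f"{path} line {i}: GMT rows need name, description and >=1 member")
            name, desc, *members = parts
            if name in sets:
                raise FormatError(f"{path}: duplicate gene-set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise RowError(f"{path} line {i}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# signature reference spectra


def read_signature_reference(path: str | Path) -> pd.DataFrame:
    """Reference SBS spectra: 96 rows x S signature columns, columns renormalized to sum 1.

    Expects a ``Type`` column listing the 96 classes (any order); rows are
    reindexed to the COSMIC ordering.
    """
    df = pd.read_csv(path, sep="\t")
    if "Type" not in df.columns:
        raise FormatError(f"signature reference {path}: missing 'Type' column")
    df = df.set_index("Type")
    if sorted(df.index) != sorted(SBS96_CLASSES):
        raise FormatError(f"signature reference {path}: expected exactly the 96 SBS classes, got {len(df.index)} rows")
    df = df.reindex(list(SBS96_CLASSES)).astype(float)
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0].tolist()
        raise FormatError(f"signature reference {path}: non-positive column(s) {bad}")
    return df / sums


def write_signature_reference(spectra: pd.DataFrame, path: str | Path) -> None:
    out = spectra.reindex(list(SBS96_CLASSES))
    out.index.name = "Type"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample normalized expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"expression {path}: duplicated gene symbol(s) {dupes[:5]}")
    if (df.values < 0).any():
        raise FormatError(f"expression {path}: negative values present")
    return df.astype(float)


def write_expression(values: pd.DataFrame, path: str | Path) -> None:
    out = values.sort_index(kind="mergesort")
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_cohort_labels(path: str | Path) -> pd.Series:
    """Two-column TSV sample -> cohort label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "cohort"]:
        raise FormatError(f"labels {path}: expected columns 'sample' and 'cohort'")
    if df["sample"].duplicated().any():
        raise FormatError(f"labels {path}: duplicated sample ids")
    return df.set_index("sample")["cohort"]


def write_cohort_labels(labels: pd.Series, path: str | Path) -> None:
    df = labels.rename("cohort").rename_axis("sample").reset_index()
    df.sort_values("sample", kind="mergesort").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pre-called gene-level CNV


def read_gene_cnv_table(path: str | Path) -> pd.DataFrame:
    """Gene x sample table of pre-called CNV states.

    Accepted states: gain, loss, neutral, invalid, missing.  This is the
    ingestion path for cohorts delivered at gene level rather than as
    segments; the source's thresholding convention is the caller's
    provenance to record.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    allowed = {"gain", "loss", "neutral", "invalid", "missing"}
    bad = set(np.unique(df.values)) - allowed
    if bad:
        raise FormatError(f"gene CNV table {path}: unknown state(s) {sorted(bad)}")
    if df.index.has_duplicates:
        raise FormatError(f"gene CNV table {path}: duplicate gene rows")
    return df


def write_gene_cnv_table(status: pd.DataFrame, path: str | Path) -> None:
    out = status.sort_index(kind="mergesort")
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
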
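"""End-to-end orchestration of the stratified multi-omics comparison.

``run_all`` drives filter -> mutation -> CNV -> expression -> signatures ->
enrichment -> integrative matrix from a single config mapping (typically
parsed from YAML), writing a write-once result bundle with a provenance
manifest.  Any stage can be skipped; every analysis threshold is a config
default, never hard-coded in a stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import core_io, cnv_diff, enrichment, expression_diff, mutation_diff, mutsig, variant_filter

logger = logging.getLogger(__name__)

__all__ = ["default_run_config", "run_all"]

DEFAULT_THRESHOLDS = {
    "af": 0.0005,
    "mutation_fdr": 0.1,
    "cnv_fdr": 0.05,
    "deg_p": 0.01,
    "deg_lfc": 2.0,
    "deg_mean_floor": 10.0,
    "enrichment_fdr": 0.05,
    "exposure_alpha": 0.05,
}

DEFAULT_SIGNATURE_PARAMS = {
    "k_min": 1,
    "k_max": 10,
    "n_replicates": 20,
    "seed": 0,
    "stability_floor": 0.8,
}

ALL_STAGES = ("filter", "mutation", "cnv", "expression", "signatures", "enrichment")


def default_run_config(paths: Mapping[str, Any], out_dir: str | Path, seed: int = 0) -> dict:
    """A complete run config over the file paths of a (simulated) study."""
    return {
        "inputs": {k: str(v) for k, v in paths.items()},
        "cohort_names": {"a": "A", "b": "B"},
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "signatures": {**DEFAULT_SIGNATURE_PARAMS, "seed": seed},
        "bootstrap": {"n_resamples": 5000, "seed": seed},
        "stages": list(ALL_STAGES),
        "out_dir": str(out_dir),
    }


def _config_hash(config: Mapping, input_digests: Mapping[str, str]) -> str:
    # the bundle location is not part of the analysis identity
    config = {k: v for k, v in config.items() if k != "out_dir"}
    payload = json.dumps({"config": config, "inputs": input_digests}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.12g")


def run_all(config: Mapping) -> Path:
    """Run the configured stages; return the result-bundle directory."""
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    sig_params = {**DEFAULT_SIGNATURE_PARAMS, **config.get("signatures", {})}
    inputs = config["inputs"]
    ca = config.get("cohort_names", {}).get("a", "A")
    cb = config.get("cohort_names", {}).get("b", "B")

    needed = {
        "filter": ["maf_a", "maf_b", "panel_bed"],
        "mutation": ["maf_a", "maf_b", "panel_bed", "labels"],
        "cnv": ["seg_a", "gene_cnv_b", "panel_bed", "cytoband", "labels"],
        "expression": ["expression", "labels"],
        "signatures": ["maf_a", "maf_b", "panel_bed", "reference_spectra", "labels"],
        "enrichment": ["gmt"],
    }
    for stage in stages:
        missing = [k for k in needed.get(stage, []) if k not in inputs]
        if missing:
            raise ValueError(f"stage {stage!r} requested but input(s) missing: {missing}")

    manifest: dict[str, Any] = {
        "thresholds": thresholds,
        "signature_params": sig_params,
        "stages_run": stages,
        "stage_runtime_s": {},
        "warnings": {},
        "tables": [],
    }
    input_digests = {k: _digest(v) for k, v in inputs.items() if Path(str(v)).is_file()}
    manifest["input_digests"] = input_digests
    manifest["manifest_hash"] = _config_hash(dict(config), input_digests)

    def emit(df: pd.DataFrame, name: str) -> None:
        _write_tsv(df, out / name)
        manifest["tables"].append(name)

    panel_genes = core_io.read_panel_bed(inputs["panel_bed"]) if "panel_bed" in inputs else None
    labels = core_io.read_cohort_labels(inputs["labels"]) if "labels" in inputs else None

    filtered: dict[str, list[core_io.VariantRecord]] = {}
    deg_results = None
    deg_universe: list[str] = []
    mutation_tests = None
    cnv_results: dict[str, pd.DataFrame] = {}

    # ---------------- filter ----------------
    if "filter" in stages:
        t0 = time.perf_counter()
        reports = {}
        for key, cohort in (("maf_a", ca), ("maf_b", cb)):
            records = core_io.read_maf(inputs[key])
            kept, report = variant_filter.run_filter_cascade(
                records, panel_genes.index, af_threshold=thresholds["af"]
            )
            filtered[cohort] = kept
            reports[cohort] = report.__dict__
        (out / "filter_report.json").write_text(json.dumps(reports, indent=1, sort_keys=True))
        manifest["stage_runtime_s"]["filter"] = round(time.perf_counter() - t0, 3)

    # ---------------- mutation ----------------
    if "mutation" in stages:
        t0 = time.perf_counter()
        if not filtered:
            raise ValueError("mutation stage requires the filter stage")
        rosters = {
            ca: sorted(labels[labels == ca].index),
            cb: sorted(labels[labels == cb].index),
        }
        all_variants = filtered[ca] + filtered[cb]
        matrix = mutation_diff.build_mutation_matrix(all_variants, rosters, list(panel_genes.index))
        mutation_tests = mutation_diff.test_gene_frequencies(matrix, fdr_threshold=thresholds["mutation_fdr"])
        emit(mutation_tests, "mutation_tests.tsv")
        emit(mutation_diff.build_oncotable(all_variants, matrix), "oncotable.tsv")
        boot_cfg = config.get("bootstrap", {})
        boot_rows = []
        for gene in mutation_tests.index[mutation_tests["significant"]]:
            b = mutation_diff.bootstrap_log_or(
                matrix, gene,
                n_resamples=int(boot_cfg.get("n_resamples", 5000)),
                seed=int(boot_cfg.get("seed", 0)),
            )
            boot_rows.append(b.__dict__)
        boot = pd.DataFrame(
            boot_rows,
            columns=["gene", "n_resamples", "log_or", "resample_mean", "resample_sd", "directional_consistency"],
        ).set_index("gene")
        emit(boot, "mutation_bootstrap.tsv")
        manifest["stage_runtime_s"]["mutation"] = round(time.perf_counter() - t0, 3)

    # ---------------- cnv ----------------
    if "cnv" in stages:
        t0 = time.perf_counter()
        arms = core_io.read_cytoband_arms(inputs["cytoband"])
        annotation = core_io.build_annotation(panel_genes, arms)
        segments = core_io.read_seg(inputs["seg_a"])
        roster_a = sorted({s.sample_id for s in segments}) or sorted(labels[labels == ca].index)
        table_a = cnv_diff.assign_gene_status(segments, annotation, roster_a, ca)
        status_b = core_io.read_gene_cnv_table(inputs["gene_cnv_b"])
        table_b = cnv_diff.from_gene_level(status_b, annotation, cb)
        table = cnv_diff.combine_cohorts(table_a, table_b)
        for event in cnv_diff.EVENTS:
            res = cnv_diff.test_cnv_frequencies(table, event, fdr_threshold=thresholds["cnv_fdr"])
            cnv_results[event] = res
            emit(res, f"cnv_gene_tests_{event}.tsv")
        armtable = cnv_diff.collapse_to_arms(table, annotation)
        emit(cnv_diff.test_arm_frequencies(armtable, fdr_threshold=thresholds["cnv_fdr"]), "cnv_arm_tests.tsv")
        emit(cnv_diff.compare_burden(armtable), "cnv_burden.tsv")
        manifest["stage_runtime_s"]["cnv"] = round(time.perf_counter() - t0, 3)

    # ---------------- expression ----------------
    if "expression" in stages:
        t0 = time.perf_counter()
        values = core_io.read_expression(inputs["expression"])
        matrix = core_io.ExpressionMatrix(values=values, cohort_labels=labels)
        kept = expression_diff.filter_low_expression(matrix, threshold=thresholds["deg_mean_floor"])
        ranks = expression_diff.rank_transform(kept)
        deg_results = expression_diff.test_differential_expression(
            ranks, kept, p_threshold=thresholds["deg_p"], lfc_threshold=thresholds["deg_lfc"]
        )
        deg_universe = list(kept.values.index)
        emit(deg_results, "deg_tests.tsv")
        manifest["stage_runtime_s"]["expression"] = round(time.perf_counter() - t0, 3)

    # ---------------- signatures ----------------
    if "signatures" in stages:
        t0 = time.perf_counter()
        if not filtered:
            raise ValueError("signatures stage requires the filter stage")
        catalog, skipped = mutsig.build_catalog(filtered[ca] + filtered[cb])
        manifest["warnings"]["catalog_skipped"] = skipped
        emit(catalog, "catalog.tsv")
        model = mutsig.extract_signatures(
            catalog,
            k_min=int(sig_params["k_min"]),
            k_max=int(sig_params["k_max"]),
            n_replicates=int(sig_params["n_replicates"]),
            seed=int(sig_params["seed"]),
            stability_floor=float(sig_params["stability_floor"]),
        )
        emit(model.signatures, "signatures.tsv")
        emit(model.exposures, "exposures.tsv")
        emit(model.diagnostics, "signature_diagnostics.tsv")
        reference = core_io.read_signature_reference(inputs["reference_spectra"])
        core_io.write_signature_reference(reference, out / "reference_spectra_used.tsv")
        manifest["tables"].append("reference_spectra_used.tsv")
        decomp = mutsig.decompose_to_reference(model, reference)
        rows = []
        for d in decomp:
            row = {"signature": d.signature, "assigned_reference": d.assigned_reference,
                   "best_single_cosine": d.best_single_cosine}
            for ref_name, pct in d.contributions.items():
                row[f"pct_{ref_name}"] = pct
            rows.append(row)
        emit(pd.DataFrame(rows).set_index("signature"), "decomposition.tsv")
        emit(
            mutsig.compare_exposures(model, labels, alpha=thresholds["exposure_alpha"]),
            "exposure_tests.tsv",
        )
        manifest["stage_runtime_s"]["signatures"] = round(time.perf_counter() - t0, 3)

    # ---------------- enrichment ----------------
    if "enrichment" in stages:
        t0 = time.perf_counter()
        collection = core_io.read_gmt(inputs["gmt"])
        panel_universe = list(panel_genes.index) if panel_genes is not None else []
        layers: dict[str, tuple[set[str], list[str]]] = {}
        if mutation_tests is not None:
            sig = mutation_tests[mutation_tests["significant"]]
            layers[f"Mutation_{ca}"] = (
                set(sig.index[sig["enriched_cohort"] == ca]), panel_universe,
            )
        if deg_results is not None:
            degs = deg_results[deg_results["deg"]]
            layers[f"DEG_Up_{ca}"] = (set(degs.index[degs["direction"] == f"up_{ca}"]), deg_universe)
            layers[f"DEG_Up_{cb}"] = (set(degs.index[degs["direction"] == f"up_{cb}"]), deg_universe)
        for event in ("gain", "loss"):
            if event in cnv_results:
                res = cnv_results[event]
                sig = res[res["significant"]]
                for cohort in (ca, cb):
                    layers[f"CNV_{event.capitalize()}_{cohort}"] = (
                        set(sig.index[sig["enriched_cohort"] == cohort]), panel_universe,
                    )
        layer_results: dict[str, pd.DataFrame] = {}
        skipped_layers = []
        for name, (query, universe) in layers.items():
            if not query or not universe:
                skipped_layers.append(name)
                continue
            try:
                res = enrichment.run_ora(query, collection, universe, fdr_threshold=thresholds["enrichment_fdr"])
            except ValueError:
                skipped_layers.append(name)
                continue
            if res.empty:
                skipped_layers.append(name)
                continue
            layer_results[name] = res
            emit(res, f"ora_{name}.tsv")
        manifest["warnings"]["enrichment_layers_skipped"] = skipped_layers
        if layer_results:
            matrix = enrichment.build_integrative_matrix(layer_results, fdr_threshold=thresholds["enrichment_fdr"])
            emit(matrix.to_table(), "integrative_matrix.tsv")
            (out / "integrative_matrix.json").write_text(
                json.dumps(
                    {
                        "order": list(matrix.scores.index),
                        "n_significant_layers": matrix.n_significant_layers.to_dict(),
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
        manifest["stage_runtime_s"]["enrichment"] = round(time.perf_counter() - t0, 3)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
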
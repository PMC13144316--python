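"""CNV status assignment, conflict invalidation, arm collapse and burden."""

import numpy as np
import pandas as pd
import pytest

from stratomics.cnv_diff import (
    ArmCnvTable,
    GeneCnvTable,
    assign_gene_status,
    collapse_to_arms,
    combine_cohorts,
    compare_burden,
    from_gene_level,
    test_arm_frequencies as arm_frequency_tests,
    test_cnv_frequencies as cnv_frequency_tests,
)
from stratomics.core_io import CnvSegment, GenomeAnnotation


def annotation_1gene():
    genes = pd.DataFrame(
        {"chromosome": ["1"], "start": [100], "end": [200]}, index=pd.Index(["G1"], name="gene")
    )
    arms = pd.DataFrame(
        {"chromosome": ["1", "1"], "arm": ["p", "q"], "start": [0, 400], "end": [400, 1000]}
    )
    return GenomeAnnotation(genes=genes, arms=arms, panel=("G1",))


def seg(sample, start, end, state, chrom="1"):
    return CnvSegment(sample, chrom, start, end, state)


class TestAssignStatus:
    def test_gain_loss_conflict_is_invalid(self):
        t = assign_gene_status(
            [seg("S1", 50, 150, "gain"), seg("S1", 150, 300, "loss")],
            annotation_1gene(), ["S1"], "A",
        )
        assert t.status.loc["G1", "S1"] == "invalid"

    def test_neutral_plus_alteration_by_mode(self):
        segments = [seg("S1", 50, 150, "gain"), seg("S1", 150, 300, "neutral")]
        default = assign_gene_status(segments, annotation_1gene(), ["S1"], "A")
        strict = assign_gene_status(segments, annotation_1gene(), ["S1"], "A", conflict_mode="strict")
        assert default.status.loc["G1", "S1"] == "gain"
        assert strict.status.loc["G1", "S1"] == "invalid"

    def test_no_overlap_is_missing(self):
        t = assign_gene_status([seg("S1", 500, 600, "gain")], annotation_1gene(), ["S1"], "A")
        assert t.status.loc["G1", "S1"] == "missing"

    def test_touching_interval_does_not_overlap(self):
        # half-open: a segment ending exactly at the gene start shares no base
        t = assign_gene_status([seg("S1", 0, 100, "gain")], annotation_1gene(), ["S1"], "A")
        assert t.status.loc["G1", "S1"] == "missing"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            assign_gene_status([], annotation_1gene(), ["S1"], "A", conflict_mode="nope")


def two_cohort_table(status_rows, genes, n_a, n_b):
    cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    status = pd.DataFrame(status_rows, index=genes, columns=cols)
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols)
    return GeneCnvTable(status=status, cohort_labels=labels)


class TestFrequencies:
    def test_valid_denominator_excludes_invalid_and_missing(self):
        # 3 gains among 10 valid of 12 total in cohort A
        row = ["gain"] * 3 + ["neutral"] * 7 + ["invalid", "missing"] + ["neutral"] * 10
        t = two_cohort_table([row], ["G1"], 12, 10)
        res = cnv_frequency_tests(t, "gain")
        assert res.loc["G1", "valid_A"] == 10
        assert res.loc["G1", "frequency_A"] == pytest.approx(0.30)

    def test_infinite_odds_ratio_flagged(self):
        row = ["gain"] * 3 + ["neutral"] * 7 + ["neutral"] * 10
        t = two_cohort_table([row], ["G1"], 10, 10)
        res = cnv_frequency_tests(t, "gain")
        assert np.isinf(res.loc["G1", "odds_ratio"])
        assert bool(res.loc["G1", "or_truncated"])

    def test_change_includes_loss(self):
        row = ["loss"] + ["neutral"] * 9 + ["neutral"] * 10
        t = two_cohort_table([row], ["G1"], 10, 10)
        res = cnv_frequency_tests(t, "change")
        assert res.loc["G1", "events_A"] == 1

    def test_gene_without_valid_samples_skipped(self):
        row = ["missing"] * 5 + ["neutral"] * 5
        t = two_cohort_table([row], ["G1"], 5, 5)
        res = cnv_frequency_tests(t, "gain")
        assert not bool(res.loc["G1", "tested"])
        assert res.loc["G1", "skip_reason"] != ""

    def test_partition_identity(self):
        rng = np.random.default_rng(0)
        states = ["gain", "loss", "neutral", "invalid", "missing"]
        rows = rng.choice(states, size=(8, 12))
        t = two_cohort_table(rows, [f"G{i}" for i in range(8)], 6, 6)
        valid = t.status.isin(["gain", "loss", "neutral"])
        for g in t.status.index:
            row = t.status.loc[g]
            assert (
                (row == "gain").sum() + (row == "loss").sum() + (row == "neutral").sum()
                == valid.loc[g].sum()
            )
            assert valid.loc[g].sum() + (row == "invalid").sum() + (row == "missing").sum() == 12

    def test_unknown_event_rejected(self):
        t = two_cohort_table([["neutral", "neutral"]], ["G1"], 1, 1)
        with pytest.raises(ValueError):
            cnv_frequency_tests(t, "amplification")


def annotation_multi():
    genes = pd.DataFrame(
        {
            "chromosome": ["1", "1", "8", "8"],
            "start": [100, 500, 100, 500],
            "end": [200, 600, 200, 600],
        },
        index=pd.Index(["G1p", "G1q", "G8p", "G8q"], name="gene"),
    )
    arms = pd.DataFrame(
        {
            "chromosome": ["1", "1", "8", "8"],
            "arm": ["p", "q", "p", "q"],
            "start": [0, 400, 0, 400],
            "end": [400, 1000, 400, 1000],
        }
    )
    return GenomeAnnotation(genes=genes, arms=arms, panel=tuple(genes.index))


class TestArms:
    def test_gain_on_both_arms_counts_two(self):
        t = two_cohort_table(
            [["gain", "neutral"], ["gain", "neutral"], ["neutral"] * 2, ["neutral"] * 2],
            ["G1p", "G1q", "G8p", "G8q"], 1, 1,
        )
        arm = collapse_to_arms(t, annotation_multi())
        assert arm.burden.loc["A0", "n_arms_gained"] == 2

    def test_single_gene_flags_whole_arm(self):
        t = two_cohort_table(
            [["neutral"] * 2, ["neutral"] * 2, ["neutral"] * 2, ["gain", "neutral"]],
            ["G1p", "G1q", "G8p", "G8q"], 1, 1,
        )
        arm = collapse_to_arms(t, annotation_multi())
        assert bool(arm.gain_flags.loc["8q", "A0"])

    def test_all_neutral_zero_burden(self):
        t = two_cohort_table([["neutral"] * 2] * 4, ["G1p", "G1q", "G8p", "G8q"], 1, 1)
        arm = collapse_to_arms(t, annotation_multi())
        assert arm.burden[["n_arms_gained", "n_arms_lost"]].values.sum() == 0

    def test_burden_is_row_sum_of_flags(self):
        rng = np.random.default_rng(1)
        states = ["gain", "loss", "neutral"]
        rows = rng.choice(states, size=(4, 10))
        t = two_cohort_table(rows, ["G1p", "G1q", "G8p", "G8q"], 5, 5)
        arm = collapse_to_arms(t, annotation_multi())
        assert (arm.burden["n_arms_gained"].values == arm.gain_flags.sum(axis=0).values).all()
        assert (arm.burden["n_arms_lost"].values == arm.loss_flags.sum(axis=0).values).all()

    def test_identical_cohorts_have_unit_q(self):
        rows = [["gain", "gain", "gain", "gain"], ["neutral"] * 4, ["loss"] * 4, ["neutral"] * 4]
        t = two_cohort_table(rows, ["G1p", "G1q", "G8p", "G8q"], 2, 2)
        arm = collapse_to_arms(t, annotation_multi())
        res = arm_frequency_tests(arm)
        assert np.allclose(res["q_value"].values, 1.0)

    def test_complete_separation_arm_has_smallest_p(self):
        # 6+6 toy: arm 1p gained in every A sample and no B sample
        rng = np.random.default_rng(2)
        rows = np.array(
            [
                ["gain"] * 6 + ["neutral"] * 6,
                list(rng.choice(["gain", "neutral"], size=12)),
                ["neutral"] * 12,
                list(rng.choice(["gain", "neutral"], size=12)),
            ],
            dtype=object,
        )
        t = two_cohort_table(rows, ["G1p", "G1q", "G8p", "G8q"], 6, 6)
        arm = collapse_to_arms(t, annotation_multi())
        res = arm_frequency_tests(arm).reset_index()
        gains = res[res["event"] == "gain"].set_index("arm")
        assert gains["p_value"].idxmin() == "1p"


class TestBurdenAndIngestion:
    def test_burden_comparison_detects_planted_shift(self):
        rng = np.random.default_rng(3)
        arms = [f"{c}{a}" for c in range(1, 23) for a in "pq"]
        n_a, n_b = 17, 50
        cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
        gain = pd.DataFrame(
            np.concatenate(
                [rng.random((44, n_a)) < 20 / 44, rng.random((44, n_b)) < 6 / 44], axis=1
            ),
            index=arms, columns=cols,
        )
        loss = pd.DataFrame(False, index=arms, columns=cols)
        table = ArmCnvTable(
            gain_flags=gain, loss_flags=loss,
            cohort_labels=pd.Series(["A"] * n_a + ["B"] * n_b, index=cols),
        )
        res = compare_burden(table)
        assert res.loc["gain", "p_value"] < 0.01
        assert res.loc["gain", "mean_A"] > res.loc["gain", "mean_B"]

    def test_gene_level_ingestion_fills_missing_panel_genes(self):
        status = pd.DataFrame({"B0": ["gain"]}, index=["G1p"])
        t = from_gene_level(status, annotation_multi(), "B")
        assert t.status.loc["G8q", "B0"] == "missing"
        assert t.provenance["B"] == "gene_level"

    def test_combine_requires_same_genes(self):
        a = two_cohort_table([["gain"]], ["G1p"], 1, 0)
        a = GeneCnvTable(
            status=pd.DataFrame({"A0": ["gain"]}, index=["G1p"]),
            cohort_labels=pd.Series({"A0": "A"}),
        )
        b = GeneCnvTable(
            status=pd.DataFrame({"B0": ["gain"]}, index=["OTHER"]),
            cohort_labels=pd.Series({"B0": "B"}),
        )
        with pytest.raises(ValueError):
            combine_cohorts(a, b)
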
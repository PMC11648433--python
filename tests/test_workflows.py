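"""Workflow enumeration/execution, Welch testing, detection curves,
consensus, PCA and reference diffing."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from mirworkbench import (
    BackgroundMethod,
    BackgroundSpec,
    DEResult,
    LaneFactors,
    NormalizerSet,
    Stringency,
    ValidationError,
    WorkflowConfig,
    WorkflowOptions,
    apply_factors,
    apply_subtraction,
    apply_threshold,
    compare_to_reference,
    consensus_table,
    detection_curve,
    enumerate_workflows,
    pca_summary,
    run_workflow,
    welch_test,
)

from conftest import build_matrix


class TestEnumerateWorkflows:
    def test_fourteen_unique_configurations(self):
        configs = enumerate_workflows()
        assert len(configs) == 14
        combos = {
            (c.background.method, c.background.stringency, c.normalization)
            for c in configs
        }
        assert len(combos) == 14

    def test_published_grid_layout(self):
        configs = {c.id: c for c in enumerate_workflows()}
        # columns 1-2: no background, NF then TR
        assert configs[1].background.method is BackgroundMethod.NONE
        assert configs[1].normalization == "normfinder"
        assert configs[2].background.method is BackgroundMethod.NONE
        assert configs[2].normalization == "total_rna"
        # columns 3-8: subtraction at 2SD/1SD/mean for NF then TR
        expected = [
            (3, Stringency.MEAN_PLUS_2SD, "normfinder"),
            (4, Stringency.MEAN_PLUS_1SD, "normfinder"),
            (5, Stringency.MEAN, "normfinder"),
            (6, Stringency.MEAN_PLUS_2SD, "total_rna"),
            (7, Stringency.MEAN_PLUS_1SD, "total_rna"),
            (8, Stringency.MEAN, "total_rna"),
        ]
        for wid, stringency, norm in expected:
            assert configs[wid].background.method is BackgroundMethod.SUBTRACT
            assert configs[wid].background.stringency is stringency
            assert configs[wid].normalization == norm
        # columns 9-14: thresholding mirrors the subtraction block
        for wid in range(9, 15):
            assert configs[wid].background.method is BackgroundMethod.THRESHOLD
            twin = configs[wid - 6]
            assert configs[wid].background.stringency is twin.background.stringency
            assert configs[wid].normalization == twin.normalization


class TestWelchTest:
    def test_identical_groups_null(self):
        res = welch_test([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.statistic == 0.0 and res.p_two_sided == 1.0

    def test_textbook_example(self):
        res = welch_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert abs(res.statistic) == pytest.approx(3.674, abs=1e-3)
        assert res.p_two_sided == pytest.approx(0.0214, abs=5e-4)
        assert res.df == pytest.approx(4.0)
        assert res.p_one_sided == pytest.approx(res.p_two_sided / 2)

    def test_swapping_groups_negates_t(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 6.0, 9.0]
        fwd, rev = welch_test(a, b), welch_test(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_two_sided == pytest.approx(rev.p_two_sided)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 2, 8)
        ours = welch_test(a, b)
        ref = sps.ttest_ind(b, a, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-12)


def _null_matrix():
    """All lanes identical: every factor is 1 and every test is null."""
    return build_matrix(
        {
            "mir-a": [10, 10, 10, 10],
            "mir-b": [500, 500, 500, 500],
            "mir-c": [50, 50, 50, 50],
            "POS_A": [1280, 1280, 1280, 1280],
            "POS_B": [320, 320, 320, 320],
            "POS_C": [80, 80, 80, 80],
            "NEG_A": [2, 2, 2, 2],
            "NEG_B": [4, 4, 4, 4],
        },
        {
            "mir-a": "endogenous",
            "mir-b": "endogenous",
            "mir-c": "endogenous",
            "POS_A": "positive",
            "POS_B": "positive",
            "POS_C": "positive",
            "NEG_A": "negative",
            "NEG_B": "negative",
        },
        groups=["A", "A", "B", "B"],
        concentrations={"POS_A": 128.0, "POS_B": 32.0, "POS_C": 8.0},
    )


NULL_SETS = {
    "normfinder": NormalizerSet(["mir-a", "mir-b", "mir-c"], "normfinder"),
    "total_rna": NormalizerSet(["mir-a", "mir-b", "mir-c"], "total_rna"),
}


class TestRunWorkflow:
    def test_null_pipeline_is_identity_with_unit_factors(self):
        m = _null_matrix()
        config = enumerate_workflows()[0]  # none + normfinder
        processed, de = run_workflow(m, config, NULL_SETS)
        assert np.allclose(processed.values.astype(float), m.values.astype(float))
        assert (de.table["p"] == 1.0).all()
        assert not de.table["significant"].any()

    def test_no_background_equals_two_step_normalisation(self, simulated_pipeline):
        from mirworkbench import content_factors, positive_control_factors

        raw = simulated_pipeline["matrix"]
        sets = simulated_pipeline["sets"]
        processed = simulated_pipeline["processed"][1]
        pos = positive_control_factors(raw)
        step1 = apply_factors(raw, pos)
        step2 = apply_factors(step1, content_factors(step1, sets["normfinder"]))
        assert np.allclose(
            processed.values.astype(float), step2.values.astype(float)
        )

    def test_operation_order_differs_between_subtypes(self):
        # hand trace: raw 3, lane factor 2, background 4
        # normalise-then-threshold: max(3*2, 4) = 6
        # threshold-then-normalise: max(3, 4)*2 = 8
        m = build_matrix({"p": [3]}, {"p": "endogenous"})
        factors = LaneFactors(pd.Series({"L1": 2.0}), "positive_control")
        bg = pd.Series({"L1": 4.0})
        norm_then_bg = apply_threshold(apply_factors(m, factors), bg)
        bg_then_norm = apply_factors(apply_threshold(m, bg), factors)
        assert norm_then_bg.values.at["L1", "p"] == 6.0
        assert bg_then_norm.values.at["L1", "p"] == 8.0

    def test_threshold_workflow_is_none_workflow_floored(self, simulated_pipeline):
        # the thresholding chain before the floor is exactly the no-background
        # chain, so workflow 9 == workflow 1 clipped at the normalised-scale
        # background (mean + 2 SD of the carried-through negatives)
        from mirworkbench import lane_background

        none_nf = simulated_pipeline["processed"][1]
        thresh_nf = simulated_pipeline["processed"][9]
        bg = lane_background(none_nf, "mean_plus_2sd")
        expected = none_nf.values.astype(float).clip(lower=bg, axis=0)
        assert np.allclose(thresh_nf.values.astype(float), expected)

    def test_missing_normalizer_set_rejected(self):
        m = _null_matrix()
        config = enumerate_workflows()[0]
        with pytest.raises(ValidationError):
            run_workflow(m, config, {"total_rna": NULL_SETS["total_rna"]})

    def test_planted_changes_significant_in_most_workflows(self, simulated_pipeline):
        truth = simulated_pipeline["truth"]
        freq = simulated_pipeline["consensus"].frequency
        assert (freq[list(truth.de_probes)] >= 10).all()

    def test_direction_matches_planted_fold(self, simulated_pipeline):
        truth = simulated_pipeline["truth"]
        directions = simulated_pipeline["consensus"].direction
        for probe in truth.de_probes:
            assert directions[probe] == truth.de_direction(probe)


class TestDetectionCurve:
    def test_all_detected_gives_flat_curve(self):
        m = build_matrix(
            {"a": [5, 5], "b": [9, 9], "NEG": [0, 0]},
            {"a": "endogenous", "b": "endogenous", "NEG": "negative"},
        )
        curve = detection_curve(m, threshold=2.0)
        assert curve.counts.tolist() == [2, 2]
        assert curve.never_detected == 0

    def test_curve_counts_by_lane_support(self):
        m = build_matrix(
            {"a": [5, 5, 5], "b": [5, 5, 0], "c": [0, 5, 0], "d": [0, 0, 0]},
            {p: "endogenous" for p in "abcd"},
        )
        curve = detection_curve(m, threshold=2.0)
        assert curve.counts.tolist() == [3, 2, 1]
        assert curve.never_detected == 1

    def test_non_increasing(self, default_simulation):
        matrix, _ = default_simulation
        curve = detection_curve(matrix)
        assert (curve.counts.diff().dropna() <= 0).all()


class TestConsensusTable:
    def _de(self, wf, sig_probes, directions):
        probes = ["p1", "p2", "p3"]
        table = pd.DataFrame(
            {
                "significant": [p in sig_probes for p in probes],
                "direction": [directions.get(p, "none") for p in probes],
            },
            index=probes,
        )
        return DEResult(workflow_id=wf, table=table, alpha=0.05)

    def test_single_workflow_frequencies(self):
        with pytest.warns(UserWarning, match="expected 14"):
            cons = consensus_table({1: self._de(1, {"p1"}, {"p1": "up_in_b"})})
        assert cons.frequency.max() == 1
        assert cons.direction["p1"] == "up_in_b"
        assert cons.direction["p2"] == "none"

    def test_disagreeing_directions_flagged_inconsistent(self):
        with pytest.warns(UserWarning):
            cons = consensus_table(
                {
                    1: self._de(1, {"p1"}, {"p1": "up_in_b"}),
                    2: self._de(2, {"p1"}, {"p1": "up_in_a"}),
                }
            )
        assert cons.direction["p1"] == "inconsistent"
        assert cons.frequency["p1"] == 2

    def test_ranking_sorted_by_frequency_then_id(self):
        with pytest.warns(UserWarning):
            cons = consensus_table(
                {
                    1: self._de(1, {"p2", "p3"}, {"p2": "up_in_b", "p3": "up_in_b"}),
                    2: self._de(2, {"p3"}, {"p3": "up_in_b"}),
                }
            )
        assert list(cons.ranked().index) == ["p3", "p2", "p1"]
        assert cons.candidates() == ["p3"]  # min_frequency defaults to 2


class TestPcaSummary:
    def test_constant_matrix_rejected(self):
        m = build_matrix(
            {"a": [5, 5, 5], "b": [7, 7, 7]}, {"a": "endogenous", "b": "endogenous"}
        )
        with pytest.raises(ValidationError, match="variance"):
            pca_summary(m)

    def test_group_dispersion_orders_planted_variance(self):
        # group B gets visibly noisier lanes than group A
        rng = np.random.default_rng(0)
        n_probes = 40
        base = rng.uniform(50, 500, n_probes)
        rows = []
        for i in range(6):
            rows.append(base * 2 ** rng.normal(0, 0.05, n_probes))
        for i in range(6):
            rows.append(base * 2 ** rng.normal(0, 0.6, n_probes))
        counts = {
            f"p{j}": [int(rows[i][j]) for i in range(12)] for j in range(n_probes)
        }
        m = build_matrix(
            counts,
            {f"p{j}": "endogenous" for j in range(n_probes)},
            groups=["A"] * 6 + ["B"] * 6,
        )
        summary = pca_summary(m)
        assert summary.group_dispersion["B"] > summary.group_dispersion["A"]

    def test_scores_invariant_to_lane_order_up_to_sign(self, default_simulation):
        matrix, _ = default_simulation
        a = pca_summary(matrix).scores
        order = matrix.lane_ids[::-1]
        reordered = matrix.subset_by_probes(matrix.probe_ids)
        reordered = type(matrix)(
            lanes=[matrix.lane(ln) for ln in order],
            probes=list(matrix.probes),
            values=matrix.values.loc[order],
            stage=matrix.stage,
        )
        b = pca_summary(reordered).scores.loc[a.index]
        for pc in ["PC1", "PC2"]:
            assert np.allclose(a[pc], b[pc], atol=1e-8) or np.allclose(
                a[pc], -b[pc], atol=1e-8
            )


class TestCompareToReference:
    def test_identity_yields_empty_diff(self, small_matrix):
        assert compare_to_reference(small_matrix, small_matrix).empty

    def test_single_perturbed_cell_reported(self, small_matrix):
        other = small_matrix.copy()
        other.values.at["L2", "mir-a"] += 1.0
        report = compare_to_reference(small_matrix, other, abs_tolerance=0.5)
        assert len(report) == 1
        row = report.iloc[0]
        assert (row["lane"], row["probe"]) == ("L2", "mir-a")
        assert row["difference"] == pytest.approx(-1.0)

    def test_infinite_tolerance_accepts_anything(self, small_matrix):
        other = small_matrix.copy()
        other.values.at["L1", "mir-b"] += 1e6
        assert compare_to_reference(
            small_matrix, other, abs_tolerance=np.inf
        ).empty

    def test_unalignable_ids_rejected(self, small_matrix):
        sub = small_matrix.subset_by_probes(small_matrix.probe_ids[:-1])
        with pytest.raises(ValidationError, match="unalignable"):
            compare_to_reference(small_matrix, sub)
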
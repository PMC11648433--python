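"""Background estimation/correction, normalisation factors and normaliser
selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mirworkbench import (
    EmptySelectionError,
    NormalizerSet,
    Stage,
    Stringency,
    ValidationError,
    apply_factors,
    apply_subtraction,
    apply_threshold,
    content_factors,
    lane_background,
    positive_control_factors,
    select_normfinder_normalizers,
    select_total_rna_normalizers,
)

from conftest import build_matrix


def matrix_with_negatives(neg_counts_per_lane, extra=None):
    """Lanes share identical endogenous counts; negatives vary per request."""
    counts = {"mir-a": [10] * len(neg_counts_per_lane[0])}
    classes = {"mir-a": "endogenous"}
    for i in range(len(neg_counts_per_lane)):
        counts[f"NEG_{i}"] = neg_counts_per_lane[i]
        classes[f"NEG_{i}"] = "negative"
    if extra:
        for pid, (cls, vals) in extra.items():
            counts[pid], classes[pid] = vals, cls
    return build_matrix(counts, classes)


class TestLaneBackground:
    def test_zero_sd_gives_mean_at_every_stringency(self):
        m = matrix_with_negatives([[2], [2], [2]])
        for stringency in Stringency:
            assert lane_background(m, stringency)["L1"] == pytest.approx(2.0)

    def test_stringency_arithmetic_with_sample_sd(self):
        # negatives {0,2,4}: mean 2, sample SD 2 -> 2 / 4 / 6
        m = matrix_with_negatives([[0], [2], [4]])
        assert lane_background(m, "mean")["L1"] == pytest.approx(2.0)
        assert lane_background(m, "mean_plus_1sd")["L1"] == pytest.approx(4.0)
        assert lane_background(m, "mean_plus_2sd")["L1"] == pytest.approx(6.0)

    def test_population_sd_toggle(self):
        m = matrix_with_negatives([[0], [2], [4]])
        sd_pop = np.std([0, 2, 4])  # ~1.633
        assert lane_background(m, "mean_plus_1sd", sd_ddof=0)["L1"] == pytest.approx(
            2.0 + sd_pop
        )

    def test_single_lane_matrix(self):
        m = matrix_with_negatives([[1], [3]])
        bg = lane_background(m, "mean")
        assert len(bg) == 1 and bg["L1"] == pytest.approx(2.0)

    def test_requires_negative_probes(self, small_matrix):
        endo_only = small_matrix.subset_by_class("endogenous")
        with pytest.raises((ValidationError, EmptySelectionError)):
            lane_background(endo_only, "mean")


class TestBackgroundCorrection:
    @pytest.fixture
    def trio(self):
        return build_matrix(
            {"p1": [0], "p2": [5], "p3": [10]},
            {"p1": "endogenous", "p2": "endogenous", "p3": "endogenous"},
        )

    def test_threshold_raises_low_counts(self, trio):
        out = apply_threshold(trio, pd.Series({"L1": 4.0}))
        assert out.values.loc["L1"].tolist() == [4.0, 5.0, 10.0]
        assert out.stage is Stage.BACKGROUND_CORRECTED

    def test_subtraction_floors_at_zero(self, trio):
        out = apply_subtraction(trio, pd.Series({"L1": 4.0}))
        assert out.values.loc["L1"].tolist() == [0.0, 1.0, 6.0]

    def test_zero_background_is_identity(self, trio):
        bg = pd.Series({"L1": 0.0})
        assert (apply_threshold(trio, bg).values == trio.values).all().all()
        assert (apply_subtraction(trio, bg).values == trio.values).all().all()

    def test_threshold_saturates_when_all_below(self, trio):
        out = apply_threshold(trio, pd.Series({"L1": 50.0}))
        assert (out.values.loc["L1"] == 50.0).all()

    def test_threshold_idempotent_and_bounded(self, trio):
        bg = pd.Series({"L1": 4.0})
        once = apply_threshold(trio, bg)
        twice = apply_threshold(once, bg)
        assert once.equals(twice)
        assert (once.values.loc["L1"] >= 4.0).all()

    def test_subtraction_inflates_low_expression_ratios(self):
        # the false-positive mechanism: (10,5) ratio 2 becomes (6,1) ratio 6
        m = build_matrix({"p": [10, 5]}, {"p": "endogenous"})
        out = apply_subtraction(m, pd.Series({"L1": 4.0, "L2": 4.0}))
        before = 10 / 5
        after = out.values.at["L1", "p"] / out.values.at["L2", "p"]
        assert after == pytest.approx(6.0)
        assert after > before

    def test_configurable_floor(self, trio):
        out = apply_subtraction(trio, pd.Series({"L1": 4.0}), floor=1.0)
        assert out.values.loc["L1"].tolist() == [1.0, 1.0, 6.0]


class TestFactorNormalisation:
    def test_identical_lanes_give_unit_factors(self, small_matrix):
        factors = positive_control_factors(small_matrix)
        assert np.allclose(factors.factors, 1.0)

    def test_two_lane_ratio_example(self):
        # geometric means g and 2g -> mean of summaries 1.5g -> factors 1.5, 0.75
        m = build_matrix(
            {"P1": [10, 20], "P2": [40, 80], "NEG": [0, 0]},
            {"P1": "positive", "P2": "positive", "NEG": "negative"},
            concentrations={"P1": 128, "P2": 32},
        )
        factors = positive_control_factors(m)
        assert factors.factors["L1"] == pytest.approx(1.5)
        assert factors.factors["L2"] == pytest.approx(0.75)

    def test_equalises_lane_summaries_exactly(self, default_simulation):
        matrix, _ = default_simulation
        factors = positive_control_factors(matrix)
        normed = apply_factors(matrix, factors)
        pos = normed.subset_by_class("positive").values
        gm = np.exp(np.log(pos).mean(axis=1))
        assert gm.max() - gm.min() <= 1e-9 * gm.mean()

    def test_arithmetic_averaging_equalises_means(self, default_simulation):
        matrix, _ = default_simulation
        factors = positive_control_factors(matrix, averaging="arithmetic")
        normed = apply_factors(matrix, factors)
        means = normed.subset_by_class("positive").values.mean(axis=1)
        assert means.max() - means.min() <= 1e-9 * means.mean()

    def test_zero_positive_counts_warn(self):
        m = build_matrix(
            {"P1": [0, 10], "P2": [40, 80]},
            {"P1": "positive", "P2": "positive"},
            concentrations={"P1": 128, "P2": 32},
        )
        with pytest.warns(UserWarning, match="0.5"):
            positive_control_factors(m)

    def test_content_factors_same_formula_different_probes(self, small_matrix):
        normalizers = NormalizerSet(["mir-a", "mir-b"], "total_rna")
        factors = content_factors(small_matrix, normalizers)
        sub = small_matrix.values[["mir-a", "mir-b"]].astype(float)
        gm = np.exp(np.log(sub).mean(axis=1))
        expected = gm.mean() / gm
        assert np.allclose(factors.factors, expected)
        assert factors.source == "content_total_rna"

    def test_doubling_one_lane_halves_its_factor(self):
        m = build_matrix(
            {"mir-a": [10, 20], "mir-b": [40, 80]},
            {"mir-a": "endogenous", "mir-b": "endogenous"},
        )
        factors = content_factors(m, NormalizerSet(["mir-a", "mir-b"], "total_rna"))
        assert factors.factors["L2"] == pytest.approx(factors.factors["L1"] / 2)

    def test_apply_factors_scales_every_cell(self, small_matrix):
        from mirworkbench import LaneFactors

        factors = LaneFactors(
            pd.Series({"L1": 2.0, "L2": 1.0, "L3": 1.0}), "positive_control"
        )
        out = apply_factors(small_matrix, factors)
        assert (out.values.loc["L1"] == small_matrix.values.loc["L1"] * 2).all()
        assert (out.values.loc["L2"] == small_matrix.values.loc["L2"]).all()


class TestTotalRnaSelection:
    def _matrix(self):
        # backgrounds (mean+1sd): negatives {0,2,4} in every lane -> 4
        return build_matrix(
            {
                "hi": [50, 60, 70],       # above background everywhere
                "edge": [50, 60, 4],      # at background in lane 3 -> excluded
                "low": [1, 2, 1],         # below everywhere
                "NEG_A": [0, 0, 0],
                "NEG_B": [2, 2, 2],
                "NEG_C": [4, 4, 4],
                "POS_A": [100, 100, 100],
            },
            {
                "hi": "endogenous",
                "edge": "endogenous",
                "low": "endogenous",
                "NEG_A": "negative",
                "NEG_B": "negative",
                "NEG_C": "negative",
                "POS_A": "positive",
            },
            concentrations={"POS_A": 128},
        )

    def test_selection_rule(self):
        pool = select_total_rna_normalizers(self._matrix())
        assert pool.probe_ids == ["hi"]
        assert pool.method == "total_rna"

    def test_min_mean_count_filter(self):
        m = self._matrix()
        assert select_total_rna_normalizers(m, min_mean_count=50).probe_ids == ["hi"]
        with pytest.raises(EmptySelectionError):
            select_total_rna_normalizers(m, min_mean_count=1000)

    def test_invariant_to_positive_control_counts(self):
        m = self._matrix()
        boosted = m.copy()
        boosted.values["POS_A"] = [9, 9, 9]
        assert (
            select_total_rna_normalizers(m).probe_ids
            == select_total_rna_normalizers(boosted).probe_ids
        )

    def test_requires_raw_stage(self):
        m = self._matrix().with_values(
            self._matrix().values * 1.0, Stage.POSITIVE_NORMALISED
        )
        with pytest.raises(ValidationError):
            select_total_rna_normalizers(m)


class TestNormfinderSelection:
    def test_n_select_equal_to_pool_reorders_only(self, default_simulation):
        matrix, _ = default_simulation
        pool = select_total_rna_normalizers(matrix)
        chosen = select_normfinder_normalizers(
            pool, matrix, n_select=len(pool.probe_ids)
        )
        assert sorted(chosen.probe_ids) == sorted(pool.probe_ids)
        stabs = chosen.stability_values[chosen.probe_ids]
        assert (stabs.diff().dropna() >= 0).all()  # ordered most-stable first

    def test_n_select_larger_than_pool_rejected(self, default_simulation):
        matrix, _ = default_simulation
        pool = select_total_rna_normalizers(matrix)
        with pytest.raises(ValidationError):
            select_normfinder_normalizers(pool, matrix, n_select=len(pool.probe_ids) + 1)

    def test_planted_stable_cohort_selected(self, default_simulation):
        matrix, truth = default_simulation
        pool = select_total_rna_normalizers(matrix)
        chosen = select_normfinder_normalizers(pool, matrix, n_select=5)
        assert set(chosen.probe_ids) <= set(truth.stable_probe_ids)

    def test_cv_ranking_cross_check(self, default_simulation):
        # coefficient-of-variation ranking is a rougher instrument but should
        # also pull its picks from the planted stable cohort
        matrix, truth = default_simulation
        pool = select_total_rna_normalizers(matrix)
        chosen = select_normfinder_normalizers(
            pool, matrix, n_select=5, use_cv_ranking=True
        )
        assert set(chosen.probe_ids) <= set(truth.stable_probe_ids)
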
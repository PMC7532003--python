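"""The percentile shift statistic: raw shifts, the empirical error model,
net shifts, per-gene probabilities and direction classification."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from apashift import shiftmodel
from apashift.shiftmodel import (
    CombinedClass,
    ErrorModel,
    build_error_model,
    classify_combined,
    classify_strain,
    gene_probability,
    net_overall_end_zone_shift,
    net_shift,
    percentile_error,
    raw_shift,
    weighted_average_net_shift,
)


class TestRawShift:
    def test_mean_of_replicate_differences_rounded(self):
        assert raw_shift((60, 60), (70, 72)) == -11

    def test_identical_conditions_give_zero(self):
        assert raw_shift((70, 70), (70, 70)) == 0

    def test_halves_round_away_from_zero(self):
        assert raw_shift((71, 70), (70, 70)) == 1
        assert raw_shift((70, 69), (70, 70)) == -1


class TestPercentileError:
    def test_mean_of_within_condition_differences(self):
        # T1-T2 = 4, R1-R2 = -2 -> round(|1|) = 1
        assert percentile_error((10, 6), (8, 10)) == 1

    def test_reproducible_replicates_have_zero_error(self):
        assert percentile_error((55, 55), (70, 70)) == 0

    def test_halves_round_away_from_zero(self):
        # T1-T2 = 3, R1-R2 = 0 -> round(1.5) = 2
        assert percentile_error((13, 10), (50, 50)) == 2


class TestNetShift:
    @pytest.mark.parametrize(
        "raw,err,k", [(-11, 1, -10), (3, 5, 0), (0, 7, 0), (8, 8, 0), (6, 2, 4)]
    )
    def test_error_subtraction_with_zeroing(self, raw, err, k):
        assert net_shift(raw, err) == k


class TestErrorModel:
    def test_hand_tabulated_distribution(self):
        # 10 genes with magnitudes [0 x8, 2, 4]
        model = build_error_model({50: [0] * 8 + [2, 4]})
        assert model.freqs[50] == {0: 8.0, 2: 0.5, 4: 0.5}
        assert model.tail_prob(50, 3) == pytest.approx(0.05)
        assert model.tail_prob(50, 0) == pytest.approx(0.9)
        assert model.max_mag[50] == 4

    def test_floor_probability_is_one_over_gene_count(self):
        model = build_error_model({50: [0] * 2790})
        assert model.floor == pytest.approx(1 / 2790)
        assert model.floor == pytest.approx(3.58e-4, rel=5e-3)
        # beyond the largest observed magnitude the floor applies
        assert model.tail_prob(50, model.max_mag[50] + 3) == pytest.approx(1 / 2790)

    def test_zero_genes_is_an_error(self):
        with pytest.raises(ValueError):
            build_error_model({50: []})

    @given(
        st.lists(st.integers(min_value=0, max_value=30), min_size=3, max_size=200)
    )
    def test_tail_probability_is_non_increasing_over_the_support(self, mags):
        model = build_error_model({50: mags})
        ps = [model.tail_prob(50, x) for x in range(0, model.max_mag[50] + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        assert 0 < ps[-1] <= 1


class TestGeneProbability:
    def _model(self):
        # tails engineered per percentile: P at the magnitudes used below are
        # q10:0.05, q25:0.05, q50:0.1, q75:0.05, q90:0.2 (G = 10)
        freqs = {
            10: {0: 8.0, 2: 0.5, 4: 0.5},
            25: {0: 8.0, 2: 0.5, 4: 0.5},
            50: {0: 8.0, 1: 1.0},
            75: {0: 8.0, 2: 0.5, 4: 0.5},
            90: {0: 7.0, 1: 1.5, 2: 0.5},
        }
        return ErrorModel("cmp", 10, freqs, {q: max(f) for q, f in freqs.items()})

    def test_product_of_five_tails_times_five(self):
        model = self._model()
        ks = {10: -3, 25: 3, 50: 1, 75: -3, 90: 1}
        assert gene_probability(ks, model) == pytest.approx(
            5 * 0.05 * 0.05 * 0.1 * 0.05 * 0.2
        )

    def test_capped_at_one_when_all_percentiles_are_null(self):
        freqs = {q: {0: 10.0} for q in (10, 25, 50, 75, 90)}
        model = ErrorModel("cmp", 10, freqs, {q: 0 for q in freqs})
        assert gene_probability({q: 0 for q in freqs}, model) == 1.0

    def test_magnitudes_beyond_max_use_the_floor(self):
        model = build_error_model({q: [0] * 2789 + [2] for q in (10, 25, 50, 75, 90)})
        p = model.tail_prob(10, model.max_mag[10] + 3)
        assert p == pytest.approx(3.58e-4, rel=5e-3)


class TestClassification:
    def test_consistent_negative_shifts_with_small_p_are_upshifted(self):
        ks = (-3, -4, -2, -5, -1)
        assert classify_strain(sum(ks), -5, 1.25e-5) == "upshifted"

    def test_large_p_blocks_the_call(self):
        assert classify_strain(-15, -3, 0.02) == "other"

    def test_mixed_signs_need_consistent_net_positions(self):
        assert classify_strain(-7, +1, 1e-4) == "other"

    def test_positive_analogue_is_downshifted(self):
        assert classify_strain(12, 4, 1e-3) == "downshifted"


class TestCombinedClassification:
    SLOW, FAST = ("slow1", "slow2"), ("fast1", "fast2")

    def _calls(self, s1, s2, f1, f2):
        return dict(zip((*self.SLOW, *self.FAST), (s1, s2, f1, f2)))

    def test_upshifted_in_both_slow_strains_is_upstream(self):
        got = classify_combined(
            self._calls("upshifted", "upshifted", "other", "other"),
            self.SLOW, self.FAST, gene="g",
        )
        assert (got.cls, got.both_flag) == ("Upstream", False)

    def test_intersection_of_criteria_sets_is_flagged_both(self):
        got = classify_combined(
            self._calls("upshifted", "upshifted", "downshifted", "downshifted"),
            self.SLOW, self.FAST,
        )
        assert got.is_upstream and got.is_downstream and got.both_flag

    def test_other_everywhere_is_neutral(self):
        got = classify_combined(
            self._calls("other", "other", "other", "other"), self.SLOW, self.FAST
        )
        assert got.cls == "Neutral"

    def test_single_strain_shifts_fall_through_to_other(self):
        got = classify_combined(
            self._calls("upshifted", "other", "other", "other"), self.SLOW, self.FAST
        )
        assert got.cls == "Other"

    def test_missing_strain_call_is_an_error(self):
        with pytest.raises(KeyError):
            classify_combined({"slow1": "other"}, self.SLOW, self.FAST)


class TestWeightedAverageNetShift:
    def test_error_diminished_shift(self):
        # s = -12, e = 2 -> -10
        assert weighted_average_net_shift((58, 60), (70, 72)) == pytest.approx(-10.0)

    def test_zeroed_when_noise_exceeds_the_shift(self):
        # s = 1, e = 3
        assert weighted_average_net_shift((74, 68), (70, 70)) == 0.0

    def test_identical_conditions_give_zero(self):
        assert weighted_average_net_shift((70, 72), (70, 72)) == 0.0


class TestNetOverallShift:
    def test_constant_percentile_shifts(self):
        assert net_overall_end_zone_shift({q: -10 for q in (10, 25, 50, 75, 90)}) == -10

    def test_zero_everywhere(self):
        assert net_overall_end_zone_shift({q: 0 for q in (10, 25, 50, 75, 90)}) == 0

    def test_two_strains_average(self):
        assert net_overall_end_zone_shift([-8, -12]) == -10


coord_pairs = st.tuples(
    st.integers(min_value=1, max_value=400), st.integers(min_value=1, max_value=400)
)


@given(coord_pairs, coord_pairs)
def test_swapping_conditions_negates_shifts_and_preserves_errors(t, r):
    assert raw_shift(t, r) == -raw_shift(r, t)
    assert percentile_error(t, r) == percentile_error(r, t)
    k = net_shift(raw_shift(t, r), percentile_error(t, r))
    k_swapped = net_shift(raw_shift(r, t), percentile_error(r, t))
    assert k == -k_swapped
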
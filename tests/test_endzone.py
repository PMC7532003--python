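"""Profiles, landmarks, percentile coordinates, usage curves, replicate QC."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from apashift import endzone
from conftest import counts_frame

WORKED = {50: 200, 60: 1000, 75: 300, 120: 40, 130: 10}


class TestFilterGenes:
    def _frame(self, totals):
        rows = []
        for gene, per_cond in totals.items():
            for cond, (r1, r2) in per_cond.items():
                rows.append((cond, 1, gene, 10, r1))
                rows.append((cond, 2, gene, 10, r2))
        return counts_frame(rows)

    def test_combined_threshold_is_inclusive(self):
        counts = self._frame({"g1": {"A": (600, 400), "B": (900, 500)}})
        assert endzone.filter_genes(counts, 1000) == ["g1"]

    def test_one_deficient_condition_drops_the_gene(self):
        counts = self._frame({"g1": {"A": (600, 399), "B": (900, 500)}})
        assert endzone.filter_genes(counts, 1000) == []

    def test_zero_threshold_keeps_all_expressed_genes(self):
        counts = self._frame(
            {"g1": {"A": (1, 0), "B": (2, 0)}, "g2": {"A": (5, 5), "B": (1, 1)}}
        )
        assert endzone.filter_genes(counts, 0) == ["g1", "g2"]


class TestBuildProfile:
    def test_worked_example_landmarks(self):
        p = endzone.build_profile(WORKED, gene="g", condition="c")
        assert p.scaled.to_dict() == {50: 20.0, 60: 100.0, 75: 30.0, 120: 4.0, 130: 1.0}
        assert p.max_position == 60
        assert set(p.major_offsets) == {50, 60, 75}
        assert (p.zone5, p.zone3, p.span) == (50, 75, 25)
        assert p.weighted_average == pytest.approx(98600 / 1550)  # 63.61
        assert p.total == 1550

    def test_single_isoform_degenerates_cleanly(self):
        p = endzone.build_profile({100: 10})
        assert (p.max_position, p.span, p.weighted_average) == (100, 0, 100.0)

    def test_zero_total_gene_is_unprofiled(self):
        assert endzone.build_profile({10: 0.0}) is None

    @given(st.floats(min_value=0.01, max_value=1e4))
    def test_profile_is_invariant_to_positive_rescaling(self, c):
        base = endzone.build_profile(WORKED)
        scaled = endzone.build_profile({k: v * c for k, v in WORKED.items()})
        assert scaled.max_position == base.max_position
        assert (scaled.zone5, scaled.zone3) == (base.zone5, base.zone3)
        assert scaled.weighted_average == pytest.approx(base.weighted_average)
        assert np.allclose(scaled.scaled.to_numpy(), base.scaled.to_numpy())

    def test_max_isoform_ties_break_to_the_proximal_offset(self):
        p = endzone.build_profile({30: 5, 80: 5, 90: 1})
        assert p.max_position == 30

    def test_weighted_average_is_translation_equivariant(self):
        base = endzone.build_profile(WORKED)
        shifted = endzone.build_profile({k + 13: v for k, v in WORKED.items()})
        assert shifted.weighted_average == pytest.approx(base.weighted_average + 13)


class TestPercentileCoords:
    def test_cumulative_walk_example(self):
        got = endzone.percentile_coords({50: 200, 60: 1000, 75: 300})
        assert got == {10: 50, 25: 60, 50: 60, 75: 60, 90: 75}

    def test_single_site_pins_all_percentiles(self):
        assert set(endzone.percentile_coords({42: 7}).values()) == {42}

    def test_uniform_counts_walk_the_offsets(self):
        got = endzone.percentile_coords({1: 1, 2: 1, 3: 1, 4: 1})
        assert got == {10: 1, 25: 1, 50: 2, 75: 3, 90: 4}

    @given(
        st.dictionaries(
            st.integers(min_value=1, max_value=400),
            st.integers(min_value=1, max_value=1000),
            min_size=1,
            max_size=12,
        )
    )
    def test_coordinates_are_non_decreasing_in_q(self, counts):
        coords = endzone.percentile_coords(counts)
        vals = [coords[q] for q in sorted(coords)]
        assert vals == sorted(vals)


class TestMetagene:
    def _profiles(self, counts_by_gene, condition):
        return {
            g: endzone.build_profile(c, gene=g, condition=condition)
            for g, c in counts_by_gene.items()
        }

    def test_identical_conditions_are_never_flagged(self):
        by_gene = {"g1": WORKED, "g2": {30: 10, 44: 90}}
        profs = {
            "A": self._profiles(by_gene, "A"),
            "B": self._profiles(by_gene, "B"),
        }
        landmarks, metagene, tests = endzone.metagene_and_landmark_table(
            profs, comparisons=[("A", "B")]
        )
        assert (tests["median_difference"] == 0).all()
        assert not tests["significant"].any()
        pd.testing.assert_series_equal(
            metagene["A"], metagene["B"], check_names=False
        )

    def test_constant_landmark_median_equals_the_constant(self):
        by_gene = {f"g{i}": {100: 10} for i in range(5)}
        profs = {"A": self._profiles(by_gene, "A")}
        landmarks, _, _ = endzone.metagene_and_landmark_table(profs)
        assert landmarks.loc["A", "max_position"] == 100
        assert landmarks.loc["A", "span"] == 0

    def test_injected_proximal_shift_lowers_the_median_weighted_average(self):
        from apashift import synthetic

        # every gene tilted proximally in the test condition
        spec = synthetic.SyntheticSpec(
            n_genes=60, depth_per_replicate=2000, sensitive_fraction=1.0, seed=1234
        )
        _, _, counts = synthetic.simulate(spec)
        genes = endzone.filter_genes(counts, 1000)
        profs = {
            c: endzone.condition_profiles(counts, genes, c) for c in ("ref", "test")
        }
        landmarks, _, tests = endzone.metagene_and_landmark_table(
            profs, comparisons=[("ref", "test")]
        )
        wa = tests[tests["landmark"] == "weighted_average"].iloc[0]
        assert landmarks.loc["test", "weighted_average"] < landmarks.loc["ref", "weighted_average"]
        assert wa["median_difference"] < 0
        assert wa["significant"]


class TestPercentCoordinateUsage:
    def test_fraction_of_non_a_positions_with_reads(self, micro_bundle):
        # offset 7: gP has C (non-A), gM has G (non-A); only gP has reads
        counts = counts_frame([("A", 1, "gP", 7, 5)])
        pct = endzone.percent_coordinate_usage(
            counts, micro_bundle, ["gP", "gM"], utr_len=40
        )
        assert pct.loc[7] == 50.0

    def test_full_coverage_gives_100_everywhere(self, micro_bundle):
        rows = [
            ("A", 1, g, o, 3)
            for g in ("gP", "gM")
            for o in micro_bundle.non_a_offsets(g)
        ]
        pct = endzone.percent_coordinate_usage(
            counts_frame(rows), micro_bundle, ["gP", "gM"], utr_len=40
        )
        assert np.nanmax(pct.to_numpy()) == 100.0
        assert (pct.dropna() == 100.0).all()

    def test_no_reads_gives_zero_at_defined_offsets(self, micro_bundle):
        pct = endzone.percent_coordinate_usage(
            counts_frame([]), micro_bundle, ["gP", "gM"], utr_len=40
        )
        assert (pct.dropna() == 0.0).all()


class TestReplicateCorrelations:
    def test_duplicated_replicate_gives_perfect_correlation(self):
        rows = [
            ("A", r, g, o, c)
            for r in (1, 2)
            for g, o, c in [("g1", 10, 500), ("g1", 20, 700), ("g2", 15, 30),
                            ("g2", 30, 250), ("g3", 40, 1000)]
        ]
        res = endzone.replicate_correlations(
            counts_frame(rows), genes=["g1", "g2", "g3"]
        )
        assert res["totals"] == pytest.approx(1.0)
        assert res["isoforms"] == pytest.approx(1.0)
        assert np.allclose(res["profiles"].to_numpy(), 1.0)

    def test_reversed_totals_anticorrelate(self):
        rows = [
            ("A", 1, "g1", 10, 1), ("A", 1, "g2", 10, 2), ("A", 1, "g3", 10, 3),
            ("A", 2, "g1", 10, 3), ("A", 2, "g2", 10, 2), ("A", 2, "g3", 10, 1),
        ]
        res = endzone.replicate_correlations(counts_frame(rows))
        assert res["totals"] == pytest.approx(-1.0)

    def test_low_count_isoforms_are_omitted_from_the_isoform_level(self):
        rows = [
            ("A", 1, "g1", 10, 9), ("A", 2, "g1", 10, 9),      # excluded
            ("A", 1, "g1", 20, 100), ("A", 2, "g1", 20, 120),
            ("A", 1, "g2", 15, 50), ("A", 2, "g2", 15, 40),
            ("A", 1, "g2", 25, 11), ("A", 2, "g2", 25, 2),      # kept: one rep >= 10
        ]
        res = endzone.replicate_correlations(counts_frame(rows))
        # correlation computed on the three kept isoforms only
        a = np.array([100, 50, 11]); b = np.array([120, 40, 2])
        expected = np.corrcoef(a, b)[0, 1]
        assert res["isoforms"] == pytest.approx(expected, abs=1e-12)
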
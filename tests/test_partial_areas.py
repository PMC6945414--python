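"""Vertical, horizontal and concordant partial areas; sPA; report assembly."""

import math

import numpy as np
import pytest

from rocpartials import (
    PartialRange,
    ScoredDataset,
    auc_trapezoid,
    build_empirical_roc,
    c_statistic,
    compute_report,
    concordant_from_components,
    normalized_measures,
    pauc_concordant,
    pauc_horizontal,
    pauc_vertical,
    spa_from_pauc,
    spa_mcclish,
    staircase_fixture,
)

from conftest import random_boundaries, random_dataset


@pytest.fixture
def diagonal():
    return build_empirical_roc(ScoredDataset(scores=[1.0, 1.0], labels=[1, 0]))


class TestPaucVertical:
    def test_diagonal_closed_form(self, diagonal):
        assert pauc_vertical(diagonal, 0, 0.5) == pytest.approx(0.125)

    def test_toy_rectangle(self, toy):
        roc = build_empirical_roc(toy)
        assert pauc_vertical(roc, 0, 0.5) == 0.25

    def test_whole_range_is_auc(self, toy):
        roc = build_empirical_roc(toy)
        assert pauc_vertical(roc, 0, 1) == auc_trapezoid(roc)

    def test_reversed_bounds_rejected(self, toy):
        with pytest.raises(ValueError, match="reversed"):
            pauc_vertical(build_empirical_roc(toy), 0.6, 0.4)


class TestPaucHorizontal:
    def test_diagonal_closed_form(self, diagonal):
        assert pauc_horizontal(diagonal, 0, 0.5) == pytest.approx(0.375)

    def test_toy_full_specificity_band(self, toy):
        roc = build_empirical_roc(toy)
        assert pauc_horizontal(roc, 0, 0.5) == 0.5

    def test_whole_range_equals_vertical_whole(self, toy):
        roc = build_empirical_roc(toy)
        assert pauc_horizontal(roc, 0, 1) == pytest.approx(auc_trapezoid(roc), abs=1e-12)

    def test_reversed_bounds_rejected(self, toy):
        with pytest.raises(ValueError, match="reversed"):
            pauc_horizontal(build_empirical_roc(toy), 0.6, 0.4)


class TestPaucConcordant:
    def test_published_part_recombination(self):
        """Half-sum of printed part components reproduces the printed value."""
        assert concordant_from_components(0.213, 0.777) == pytest.approx(0.495)

    def test_toy_quadrant(self, toy):
        roc = build_empirical_roc(toy)
        assert pauc_concordant(roc, PartialRange(0, 0.5, 0, 0.5)) == 0.375

    def test_whole_curve_reduces_to_auc(self, toy):
        roc = build_empirical_roc(toy)
        assert pauc_concordant(roc, PartialRange(0, 1, 0, 1)) == pytest.approx(
            auc_trapezoid(roc), abs=1e-12
        )

    def test_off_curve_endpoint_named(self, toy):
        roc = build_empirical_roc(toy)
        with pytest.raises(ValueError, match="right endpoint"):
            pauc_concordant(roc, PartialRange(0, 0.25, 0, 0.9))

    @pytest.mark.parametrize("seed", range(15))
    def test_additive_over_adjacent_ranges(self, seed):
        from rocpartials import PartitionSpec, resolve_partition

        data = random_dataset(seed)
        roc = build_empirical_roc(data)
        ranges = resolve_partition(
            roc, PartitionSpec(fpr_boundaries=tuple(random_boundaries(seed)))
        )
        total = sum(pauc_concordant(roc, r) for r in ranges)
        assert total == pytest.approx(auc_trapezoid(roc), abs=1e-12)
        for r in ranges:
            assert pauc_vertical(roc, r.x1, r.x2) <= r.width + 1e-12
            assert pauc_horizontal(roc, r.y1, r.y2) <= r.height + 1e-12
            assert pauc_concordant(roc, r) <= 0.5 * (r.width + r.height) + 1e-12


class TestNormalizedMeasures:
    def test_whole_curve_all_equal_auc(self, toy):
        roc = build_empirical_roc(toy)
        nm = normalized_measures(roc, PartialRange(0, 1, 0, 1))
        assert nm.pauc_norm == nm.pauc_x_norm == nm.pauc_c_norm == auc_trapezoid(roc)

    def test_toy_quadrant_values(self, toy):
        roc = build_empirical_roc(toy)
        nm = normalized_measures(roc, PartialRange(0, 0.5, 0, 0.5))
        assert nm == (0.5, 1.0, 0.75)

    def test_published_normalized_pauc_within_rounding(self, toy):
        # 21.3% over a width-0.33 band: 64.5% vs the printed 64.6%
        assert 0.213 / 0.33 == pytest.approx(0.646, abs=0.002)

    def test_zero_width_rejected(self):
        data = staircase_fixture("vertical_end")
        roc = build_empirical_roc(data)
        with pytest.raises(ValueError, match="zero-width"):
            normalized_measures(roc, PartialRange(0, 0, 0, 0.6))


class TestSPA:
    def test_published_value(self):
        """sPA of the printed leftmost-part pAUC over FPR [0, 0.33]."""
        assert spa_from_pauc(0.213, 0, 0.33) == pytest.approx(0.788, abs=5e-4)

    def test_chance_level_is_half(self):
        # pAUC equal to the diagonal area over the band
        assert spa_from_pauc(0.125, 0, 0.5) == 0.5

    def test_full_rectangle_is_one(self):
        assert spa_from_pauc(0.5, 0, 0.5) == 1.0

    def test_below_diagonal_goes_under_half(self):
        assert spa_from_pauc(0.05, 0, 0.5) < 0.5

    def test_curve_wrapper_matches_pauc_route(self, toy):
        roc = build_empirical_roc(toy)
        assert spa_mcclish(roc, 0, 0.5) == spa_from_pauc(
            pauc_vertical(roc, 0, 0.5), 0, 0.5
        )

    def test_zero_width_rejected(self, toy):
        with pytest.raises(ValueError, match="zero-width"):
            spa_mcclish(build_empirical_roc(toy), 0.5, 0.5)


class TestDegenerateRanges:
    def test_pure_vertical_part_has_no_vertical_area(self):
        """A purely vertical partial curve: pAUC = 0 but pAUC_x > 0, and the
        area route still agrees with the partial c statistic."""
        from rocpartials import partial_c, range_to_weights

        data = staircase_fixture("vertical_end")
        roc = build_empirical_roc(data)
        prange = PartialRange(0, 0, 0, 0.6)
        assert pauc_vertical(roc, 0, 0) == 0.0
        assert pauc_horizontal(roc, 0, 0.6) > 0.0
        c_delta = partial_c(data, range_to_weights(data, roc, prange))
        assert pauc_concordant(roc, prange) == pytest.approx(c_delta, abs=1e-12)


class TestComputeReport:
    def test_toy_two_part_report(self, toy):
        report = compute_report(toy, [0, 0.5, 1])
        assert report.parts["pauc_c"].tolist() == [0.5, 0.25]
        assert report.sums()["pauc_c"] == pytest.approx(report.whole["auc"])
        assert math.isnan(report.parts["pauc_x_norm"].iloc[1])  # degenerate part 2

    def test_single_part_equals_whole(self, toy):
        report = compute_report(toy, [0, 1])
        row = report.parts.iloc[0]
        assert row["pauc"] == row["pauc_c"] == row["pauc_x"] == report.whole["auc"]
        assert row["c_delta"] == report.whole["c"]
        assert row["local_c"] == report.whole["c"]

    @pytest.mark.parametrize("seed", [2, 7, 13])
    def test_all_sum_columns_equal_auc(self, seed):
        data = random_dataset(seed)
        report = compute_report(data, random_boundaries(seed))
        auc = report.whole["auc"]
        assert report.whole["c"] == pytest.approx(auc, abs=1e-10)
        for col, total in report.sums().items():
            assert total == pytest.approx(auc, abs=1e-9), col
        assert np.allclose(report.parts["pauc_c"], report.parts["c_delta"], atol=1e-9)
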
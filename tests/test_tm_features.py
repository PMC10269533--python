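"""TM geometry: hydropathy predictor, surface area, raft flag, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ttrcensus import resources
from ttrcensus.tm_features import (
    KYTE_DOOLITTLE,
    AreaTable,
    TMParams,
    TMRegion,
    calibrate_area_table,
    calibration_factor,
    predict_tm_regions,
    raft_propensity,
    surface_area_per_aa,
    tm_profile,
)

PARAMS = TMParams()


def brute_force_tm(sequence, params=PARAMS):
    """Independent re-implementation of the window rule (explicit loops,
    exact rational arithmetic for the threshold comparison)."""
    from fractions import Fraction

    w, h = params.hydropathy_window, params.hydropathy_window // 2
    threshold = Fraction(str(params.hydropathy_threshold))
    n = len(sequence)
    if n < w:
        return []
    spans = []
    current = None
    for center in range(h, n - h):
        mean = Fraction(
            sum(int(round(KYTE_DOOLITTLE[a] * 10)) for a in sequence[center - h : center + h + 1]),
            10 * w,
        )
        if mean >= threshold:
            if current is None:
                current = [center - h, center + h]
            else:
                current[1] = center + h
        else:
            if current is not None:
                spans.append(current)
                current = None
    if current is not None:
        spans.append(current)
    merged = []
    for s, e in spans:
        if merged and s - merged[-1][1] - 1 <= params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        (s + 1, e + 1) for s, e in merged if e - s + 1 >= params.min_region_length
    ]


class TestPredictor:
    def test_hydrophilic_sequence_has_no_regions(self):
        assert predict_tm_regions("D" * 100) == []

    def test_single_leucine_stretch_found(self):
        seq = "E" * 5 + "L" * 30 + "K" * 5
        regions = predict_tm_regions(seq)
        assert len(regions) == 1
        (r,) = regions
        # the Leu stretch (residues 6..35) is covered, +/- window expansion
        assert r.start <= 6 and r.end >= 35
        assert [(r.start, r.end)] == brute_force_tm(seq)

    def test_sequence_shorter_than_window_gives_nothing(self):
        assert predict_tm_regions("L" * 18) == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            predict_tm_regions("")

    @given(st.text(alphabet="LDG", min_size=1, max_size=60))
    @settings(max_examples=400, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, seq):
        got = [(r.start, r.end) for r in predict_tm_regions(seq)]
        assert got == brute_force_tm(seq)

    @given(st.text(alphabet="LDG", min_size=19, max_size=60))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_regions_sorted_disjoint_and_long_enough(self, seq):
        regions = predict_tm_regions(seq)
        for r in regions:
            assert r.length >= PARAMS.min_region_length
            assert 1 <= r.start <= r.end <= len(seq)
        for a, b in zip(regions, regions[1:]):
            assert b.start > a.end


class TestSurfaceArea:
    def test_uniform_region_scores_the_residue_constant(self, area_table):
        seq = "G" * 30
        sa = surface_area_per_aa(seq, [TMRegion(5, 24)], area_table)
        assert sa == pytest.approx(area_table["G"])

    def test_equal_halves_score_the_arithmetic_mean(self, area_table):
        seq = "G" * 10 + "A" * 5 + "W" * 10
        regions = [TMRegion(1, 10), TMRegion(16, 25)]
        expected = (area_table["G"] + area_table["W"]) / 2
        assert surface_area_per_aa(seq, regions, area_table) == pytest.approx(expected)

    def test_region_order_does_not_matter(self, area_table):
        seq = "GAVLIWFMKR" * 4
        a = [TMRegion(3, 12), TMRegion(20, 33)]
        assert surface_area_per_aa(seq, a, area_table) == pytest.approx(
            surface_area_per_aa(seq, list(reversed(a)), area_table)
        )

    def test_empty_region_list_rejected(self, area_table):
        with pytest.raises(ValueError, match="no TM residues"):
            surface_area_per_aa("GGGG", [], area_table)

    @given(st.integers(0, 19))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_upgrading_a_residue_strictly_increases_area(self, pos):
        table = resources.default_area_table()
        seq = list("G" * 20)
        sa0 = surface_area_per_aa("".join(seq), [TMRegion(1, 20)], table)
        seq[pos] = "W"  # strictly larger constant than G
        sa1 = surface_area_per_aa("".join(seq), [TMRegion(1, 20)], table)
        assert sa1 > sa0

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=20, max_size=40))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bounds_between_table_extremes(self, seq):
        table = resources.default_area_table()
        sa = surface_area_per_aa(seq, [TMRegion(1, len(seq))], table)
        assert table.min() <= sa <= table.max()


class TestRaftThreshold:
    @pytest.mark.parametrize(
        "sa, expected", [(172.0, True), (172.01, False), (100.0, True)]
    )
    def test_inclusive_threshold(self, sa, expected):
        assert raft_propensity(sa) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            raft_propensity(float("nan"))


class TestProfile:
    def test_single_region_arithmetic(self, area_table):
        seq = "K" * 6 + "L" * 23 + "K" * 6
        p = tm_profile(seq, [TMRegion(7, 29)], PARAMS, area_table)
        assert (p.n_regions, p.mean_length) == (1, 23.0)
        assert p.sa_per_aa == pytest.approx(area_table["L"])

    def test_equal_composition_regions_are_symmetric(self, area_table):
        seq = "L" * 20 + "K" * 10 + "L" * 20
        p = tm_profile(seq, [TMRegion(1, 20), TMRegion(31, 50)], PARAMS, area_table)
        assert p.mean_length == 20.0
        assert p.sa_per_aa == pytest.approx(
            surface_area_per_aa(seq, [TMRegion(1, 20)], area_table)
        )

    def test_no_regions_leaves_geometry_absent(self, area_table):
        p = tm_profile("MKKK" * 10, [], PARAMS, area_table)
        assert (p.n_regions, p.mean_length, p.sa_per_aa, p.raft_flag) == (0, None, None, None)

    def test_residue_weighted_pooling_differs_from_region_means(self, area_table):
        # a short W-rich region and a long G region: pooling weights by residues
        seq = "W" * 5 + "K" * 10 + "G" * 25
        regions = [TMRegion(1, 5), TMRegion(16, 40)]
        pooled = surface_area_per_aa(seq, regions, area_table)
        per_region_mean = (area_table["W"] + area_table["G"]) / 2
        expected = (5 * area_table["W"] + 25 * area_table["G"]) / 30
        assert pooled == pytest.approx(expected)
        assert abs(pooled - per_region_mean) > 1.0


class TestCalibration:
    def test_poly_leu_factor_is_closed_form(self):
        base = AreaTable.base()
        seq = "K" * 5 + "L" * 20 + "K" * 5
        factor = calibration_factor(seq, TMRegion(6, 25), base, target=172.0)
        assert factor == pytest.approx(172.0 / base["L"])

    def test_vendored_table_reproduces_anchor_calibration(self, area_table):
        anchor, region = resources.load_anchor()
        recomputed = calibrate_area_table(anchor.sequence, region, AreaTable.base())
        assert recomputed.calibration_factor == pytest.approx(
            area_table.calibration_factor, abs=1e-9
        )
        sa = surface_area_per_aa(anchor.sequence, [region], area_table)
        assert sa == pytest.approx(172.0, abs=1e-6)
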
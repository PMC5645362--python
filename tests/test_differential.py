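"""The DAve/DCI statistics, calling, overlap analysis and heat matrix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapdiff.differential import (
    DifferentialRecord,
    DiffThresholds,
    UndefinedStatisticError,
    compare_conditions,
    compute_dave,
    compute_dci,
    dave_bin,
    heatmap_matrix,
    overlap_analysis,
)
from tests.conftest import make_profile

score_st = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)
pos_score_st = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


class TestComputeDave:
    @pytest.mark.parametrize("x, y, expected", [
        (100.0, 0.0, 2.0),     # exclusive protein sits at the bound
        (0.0, 100.0, -2.0),
        (250.0, 250.0, 0.0),
        (300.0, 100.0, 1.0),   # 200 / 200
    ])
    def test_known_values(self, x, y, expected):
        assert compute_dave(x, y) == pytest.approx(expected)

    def test_undefined_when_absent_from_both(self):
        with pytest.raises(UndefinedStatisticError):
            compute_dave(0.0, 0.0)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_dave(-1.0, 5.0)

    @given(pos_score_st, pos_score_st)
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetric_and_bounded(self, x, y):
        d = compute_dave(x, y)
        assert d == pytest.approx(-compute_dave(y, x))
        assert abs(d) <= 2.0
        # the bound is attained exactly (not approached) iff one score is 0
        assert (abs(d) == 2.0) == (x == 0 or y == 0)

    @given(pos_score_st, pos_score_st, st.floats(min_value=1e-2, max_value=1e3))
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariant(self, x, y, c):
        assert compute_dave(c * x, c * y) == pytest.approx(compute_dave(x, y), rel=1e-9)


class TestComputeDci:
    @pytest.mark.parametrize("x, y, expected", [
        (100.0, 100.0, 0.0),
        (50.0, 30.0, 800.0),     # (80 * 20) / 2
        (0.0, 60.0, -1800.0),    # (60 * -60) / 2
    ])
    def test_known_values(self, x, y, expected):
        assert compute_dci(x, y) == pytest.approx(expected)

    @given(score_st, score_st, st.floats(min_value=1e-2, max_value=1e2))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_sign_and_quadratic_scaling(self, x, y, c):
        d = compute_dci(x, y)
        assert d == pytest.approx(-compute_dci(y, x))
        assert np.sign(d) == np.sign(x - y)
        assert compute_dci(c * x, c * y) == pytest.approx(c**2 * d, rel=1e-9)

    @given(pos_score_st, pos_score_st)
    @settings(max_examples=100, derandomize=True)
    def test_same_sign_as_dave(self, x, y):
        assert compute_dave(x, y) * compute_dci(x, y) >= 0


class TestCompareConditions:
    def test_hand_worked_calls(self):
        px = make_profile("X", {"P": 60.0, "Q": 25.0, "R": 100.0})
        py = make_profile("Y", {"P": 20.0, "R": 100.0})
        records = {r.accession: r for r in compare_conditions(px, py)}
        p, q, r = records["P"], records["Q"], records["R"]
        assert (p.dave, p.dci, p.call) == (pytest.approx(1.0), pytest.approx(1600.0), "up_in_X")
        # exclusive but too weak for the DCI gate: (25, 0) -> DCI 312.5 < 400
        assert (q.dave, q.dci, q.call, q.exclusive) == (2.0, pytest.approx(312.5), "unchanged", True)
        assert (r.dave, r.call) == (0.0, "unchanged")

    def test_both_zero_proteins_are_skipped(self):
        px = make_profile("X", {"P": 50.0})
        py = make_profile("Y", {"Q": 50.0})
        accs = {r.accession for r in compare_conditions(px, py)}
        assert accs == {"P", "Q"}  # union of detected, nothing invented

    def test_min_presence_zeroes_single_replicate_identifications(self):
        px = make_profile("X", {"P": 100.0}, presence={"P": 1})
        py = make_profile("Y", {"P": 20.0}, presence={"P": 2})
        (loose,) = compare_conditions(px, py, min_presence=1)
        (strict,) = compare_conditions(px, py, min_presence=2)
        assert loose.score_x == 100.0
        assert strict.score_x == 0.0 and strict.exclusive

    def test_exclusive_gate_threshold_on_score_grid(self):
        # an exclusive protein passes DCI >= 400 iff its score >= sqrt(800)
        gate = math.sqrt(2 * 400.0)
        for s in np.arange(0.5, 60.0, 0.5):
            px = make_profile("X", {"P": float(s)})
            py = make_profile("Y", {})
            (rec,) = compare_conditions(px, py)
            assert (rec.call == "up_in_X") == (s >= gate)
            assert rec.dave == 2.0

    def test_calls_match_brute_force_reevaluation(self, small_experiment):
        from mapdiff.psm import filter_psms
        from mapdiff.quant import aggregate_proteins, average_replicates

        design, tables, _ = small_experiment
        profiles = {
            c: average_replicates(
                [aggregate_proteins(filter_psms(tables[f"{c}_r{r}"]), f"{c}_r{r}", 10.0)
                 for r in (1, 2)], c)
            for c in design.conditions
        }
        records = compare_conditions(profiles["A"], profiles["B"])
        th = DiffThresholds()
        for r in records:
            dave = (r.score_x - r.score_y) / ((r.score_x + r.score_y) * 0.5)
            dci = (r.score_x + r.score_y) * (r.score_x - r.score_y) / 2
            if dave >= th.dave_min and dci >= th.dci_min:
                expected = "up_in_X"
            elif dave <= -th.dave_min and dci <= -th.dci_min:
                expected = "up_in_Y"
            else:
                expected = "unchanged"
            assert r.call == expected
            assert r.exclusive == ((r.score_x == 0) != (r.score_y == 0))


def _rec(acc, dave, call):
    return DifferentialRecord(acc, 1.0, 1.0, dave, 1000.0 * np.sign(dave), call, False)


class TestOverlapAnalysis:
    def test_strict_counts_shared_called_proteins(self):
        a = [_rec("p1", 1.0, "up_in_X"), _rec("p2", 1.0, "up_in_X"), _rec("p3", -1.0, "up_in_Y")]
        b = [_rec("p2", 1.0, "up_in_X"), _rec("p3", -1.0, "up_in_Y"), _rec("p4", 0.1, "unchanged")]
        result = overlap_analysis(a, b, "strict")
        assert (result.n_shared, result.n_total) == (2, 3)
        assert result.fraction == pytest.approx(2 / 3)

    def test_identical_lists_fully_concordant(self):
        a = [_rec("p1", 1.0, "up_in_X"), _rec("p2", -0.8, "up_in_Y")]
        assert overlap_analysis(a, a, "relaxed").fraction == 1.0

    def test_sign_flipped_lists_are_discordant(self):
        a = [_rec("p1", 1.0, "up_in_X"), _rec("p2", -0.8, "up_in_Y")]
        b = [_rec("p1", -1.0, "up_in_Y"), _rec("p2", 0.8, "up_in_X")]
        assert overlap_analysis(a, b, "relaxed").fraction == 0.0

    def test_relaxed_credits_subthreshold_trends(self):
        a = [_rec("p1", 1.0, "up_in_X"), _rec("p2", 0.9, "up_in_X")]
        b = [_rec("p1", 0.2, "unchanged"), _rec("p2", -0.3, "unchanged")]
        result = overlap_analysis(a, b, "relaxed")
        assert (result.n_shared, result.n_total) == (1, 2)


class TestHeatmapMatrix:
    def test_layout_clamping_and_missing_cells(self):
        comps = {
            "c1": [_rec("p1", 2.0, "up_in_X"), _rec("p2", 0.1, "unchanged")],
            "c2": [_rec("p2", -0.7, "up_in_Y")],
        }
        mat = heatmap_matrix(comps)
        assert mat.loc["p1", "c1"] == 2.0
        assert np.isnan(mat.loc["p1", "c2"])  # missing is distinct from 0
        assert mat.loc["p2", "c2"] == -0.7

    def test_grouping_orders_rows_and_drops_orphans(self):
        comps = {"c1": [_rec("p1", 1.0, "up_in_X"), _rec("p2", -1.0, "up_in_Y")]}
        with pytest.warns(UserWarning, match="no comparison"):
            mat = heatmap_matrix(comps, groups={"p2": "glycolysis", "p9": "tca"})
        assert list(mat.index) == ["p2", "p1"]  # annotated group sorts first
        assert "p9" not in mat.index

    @pytest.mark.parametrize("dave, expected", [
        (0.1, 0), (-0.39, 0),       # neutral band
        (2.0, 8), (-2.0, -8),       # deepest bins
        (0.4, 1), (-0.7, -2),       # linear binning above the gate
        (3.5, 8),                   # clamped first
    ])
    def test_colour_bins(self, dave, expected):
        assert dave_bin(dave) == expected
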
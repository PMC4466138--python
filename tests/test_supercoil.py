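"""Supercoil parametrization, placement, clash scanning and sweeps."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

from fingertrap.geometry import RigidTransform, principal_axis
from fingertrap.repeats import RepeatStructure, make_ideal_repeat
from fingertrap.supercoil import (build_tetramer, compute_params, detect_clashes,
                                  full_extension_length, measure_geometry,
                                  min_compact_length, place_repeat, scan_roll,
                                  sweep, _brute_force_clashes)


@pytest.fixture(scope="module")
def params60():
    return compute_params(60.0)


@pytest.fixture(scope="module")
def model60(params60):
    return build_tetramer(make_ideal_repeat(seed=1), params60)


class TestParams:
    def test_60nm_pitch_and_radius(self, params60):
        assert params60.pitch == pytest.approx(6.4865, abs=5e-4)
        assert params60.radius == pytest.approx(2.3516, abs=5e-4)

    def test_full_extension_is_straight(self):
        length = full_extension_length()
        assert length == pytest.approx(184.075, abs=1e-9)
        assert compute_params(length).radius == pytest.approx(0.0, abs=1e-9)

    def test_contour_closure_at_60nm(self, params60):
        recomputed = np.hypot(params60.pitch, 8 * params60.radius)
        assert recomputed == pytest.approx(19.9, abs=1e-12)

    def test_over_extended_rejected(self):
        with pytest.raises(ValueError, match="over-extended"):
            compute_params(300.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        length=st.floats(min_value=1.0, max_value=184.0),
        contour=st.floats(min_value=18.0, max_value=22.0),
    )
    def test_contour_closure_property(self, length, contour):
        max_len = 37 * contour / 4
        length = min(length, max_len * 0.999999)
        p = compute_params(length, contour_length=contour)
        resid = p.contour_length**2 - p.pitch**2 - (8 * p.radius) ** 2
        assert abs(resid) <= 1e-9 * p.contour_length**2
        assert p.total_length == pytest.approx(37 * p.pitch / 4, rel=1e-9)


class TestPlacement:
    def test_quarter_turn_per_repeat(self, params60, ideal_repeat):
        r0, _ = place_repeat(ideal_repeat, params60, 0)
        r1, _ = place_repeat(ideal_repeat, params60, 1)
        m0, m1 = r0.anchor_midpoint, r1.anchor_midpoint
        az = np.degrees(np.arctan2(m1[1], m1[0]) - np.arctan2(m0[1], m0[0]))
        assert az % 360 == pytest.approx(90.0, abs=1e-6)

    def test_full_turn_recovers_azimuth_with_pitch_rise(self, params60, ideal_repeat):
        r0, _ = place_repeat(ideal_repeat, params60, 0)
        r4, _ = place_repeat(ideal_repeat, params60, 4)
        m0, m4 = r0.anchor_midpoint, r4.anchor_midpoint
        assert m4[0] == pytest.approx(m0[0], abs=1e-6)
        assert m4[1] == pytest.approx(m0[1], abs=1e-6)
        assert m4[2] - m0[2] == pytest.approx(params60.pitch * 10.0, abs=1e-6)

    def test_zero_radius_puts_midpoints_on_axis(self, ideal_repeat):
        p = compute_params(full_extension_length())
        for k in (0, 3, 11):
            rep, _ = place_repeat(ideal_repeat, p, k)
            assert np.hypot(*rep.anchor_midpoint[:2]) == pytest.approx(0.0, abs=1e-9)

    def test_placement_is_rigid(self, params60, ideal_repeat):
        ref = pdist(ideal_repeat.ca)
        for k in (0, 7, 21):
            rep, _ = place_repeat(ideal_repeat, params60, k)
            assert np.max(np.abs(pdist(rep.ca) - ref)) < 1e-6

    def test_out_of_range_index_rejected(self, params60, ideal_repeat):
        with pytest.raises(ValueError):
            place_repeat(ideal_repeat, params60, 37)


class TestTetramer:
    def test_74_repeats_and_no_clashes_at_default_roll(self, model60):
        assert model60.n_repeats == 74
        assert detect_clashes(model60) == []

    def test_hollow_core_across_compact_lengths(self):
        repeat = make_ideal_repeat(seed=1)
        for length in (55.0, 60.0, 65.0, 70.0):
            p = compute_params(length)
            m = build_tetramer(repeat, p)
            ca = m.ca
            axis = principal_axis(ca)
            rel = ca - ca.mean(axis=0)
            radial = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
            assert radial.min() > 0.5 * p.radius * 10.0

    def test_right_handed_chirality(self, model60):
        assert measure_geometry(model60)["chirality"] == 1

    def test_left_handed_option_flips_chirality(self):
        p = compute_params(60.0, handedness="left")
        m = build_tetramer(make_ideal_repeat(seed=1), p)
        assert measure_geometry(m)["chirality"] == -1

    def test_strands_antiparallel(self, model60):
        dot = np.dot(model60.strand_a.direction, model60.strand_b.direction)
        assert dot < 0

    def test_measured_length_close_to_requested(self, model60, params60):
        geo = measure_geometry(model60)
        assert abs(geo["length_nm"] - params60.total_length) <= params60.rise_per_repeat

    def test_radius_brackets_em_peak_at_resting_lengths(self):
        for length in (55.0, 60.0, 65.0):
            assert 2.2 <= compute_params(length).radius <= 2.4

    def test_twofold_symmetry_about_perpendicular_axis(self, model60):
        point, direction = model60.symmetry_axis
        flip = RigidTransform.about_axis(direction, 180.0, point=point)
        for rep_a, rep_b in zip(model60.strand_a.repeats, model60.strand_b.repeats):
            mapped = flip.apply(rep_a.ca)
            rmsd = np.sqrt(np.mean(np.sum((mapped - rep_b.ca) ** 2, axis=1)))
            assert rmsd <= 0.1


class TestGeometry:
    def test_bend_at_60nm(self, model60):
        geo = measure_geometry(model60)
        assert geo["bend_deg"] == pytest.approx(83.9, abs=0.5)

    def test_contour_per_turn_is_invariant(self, model60):
        geo = measure_geometry(model60)
        assert geo["contour_per_turn_nm"] == pytest.approx(19.9, abs=0.1)

    def test_straight_limit_has_zero_bend(self, ideal_repeat):
        p = compute_params(full_extension_length())
        m = build_tetramer(ideal_repeat, p)
        assert measure_geometry(m)["bend_deg"] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_repeats_rejected(self, ideal_repeat):
        p = compute_params(15.0, n_repeats=4)
        m = build_tetramer(ideal_repeat, p)
        with pytest.raises(ValueError, match="at least 5"):
            measure_geometry(m)


class TestClashes:
    def test_far_apart_repeats_do_not_clash(self, ideal_repeat):
        p = compute_params(150.0)
        m = build_tetramer(ideal_repeat, p)
        # large pitch separates everything except through-linker joints
        assert detect_clashes(m) == []

    def test_coincident_repeats_all_listed(self, ideal_repeat):
        from fingertrap.assembly import StrandModel
        from fingertrap.supercoil import TetramerModel

        rep = replace(ideal_repeat, repeat_id="X1")
        dup = replace(ideal_repeat, repeat_id="X2")
        strand_a = StrandModel([rep], [RigidTransform.identity()])
        strand_b = StrandModel([dup], [RigidTransform.identity()])
        model = TetramerModel(compute_params(60.0), strand_a, strand_b)
        clashes = detect_clashes(model)
        # every residue coincides with its own copy at distance zero
        assert len(clashes) >= ideal_repeat.n_res

    def test_tree_matches_brute_force(self):
        repeat = make_ideal_repeat(n_res=24, seed=3)
        p = compute_params(15.0, n_repeats=5, roll=-120.0)
        model = build_tetramer(repeat, p)
        fast = set(map(tuple, detect_clashes(model)))
        slow = set(map(tuple, _brute_force_clashes(model)))
        assert fast == slow
        assert len(fast) > 0  # scenario chosen to actually contain clashes


@pytest.fixture(scope="module")
def scan65():
    return scan_roll(make_ideal_repeat(seed=1), 65.0)


class TestRollScan:

    def test_window_exists_and_contains_minus_30(self, scan65):
        window = scan65.attrs["window"]
        assert window is not None
        lo, hi = window
        assert lo <= -30.0 <= hi

    def test_window_at_least_30_degrees_wide(self, scan65):
        lo, hi = scan65.attrs["window"]
        assert hi - lo >= 30.0

    def test_rolls_120_degrees_from_window_clash(self, scan65):
        lo, hi = scan65.attrs["window"]
        mid = (lo + hi) / 2.0
        for away in (mid + 120.0, mid - 120.0):
            away = (away + 180.0) % 360.0 - 180.0
            row = scan65.iloc[(scan65.roll - away).abs().idxmin()]
            assert row.clashes > 0

    def test_result_has_one_entry_per_roll(self, ideal_repeat):
        rolls = np.arange(-180.0, 180.0, 30.0)
        table = scan_roll(ideal_repeat, 65.0, rolls=rolls)
        assert len(table) == 12

    def test_thin_rod_repeat_never_clashes(self):
        # degenerate thin repeat: backbone strung along the anchor axis
        n = 24
        z = np.linspace(0.0, 45.0, n)
        coords = np.zeros((n, 3, 3))
        coords[:, 0, 2] = z - 0.4
        coords[:, 1, 2] = z
        coords[:, 2, 2] = z + 0.4
        # sub-Å wiggle so the seam normal (centroid offset) is defined
        coords[:, 1, 0] = 0.2 * np.sin(z)
        coords[:, 0, 0] = 0.3
        rod = RepeatStructure("rod", np.arange(1, n + 1), "L" + "A" * (n - 2) + "L",
                              coords, 1, n)
        table = scan_roll(rod, 65.0)
        assert table["clashes"].max() == 0


class TestSweep:
    def test_radius_and_bend_strictly_decrease(self, ideal_repeat):
        table, _ = sweep(ideal_repeat, lengths=np.arange(55.0, 185.0, 1.0))
        assert np.all(np.diff(table.radius_nm) < 0)
        assert np.all(np.diff(table.bend_deg) < 0)

    def test_threefold_extension_in_one_sweep(self, ideal_repeat):
        table, _ = sweep(ideal_repeat, lengths=[55.0, 165.0])
        assert len(table) == 2
        assert table.length_nm.iloc[1] / table.length_nm.iloc[0] == 3.0

    def test_invalid_lengths_skipped(self, ideal_repeat):
        table, _ = sweep(ideal_repeat, lengths=[60.0, 300.0, 65.0])
        assert list(table.length_nm) == [60.0, 65.0]

    def test_contour_invariant_along_sweep(self, ideal_repeat):
        lengths = [55.0, 90.0, 130.0, 170.0]
        _, models = sweep(ideal_repeat, lengths=lengths, build_models=True)
        for m in models:
            geo = measure_geometry(m)
            assert geo["contour_per_turn_nm"] == pytest.approx(19.9, abs=0.1)

    def test_chirality_right_handed_at_all_sampled_lengths(self, ideal_repeat):
        _, models = sweep(ideal_repeat, lengths=[55.0, 100.0, 150.0, 180.0],
                          build_models=True)
        for m in models:
            assert measure_geometry(m)["chirality"] == 1


class TestCompactLowerBound:
    def test_twenty_stacked_repeats(self):
        assert min_compact_length(20, 2.5) == 50.0

    @pytest.mark.parametrize("n, width, expected", [(0, 2.5, 0.0), (10, 2.5, 25.0)])
    def test_linearity(self, n, width, expected):
        assert min_compact_length(n, width) == expected
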
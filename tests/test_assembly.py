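"""Rigid superposition and extended-strand assembly."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from fingertrap.assembly import (build_extended_strand, count_strand_repeats,
                                 make_antiparallel_partner)
from fingertrap.geometry import RigidTransform, superpose


@pytest.fixture()
def point_set():
    return np.random.default_rng(0).normal(size=(8, 3)) * 10.0


class TestSuperpose:
    def test_identity(self, point_set):
        tf, rmsd = superpose(point_set, point_set)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)

    def test_pure_translation(self, point_set):
        shift = np.array([5.0, -3.0, 2.0])
        tf, rmsd = superpose(point_set, point_set + shift)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, shift, atol=1e-9)

    def test_recovers_known_37_degree_rotation(self, point_set):
        true = RigidTransform.about_axis([0, 0, 1], 37.0, point=[1.0, 2.0, 3.0])
        tf, rmsd = superpose(point_set, true.apply(point_set))
        angle = np.degrees(np.linalg.norm(Rotation.from_matrix(tf.rotation).as_rotvec()))
        assert angle == pytest.approx(37.0, abs=1e-6)
        assert rmsd <= 1e-6

    def test_too_few_points_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError):
            superpose(pts, pts)

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(pts, pts)

    def test_analytic_beats_rotation_grid_search(self):
        """Kabsch RMSD never exceeds a brute-force grid search over
        single-axis rotations (independent oracle)."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.normal(size=(4, 3)) * 5.0
            ref = RigidTransform.about_axis(
                rng.normal(size=3), rng.uniform(0, 180), point=rng.normal(size=3)
            ).apply(pts) + rng.normal(0.0, 0.5, size=(4, 3))
            _, rmsd = superpose(pts, ref)
            best_grid = np.inf
            ref_c = ref - ref.mean(axis=0)
            pts_c = pts - pts.mean(axis=0)
            for axis in (np.eye(3)):
                for ang in np.arange(0.0, 360.0, 2.0):
                    rot = Rotation.from_rotvec(np.deg2rad(ang) * axis).as_matrix()
                    grid_rmsd = np.sqrt(np.mean(np.sum((pts_c @ rot.T - ref_c) ** 2, -1)))
                    best_grid = min(best_grid, grid_rmsd)
            assert rmsd <= best_grid + 1e-9


class TestExtendedStrand:
    def test_two_repeat_strand_doubles_single_rise(self, two_repeat_template):
        s1 = build_extended_strand(two_repeat_template, 1)
        s2 = build_extended_strand(two_repeat_template, 2)
        single = s1.length
        # one repeat adds one rise; extent(2) = extent(1) + rise
        rise = s2.length - single
        s3 = build_extended_strand(two_repeat_template, 3)
        assert s3.length - s2.length == pytest.approx(rise, abs=0.1)

    def test_37_repeat_strand_in_printed_extended_range(self, two_repeat_template):
        strand = build_extended_strand(two_repeat_template, 37)
        assert strand.n_repeats == 37
        assert 180.0 <= strand.length / 10.0 <= 200.0

    def test_straight_template_gives_straight_strand(self, two_repeat_template):
        strand = build_extended_strand(two_repeat_template, 10)
        mids = np.array([r.anchor_midpoint for r in strand.repeats])
        axis = strand.long_axis
        rel = mids - mids.mean(axis=0)
        off_axis = rel - np.outer(rel @ axis, axis)
        assert np.linalg.norm(off_axis, axis=1).max() < 1.0

    def test_consecutive_anchor_gaps_bounded(self, two_repeat_template):
        strand = build_extended_strand(two_repeat_template, 8)
        assert strand.anchor_gaps().max() < 15.0

    def test_rigidity_of_placed_repeats(self, two_repeat_template):
        strand = build_extended_strand(two_repeat_template, 6)
        ref = pdist(strand.repeats[0].ca)
        for rep in strand.repeats[1:]:
            assert np.max(np.abs(pdist(rep.ca) - ref)) < 1e-6

    def test_kinked_template_gives_constant_curvature(self, ideal_repeat):
        """A template with a fixed inter-repeat kink must propagate into a
        gentle helix of uniform local curvature."""
        from fingertrap.repeats import make_chain

        template = make_chain(ideal_repeat, 2)
        kink = RigidTransform.about_axis(
            [1.0, 0.0, 0.0], 4.0, point=template[1].anchor_coords[0]
        )
        template = [template[0], template[1].transformed(kink)]
        strand = build_extended_strand(template, 12)
        mids = np.array([r.anchor_midpoint for r in strand.repeats])
        curvatures = []
        for i in range(1, len(mids) - 1):
            v1 = mids[i] - mids[i - 1]
            v2 = mids[i + 1] - mids[i]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            curvatures.append(np.arccos(np.clip(cosang, -1, 1)))
        curvatures = np.array(curvatures)
        assert curvatures.max() / curvatures.min() < 1.1


class TestAntiparallelPartner:
    def test_partner_preserves_length(self, two_repeat_template):
        strand = build_extended_strand(two_repeat_template, 8)
        partner = make_antiparallel_partner(strand)
        assert partner.length == pytest.approx(strand.length, abs=1e-6)

    def test_directions_antiparallel(self, two_repeat_template):
        strand = build_extended_strand(two_repeat_template, 8)
        partner = make_antiparallel_partner(strand)
        assert np.dot(strand.direction, partner.direction) == pytest.approx(-1.0, abs=1e-6)

    def test_involution_recovers_original(self, two_repeat_template):
        strand = build_extended_strand(two_repeat_template, 8)
        back = make_antiparallel_partner(make_antiparallel_partner(strand))
        assert np.max(np.abs(back.ca - strand.ca)) <= 1e-6


class TestRepeatAccounting:
    def test_heterotetramer_strand_has_37_repeats(self):
        assert count_strand_repeats(20, 16, 1) == 37

    @pytest.mark.parametrize(
        "args, expected", [((0, 0, 0), 0), ((20, 16, 0), 36), ((1, 2, 3), 6)]
    )
    def test_arithmetic(self, args, expected):
        assert count_strand_repeats(*args) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="alpha_full"):
            count_strand_repeats(-1, 16, 1)
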
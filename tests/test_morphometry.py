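"""Frenet profiles, tortuosity, branch metrics, bending and dominance."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vbmorph import (basilar_bending, branch_metrics, frenet_profiles,
                     tortuosity, tree_morphometry, vertebral_dominance)
from vbmorph.centerline import Branch, VesselTree, resample_branch
from vbmorph.morphometry import BranchMorphometry
from vbmorph.synthetic import arc_through, make_parametric_centerline


def analytic_tree(bend_mm=0.0, side="even"):
    """VesselTree built directly from analytic curves (no voxel pipeline)."""
    top = np.array([0.0, 0.0, 24.0])
    sign = {"left": 1.0, "right": -1.0, "even": 0.0}[side]
    ba = arc_through((0, 0, 0), top, bend_mm if sign else 0.0,
                     (sign if sign else 1.0, 0.0, 0.0))
    va_l = arc_through((9.0, 0, -22.0), (0, 0, 0), 1.0, (1.0, 0, 0))
    va_r = arc_through((-9.0, 0, -22.0), (0, 0, 0), 1.0, (-1.0, 0, 0))
    mk = lambda lbl, c, r: Branch(lbl, c.points, np.full(len(c.points), r))
    return VesselTree(np.zeros(3), top, {
        "va_left": mk("va_left", va_l, 1.7),
        "va_right": mk("va_right", va_r, 1.4),
        "ba": mk("ba", ba, 1.6)})


class TestFrenetProfiles:
    def test_circle_curvature(self):
        c = make_parametric_centerline("planar-arc", radius=10.0, angle=math.pi,
                                       step=0.25)
        kappa, tau = frenet_profiles(c.points)
        interior = slice(3, -3)
        assert np.allclose(kappa[interior], 0.1, atol=0.002)
        assert np.allclose(tau[interior], 0.0, atol=1e-6)

    def test_helix_closed_form(self):
        c = make_parametric_centerline("helix", a=3.0, b=2.0, angle=2 * math.pi,
                                       step=0.25)
        kappa, tau = frenet_profiles(c.points)
        interior = slice(3, -3)
        assert np.allclose(kappa[interior], 3 / 13, rtol=0.01)
        assert np.allclose(tau[interior], 2 / 13, rtol=0.01)

    def test_straight_line_guarded_to_zero(self):
        c = make_parametric_centerline("straight", start=(0, 0, 0), end=(5, 5, 20))
        kappa, tau = frenet_profiles(c.points)
        assert np.allclose(kappa, 0.0, atol=1e-9)
        assert np.allclose(tau, 0.0)  # torsion guard where kappa ~ 0

    def test_nonuniform_sampling_rejected(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10),
                               np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 20.0])])
        with pytest.raises(ValueError, match="uniform"):
            frenet_profiles(pts)


class TestTortuosity:
    def test_straight_zero(self):
        pts = np.column_stack([np.zeros(5), np.zeros(5), np.linspace(0, 10, 5)])
        assert tortuosity(pts) == 0.0

    def test_semicircle(self):
        c = make_parametric_centerline("planar-arc", radius=10.0, angle=math.pi,
                                       step=0.05)
        assert tortuosity(c.points) == pytest.approx(math.pi / 2 - 1, rel=1e-4)

    def test_helix_one_turn_closed_form(self):
        a, b, th = 3.0, 2.0, 2 * math.pi
        c = make_parametric_centerline("helix", a=a, b=b, angle=th, step=0.05)
        expected = (math.hypot(a, b) * th) / (b * th) - 1
        assert tortuosity(c.points) == pytest.approx(expected, rel=1e-3)

    def test_coincident_endpoints_rejected(self):
        c = make_parametric_centerline("planar-arc", radius=5.0,
                                       angle=2 * math.pi - 1e-9, step=0.1)
        with pytest.raises(ValueError):
            tortuosity(np.vstack([c.points, c.points[:1]]))


class TestBranchMetrics:
    def test_cylinder_closed_forms(self, cylinder, cylinder_mask):
        from vbmorph.centerline import radius_profile
        _, axis = cylinder
        pts = resample_branch(axis.points, step=0.25)
        br = Branch("tube", pts, radius_profile(cylinder_mask, pts))
        m = branch_metrics(br, cylinder_mask)
        assert m.length_mm == pytest.approx(40.0, abs=1.0)
        assert m.volume_mm3 == pytest.approx(math.pi * 4 * 40, rel=0.10)
        assert m.mean_cross_section_mm2 == pytest.approx(math.pi * 4, rel=0.10)
        assert m.tortuosity == pytest.approx(0.0, abs=1e-6)

    def test_branch_volumes_partition_mask(self, bent_tree, bent_mask):
        metrics = tree_morphometry(bent_tree, bent_mask)
        total = sum(m.volume_mm3 for m in metrics.values())
        assert total == pytest.approx(bent_mask.volume_mm3, rel=1e-12)

    def test_tapered_tube_area_bounded_by_planted_sections(self):
        import numpy as np
        from vbmorph import SegmentationMask
        from vbmorph.centerline import radius_profile
        x, y, zz = np.indices((25, 25, 65)) * 0.5
        radius_at = 1.2 + zz * 0.06
        cone = (x - 6.0) ** 2 + (y - 6.0) ** 2 <= radius_at ** 2
        mask = SegmentationMask(cone, (0.5,) * 3)
        z = np.linspace(1, 31, 121)
        axis = np.column_stack([np.full_like(z, 6.0), np.full_like(z, 6.0), z])
        br = Branch("cone", axis, radius_profile(mask, axis))
        m = branch_metrics(br, mask)
        lo, hi = math.pi * 1.2 ** 2, math.pi * 3.2 ** 2
        assert lo <= m.mean_cross_section_mm2 <= hi


class TestBasilarBending:
    def test_planted_bow_right(self):
        tree = analytic_tree(3.0, "right")
        bend = basilar_bending(tree)
        assert bend.direction == "right"
        assert bend.deviation_extent_mm == pytest.approx(3.0, abs=0.2)
        assert bend.signed_lateral_mm == pytest.approx(-3.0, abs=0.2)

    def test_straight_ba_even(self):
        bend = basilar_bending(analytic_tree())
        assert bend.direction == "even"
        assert bend.deviation_extent_mm < 0.05

    def test_mirror_flips_direction_preserves_extent(self):
        t_r = analytic_tree(3.0, "right")
        t_l = analytic_tree(3.0, "left")
        b_r, b_l = basilar_bending(t_r), basilar_bending(t_l)
        assert b_l.direction == "left"
        assert b_l.deviation_extent_mm == pytest.approx(b_r.deviation_extent_mm,
                                                        rel=1e-9)
        assert b_l.signed_lateral_mm == pytest.approx(-b_r.signed_lateral_mm,
                                                      rel=1e-9)

    def test_pipeline_recovers_planted_direction(self, bent_tree):
        bend = basilar_bending(bent_tree)
        assert bend.direction == "right"
        assert bend.deviation_extent_mm == pytest.approx(3.0, abs=0.5)


class TestVertebralDominance:
    @pytest.mark.parametrize("dl,dr,side,diff", [
        (3.2, 2.8, "left", 0.4),
        (3.0, 2.9, "even", 0.1),
        (3.0, 3.0, "even", 0.0),
        (2.6, 3.1, "right", -0.5),
        (3.0, 2.7, "left", 0.3),  # boundary: |diff| == threshold is dominant
    ])
    def test_diameter_difference_rule(self, dl, dr, side, diff):
        res = vertebral_dominance(dl, dr)
        assert res.side == side
        assert res.diameter_difference_mm == pytest.approx(diff)

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(ValueError):
            vertebral_dominance(0.0, 3.0)

    def test_accepts_branch_morphometry_objects(self):
        mk = lambda d: BranchMorphometry("va", 30.0, 0.1, 0.1, 0.0, 0.1,
                                         200.0, 8.0, d)
        assert vertebral_dominance(mk(3.4), mk(2.8)).side == "left"


class TestInvariances:
    def _helix_branch(self):
        c = make_parametric_centerline("helix", a=3.0, b=2.0, angle=5.0, step=0.25)
        return c.points

    def test_rigid_translation_invariance(self):
        pts = self._helix_branch()
        k1, t1 = frenet_profiles(pts)
        k2, t2 = frenet_profiles(pts + np.array([13.0, -7.0, 5.0]))
        assert np.allclose(k1, k2) and np.allclose(t1, t2)
        assert tortuosity(pts) == pytest.approx(tortuosity(pts + 11.0))

    @given(st.floats(min_value=0.5, max_value=3.0))
    def test_uniform_scaling_law(self, c):
        pts = self._helix_branch()
        k1, t1 = frenet_profiles(pts)
        k2, t2 = frenet_profiles(pts * c)
        assert np.allclose(k2, k1 / c, rtol=1e-6)
        assert np.allclose(t2, t1 / c, rtol=1e-6, atol=1e-12)
        assert tortuosity(pts * c) == pytest.approx(tortuosity(pts), rel=1e-9)
        arc1 = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        arc2 = np.linalg.norm(np.diff(pts * c, axis=0), axis=1).sum()
        assert arc2 == pytest.approx(c * arc1, rel=1e-12)

    def test_rotation_about_z_preserves_indices(self):
        tree = analytic_tree(3.0, "right")
        th = math.radians(12)
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        rot = VesselTree(tree.confluence @ R.T, tree.basilar_top @ R.T,
                         {l: Branch(l, b.points @ R.T, b.radii)
                          for l, b in tree.branches.items()})
        b1, b2 = basilar_bending(tree), basilar_bending(rot)
        assert b2.deviation_extent_mm == pytest.approx(b1.deviation_extent_mm,
                                                       rel=1e-9)
        k1, _ = frenet_profiles(tree.branches["ba"].points)
        k2, _ = frenet_profiles(rot.branches["ba"].points)
        assert np.allclose(k1, k2, atol=1e-9)

    def test_x_mirror_flips_dominance_and_direction_only(self):
        tree = analytic_tree(3.0, "right")
        M = np.diag([-1.0, 1.0, 1.0])
        mir = VesselTree(tree.confluence @ M, tree.basilar_top @ M, {
            "va_left": Branch("va_left", tree.branches["va_right"].points @ M,
                              tree.branches["va_right"].radii),
            "va_right": Branch("va_right", tree.branches["va_left"].points @ M,
                               tree.branches["va_left"].radii),
            "ba": Branch("ba", tree.branches["ba"].points @ M,
                         tree.branches["ba"].radii)})
        b1, b2 = basilar_bending(tree), basilar_bending(mir)
        assert b1.direction == "right" and b2.direction == "left"
        assert b2.deviation_extent_mm == pytest.approx(b1.deviation_extent_mm)
        d1 = vertebral_dominance(3.4, 2.8)
        d2 = vertebral_dominance(2.8, 3.4)
        assert (d1.side, d2.side) == ("left", "right")
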
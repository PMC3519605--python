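"""Geometry: classification, angles, curvature, extensions, domains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vbsflow.geometry import (
    Centerline,
    ConfluenceGeometry,
    build_class_geometry,
    build_computational_domain,
    classify_configuration,
    confluence_angle,
    curvature_and_wall_orientation,
    extrude_flow_extensions,
    make_tube_geometry,
    reynolds_number,
    rotation_matrix,
    sample_cross_sections,
)
from vbsflow.solver import FluidProperties

FLUID = FluidProperties()

CLASS_GRID = [
    (cls, ang, side)
    for cls in ("Walking", "TuningFork", "Lambda")
    for ang in ((60, 74, 86) if cls != "Lambda" else (48, 52, 60))
    for side in ("LV", "RV")
]


class TestClassifier:
    @pytest.mark.parametrize("cls,ang,side", CLASS_GRID)
    def test_every_generated_class_is_recovered(self, cls, ang, side):
        g = build_class_geometry(cls, angle_deg=ang, dominant_side=side)
        assert classify_configuration(g) == cls

    @pytest.mark.parametrize("cls", ["Walking", "TuningFork", "Lambda"])
    def test_rigid_motion_and_mirror_invariance(self, cls):
        g = build_class_geometry(cls)
        want = classify_configuration(g)
        R = rotation_matrix([0.3, -1.2, 0.8], 1.234)
        M = np.diag([-1.0, 1.0, 1.0])
        t = np.array([0.01, -0.02, 0.005])
        assert classify_configuration(g.transformed(R, t)) == want
        assert classify_configuration(g.transformed(M)) == want
        assert classify_configuration(g.transformed(M @ R)) == want

    def test_resampling_invariance(self):
        g = build_class_geometry("Walking")
        dense = ConfluenceGeometry(
            {b: c.resampled(n=2 * c.n_points) for b, c in g.branches.items()},
            g.apex,
        )
        assert classify_configuration(dense) == "Walking"

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_random_rotations_never_change_the_class(self, seed):
        rng = np.random.default_rng(seed)
        g = build_class_geometry("TuningFork")
        axis = rng.normal(size=3)
        R = rotation_matrix(axis / np.linalg.norm(axis), rng.uniform(0, np.pi))
        assert classify_configuration(g.transformed(R)) == "TuningFork"

    def test_degenerate_centerline_is_an_error(self):
        g = build_class_geometry("TuningFork")
        short = {
            b: Centerline(c.points[-3:], c.radius[-3:])
            for b, c in g.branches.items()
        }
        short["BAS"] = Centerline(g.branches["BAS"].points[:3],
                                  g.branches["BAS"].radius[:3])
        with pytest.raises(ValueError):
            classify_configuration(ConfluenceGeometry(short, g.apex))


class TestConfluenceAngle:
    def test_straight_vertebrals_at_plus_minus_30_degrees(self):
        g = build_class_geometry(
            "TuningFork", angle_deg=60, vertebral_arc_deg=(1e-3, -1e-3)
        )
        assert confluence_angle(g) == pytest.approx(60.0, abs=0.1)

    @pytest.mark.parametrize("cls,ang,side", CLASS_GRID)
    def test_measured_angle_matches_construction_within_2_degrees(
        self, cls, ang, side
    ):
        g = build_class_geometry(cls, angle_deg=ang, dominant_side=side)
        assert confluence_angle(g) == pytest.approx(
            g.construction_angle_deg, abs=2.0
        )

    def test_offset_beyond_branch_length_is_an_error(self):
        g = build_class_geometry("TuningFork")
        with pytest.raises(ValueError):
            confluence_angle(g, n_diameters=50)


class TestCurvature:
    def test_circular_arc_curvature_is_inverse_radius(self):
        """20 mm bend radius -> 50 1/m along the arc interior."""
        length, r_bas = 22e-3, 1.62e-3
        head = 2 * r_bas  # straight proximal run carries no curvature
        arc_deg = np.degrees(50.0 * (length - head))
        g = build_class_geometry("TuningFork", basilar_arc_deg=arc_deg,
                                 basilar_length=length)
        s, k, outer, flat = curvature_and_wall_orientation(g, "BAS")
        interior = (s > head + 3e-3) & (s < length - 2e-3)
        assert np.median(k[interior]) == pytest.approx(50.0, rel=0.05)

    def test_straight_tube_is_flagged_flat_everywhere(self):
        g = make_tube_geometry()
        s, k, outer, flat = curvature_and_wall_orientation(g, "BAS")
        assert flat.all()

    def test_planar_s_curve_outer_wall_flips_at_inflection(self):
        # x(z) = A sin(2 pi z / L): curvature changes sign at z = L/2
        L, A = 24e-3, 3e-3
        z = np.linspace(0, L, 160)
        pts = np.stack([A * np.sin(2 * np.pi * z / L), np.zeros_like(z), z], 1)
        geom = ConfluenceGeometry(
            {"LV": Centerline(np.array([pts[0] - [0, 0, 5e-3], pts[0]]), 1.5e-3),
             "BAS": Centerline(pts, 1.5e-3)},
            apex=pts[0],
        )
        s, k, outer, flat = curvature_and_wall_orientation(geom, "BAS")
        sx = outer[~flat][:, 0]
        n = len(sx)
        assert np.sign(np.median(sx[: n // 3])) != np.sign(
            np.median(sx[-n // 3:])
        )


class TestFlowExtensions:
    def test_laminar_development_length_closed_form(self):
        """Q = 3 ml/s, D = 3 mm: Re ~ 364, inlet extension ~ 0.0655 m."""
        g = build_class_geometry(
            "TuningFork", radii={"LV": 1.5e-3, "RV": 1.5e-3, "BAS": 1.5e-3}
        )
        assert reynolds_number(3e-6, 3e-3, FLUID) == pytest.approx(364.3, rel=1e-3)
        ext = extrude_flow_extensions(g, {"LV": 3e-6, "RV": 3e-6}, FLUID)
        assert ext.extension_lengths["LV"] == pytest.approx(0.0656, abs=5e-4)

    def test_zero_flow_extension_hits_three_diameter_floor(self):
        g = build_class_geometry(
            "TuningFork", radii={"LV": 1.5e-3, "RV": 1.5e-3, "BAS": 1.5e-3}
        )
        ext = extrude_flow_extensions(g, {"LV": 0.0, "RV": 0.0}, FLUID)
        assert ext.extension_lengths["LV"] == pytest.approx(3 * 3e-3)

    def test_extension_length_is_linear_in_flow(self):
        g = build_class_geometry(
            "TuningFork", radii={"LV": 1.5e-3, "RV": 1.5e-3, "BAS": 1.5e-3}
        )
        e1 = extrude_flow_extensions(g, {"LV": 3e-6, "RV": 3e-6}, FLUID)
        e2 = extrude_flow_extensions(g, {"LV": 6e-6, "RV": 6e-6}, FLUID)
        assert e2.extension_lengths["LV"] == pytest.approx(
            2 * e1.extension_lengths["LV"], rel=1e-9
        )

    def test_profile_policy_uses_the_floor_only(self):
        g = build_class_geometry(
            "TuningFork", radii={"LV": 1.5e-3, "RV": 1.5e-3, "BAS": 1.5e-3}
        )
        ext = extrude_flow_extensions(g, {"LV": 3e-6, "RV": 3e-6}, FLUID,
                                      policy="profile")
        assert ext.extension_lengths["LV"] == pytest.approx(3 * 3e-3)


class TestComputationalDomain:
    def test_signed_distance_at_tube_centerline_equals_radius(self):
        R = 1.5e-3
        g = make_tube_geometry(radius=R, length=12e-3)
        dom = build_computational_domain(g, 2 * R / 10)
        phi = g.signed_distance(np.array([[0.0, 0.0, 0.0]]))
        assert phi[0] == pytest.approx(-R, abs=dom.h)

    def test_lumen_volume_matches_analytic_tube_volume(self):
        R = 1.5e-3
        g = make_tube_geometry(radius=R, length=12e-3)
        dom = build_computational_domain(g, 2 * R / 10)
        # tube volume plus the hemispherical cap the distance field closes
        # the inlet end with (the outlet end is clipped by the grid top)
        exact = np.pi * R**2 * 12e-3 + 2.0 / 3.0 * np.pi * R**3
        assert dom.lumen_volume() == pytest.approx(exact, rel=0.05)

    def test_volume_error_shrinks_with_refinement(self):
        R = 1.5e-3
        g = make_tube_geometry(radius=R, length=12e-3)
        exact = np.pi * R**2 * 12e-3
        errs = [
            abs(build_computational_domain(g, 2 * R / n).lumen_volume() - exact)
            / exact
            for n in (6, 12, 24)
        ]
        assert errs[2] < errs[0]

    def test_wall_sample_normals_are_unit_and_outward(self):
        g = make_tube_geometry(radius=1.5e-3, length=12e-3)
        dom = build_computational_domain(g, 3e-4)
        nrm = dom.wall_normals[dom.wall_valid]
        assert np.allclose(np.linalg.norm(nrm, axis=1), 1.0, atol=1e-6)
        pos = dom.wall_verts[dom.wall_valid]
        radial = pos[:, :2] / np.linalg.norm(pos[:, :2], axis=1, keepdims=True)
        assert np.mean(np.einsum("ij,ij->i", nrm[:, :2], radial)) > 0.9

    def test_under_resolved_grid_is_an_error_naming_the_spacing(self):
        g = make_tube_geometry(radius=1.5e-3, length=12e-3)
        with pytest.raises(ValueError, match="spacing"):
            build_computational_domain(g, 1e-3)


class TestCrossSections:
    def test_straight_tube_section_area(self):
        R = 1.5e-3
        g = make_tube_geometry(radius=R, length=12e-3)
        cs = sample_cross_sections(g, "BAS", [3e-3])[0]
        assert cs.area == pytest.approx(np.pi * R**2, rel=0.03)

    def test_section_at_apex_spans_both_vertebral_lumina(self):
        g = build_class_geometry("TuningFork")
        cs = sample_cross_sections(g, "BAS", [0.0], half_width_factor=3.0)[0]
        # wider than one vessel: the merged footprint exceeds one circle
        r_bas = g.branches["BAS"].radius[0]
        assert cs.area > 1.1 * np.pi * r_bas**2

    def test_station_out_of_range_is_an_error(self):
        g = make_tube_geometry()
        with pytest.raises(ValueError):
            sample_cross_sections(g, "BAS", [1.0])

    def test_plane_normal_equals_centerline_tangent(self):
        g = build_class_geometry("Walking")
        c = g.branches["BAS"]
        cs = sample_cross_sections(g, "BAS", [0.5 * c.length])[0]
        assert np.allclose(cs.normal, c.tangent_at(0.5 * c.length), atol=1e-9)


class TestTubeBuilders:
    def test_self_intersection_detected(self):
        with pytest.raises(ValueError, match="self-intersect"):
            build_class_geometry(
                "TuningFork", angle_deg=4.0,
                radii={"LV": 1.7e-3, "RV": 1.7e-3, "BAS": 1.6e-3},
                vertebral_arc_deg=(0.5, -0.5),
            )
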
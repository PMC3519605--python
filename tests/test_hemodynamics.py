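"""Wall-shear metrics, profiles, pathlines, mixing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vbsflow.geometry import sample_cross_sections
from vbsflow.hemodynamics import (
    WallShearSeries,
    hemodynamic_maps,
    low_wss_regions,
    oscillatory_shear_index,
    time_averaged_wss,
    trace_pathlines,
    velocity_profile_metrics,
    wall_shear_stress_series,
    wall_shear_vector,
)
from vbsflow.solver import FlowField


def _series(tau, period=1.0, n_samples=None):
    tau = np.asarray(tau, dtype=float)
    n_t, n_s = tau.shape[:2]
    t = np.arange(n_t) / n_t * period
    return WallShearSeries(
        positions=np.zeros((n_s, 3)),
        normals=np.tile([0.0, 0.0, 1.0], (n_s, 1)),
        times=t,
        tau=tau,
        valid=np.ones(n_s, bool),
        period=period,
    )


class TestShearIdentities:
    def test_constant_shear_time_average(self):
        tau = np.zeros((100, 1, 3))
        tau[:, 0, 0] = 2.0
        assert time_averaged_wss(_series(tau))[0] == pytest.approx(2.0)

    def test_rectified_sine_averages_to_two_over_pi(self):
        t = np.arange(500) / 500.0
        tau = np.zeros((500, 1, 3))
        tau[:, 0, 0] = np.sin(2 * np.pi * t)
        assert time_averaged_wss(_series(tau))[0] == pytest.approx(
            2 / np.pi, rel=1e-3
        )

    def test_unidirectional_shear_has_zero_osi(self):
        t = np.arange(200) / 200.0
        tau = np.zeros((200, 1, 3))
        tau[:, 0, 1] = 1.0 + 0.5 * np.sin(2 * np.pi * t)
        assert oscillatory_shear_index(_series(tau))[0] == pytest.approx(0.0,
                                                                         abs=1e-12)

    def test_zero_mean_oscillation_has_maximal_osi(self):
        t = np.arange(500) / 500.0
        tau = np.zeros((500, 1, 3))
        tau[:, 0, 0] = np.sin(2 * np.pi * t)
        assert oscillatory_shear_index(_series(tau))[0] == pytest.approx(0.5,
                                                                         abs=1e-6)

    def test_half_cycle_reversal_gives_one_third(self):
        """+2 Pa then -1 Pa along a fixed direction: OSI = 1/2(1-0.5/1.5)."""
        tau = np.zeros((500, 1, 3))
        tau[:250, 0, 0] = 2.0
        tau[250:, 0, 0] = -1.0
        assert oscillatory_shear_index(_series(tau))[0] == pytest.approx(
            1.0 / 3.0, abs=1e-9
        )

    def test_zero_shear_maps_to_zero_osi(self):
        tau = np.zeros((10, 2, 3))
        assert np.allclose(oscillatory_shear_index(_series(tau)), 0.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 100_000))
    def test_osi_always_within_half_interval(self, seed):
        rng = np.random.default_rng(seed)
        tau = rng.normal(size=(40, 5, 3)) * rng.uniform(0.1, 5)
        osi = oscillatory_shear_index(_series(tau))
        assert np.all(osi >= 0.0) and np.all(osi <= 0.5)

    def test_steady_field_has_zero_osi_and_tawss_equals_magnitude(
        self, poiseuille_solution, fluid
    ):
        dom = poiseuille_solution["domain"]
        f = poiseuille_solution["field"]
        series = wall_shear_stress_series([f] * 5, dom, fluid)
        maps = hemodynamic_maps(series)
        tau0, _ = wall_shear_vector(f, dom.wall_verts, dom.wall_normals,
                                    fluid.viscosity)
        assert np.allclose(maps.osi, 0.0, atol=1e-12)
        assert np.allclose(maps.tawss, np.linalg.norm(tau0, axis=1), atol=1e-12)

    def test_wss_is_tangential_to_the_wall(self, poiseuille_solution, fluid):
        dom = poiseuille_solution["domain"]
        tau, ok = wall_shear_vector(
            poiseuille_solution["field"], dom.wall_verts, dom.wall_normals,
            fluid.viscosity,
        )
        mag = np.linalg.norm(tau, axis=1)
        sel = ok & (mag > 0)
        dot = np.abs(np.einsum("ij,ij->i", tau[sel], dom.wall_normals[sel]))
        assert np.all(dot <= 1e-10 * mag[sel])

    def test_zero_flow_gives_zero_shear(self, poiseuille_solution, fluid):
        dom = poiseuille_solution["domain"]
        f = poiseuille_solution["field"]
        zero = FlowField(np.zeros_like(f.u), np.zeros_like(f.v),
                         np.zeros_like(f.w), np.zeros_like(f.p), 0.0, dom)
        tau, ok = wall_shear_vector(zero, dom.wall_verts, dom.wall_normals,
                                    fluid.viscosity)
        assert np.allclose(tau, 0.0)


class TestLowWssRegions:
    def test_uniformly_high_tawss_has_no_regions(self, poiseuille_solution):
        dom = poiseuille_solution["domain"]
        tawss = np.full(dom.wall_verts.shape[0], 2.0)
        assert low_wss_regions(tawss, dom, 1.0) == []

    def test_uniformly_low_tawss_covers_the_surface(self, poiseuille_solution):
        dom = poiseuille_solution["domain"]
        tawss = np.full(dom.wall_verts.shape[0], 0.5)
        regions = low_wss_regions(tawss, dom, 1.0, valid=dom.wall_valid)
        total = sum(r.area for r in regions)
        assert len(regions) >= 1
        assert total == pytest.approx(
            dom.wall_sample_areas()[dom.wall_valid].sum(), rel=0.05
        )


class TestProfileMetrics:
    def test_poiseuille_slice_has_one_central_peak(self, poiseuille_solution):
        dom = poiseuille_solution["domain"]
        f = poiseuille_solution["field"]
        bas = dom.geometry.branches["BAS"]
        cs = sample_cross_sections(dom.geometry, "BAS", [0.5 * bas.length])
        m = velocity_profile_metrics(f, cs)[0]
        assert m.peak_count == 1
        assert m.skew_index is None  # straight tube: no outer wall defined

    def test_all_zero_slice_flags_no_peaks(self, poiseuille_solution):
        dom = poiseuille_solution["domain"]
        f = poiseuille_solution["field"]
        zero = FlowField(np.zeros_like(f.u), np.zeros_like(f.v),
                         np.zeros_like(f.w), np.zeros_like(f.p), 0.0, dom)
        bas = dom.geometry.branches["BAS"]
        cs = sample_cross_sections(dom.geometry, "BAS", [0.5 * bas.length])
        m = velocity_profile_metrics(zero, cs)[0]
        assert m.peak_count == 0 and m.skew_index is None


class TestGridIndependenceProtocol:
    def test_identical_spacing_twice_gives_zero_differences(self, fluid):
        """Same grid solved twice: the protocol must report zero change."""
        from vbsflow.geometry import extrude_flow_extensions
        from vbsflow.hemodynamics import grid_independence_study
        from vbsflow.geometry import make_tube_geometry

        g = make_tube_geometry(radius=1.5e-3, length=8e-3)
        ext = extrude_flow_extensions(g, {"LV": 2e-6}, fluid, policy="profile")
        res = grid_independence_study(ext, {"LV": 2e-6}, fluid,
                                      base_spacing=2 * 1.5e-3 / 7,
                                      refinement=1.0, n_stations=4)
        assert res["peak_velocity_diff_pct"] == pytest.approx(0.0, abs=1e-10)
        assert res["wss_diff_pct"] == pytest.approx(0.0, abs=1e-10)


class TestPathlines:
    def test_zero_velocity_pathlines_stay_at_their_seeds(self, poiseuille_solution):
        dom = poiseuille_solution["domain"]
        f = poiseuille_solution["field"]
        zero = FlowField(np.zeros_like(f.u), np.zeros_like(f.v),
                         np.zeros_like(f.w), np.zeros_like(f.p), 0.0, dom)
        mx = trace_pathlines(zero, n_seeds_per_inlet=5, seed=1)
        for _, path in mx.pathlines:
            assert path.shape[0] == 1

    def test_origin_fractions_sum_to_one_per_half(self, symmetric_merge_control):
        mx = trace_pathlines(symmetric_merge_control["field"],
                             n_seeds_per_inlet=16, seed=2)
        for fr in mx.origin_fractions.values():
            for half, d in fr.items():
                if d:
                    assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)

    def test_helicity_sign_follows_rotation_and_flips_under_mirror(
        self, poiseuille_solution
    ):
        """Solid-body rotation + axial flow: helicity sign = rotation sign."""
        dom = poiseuille_solution["domain"]
        f = poiseuille_solution["field"]
        omega = 50.0  # rad/s
        yc = dom.origin[1] + (np.arange(dom.shape[1]) + 0.5)[None, :, None] * dom.h
        xc = dom.origin[0] + (np.arange(dom.shape[0]) + 0.5)[:, None, None] * dom.h
        swirl = FlowField(
            u=np.broadcast_to(-omega * yc, f.u.shape).copy(),
            v=np.broadcast_to(omega * xc, f.v.shape).copy(),
            w=np.full_like(f.w, 0.2),
            p=np.zeros_like(f.p),
            time=0.0,
            domain=dom,
        )
        from vbsflow.hemodynamics import helicity_index

        bas = dom.geometry.branches["BAS"]
        h_pos = helicity_index(swirl, [0.5 * bas.length])[0]
        # the mirror image of this field is the opposite-handed swirl
        mirrored = FlowField(
            u=np.broadcast_to(omega * yc, f.u.shape).copy(),
            v=np.broadcast_to(-omega * xc, f.v.shape).copy(),
            w=swirl.w.copy(), p=swirl.p.copy(), time=0.0, domain=dom,
        )
        h_neg = helicity_index(mirrored, [0.5 * bas.length])[0]
        assert h_pos > 0.1
        assert h_neg == pytest.approx(-h_pos, rel=1e-9)
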
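"""Flow solver: inlet contracts, analytic validation, conservation."""

import numpy as np
import pytest

from vbsflow.geometry import (
    build_computational_domain,
    make_tube_geometry,
    rotation_matrix,
    sample_cross_sections,
)
from vbsflow.hemodynamics import fit_axis_velocity, wall_shear_vector
from vbsflow.solver import (
    FluidProperties,
    MaskedGridSolver,
    SolverConfig,
    check_cycle_convergence,
    CycleDiagnostics,
    inlet_velocity_bc,
    mass_balance,
    solve_pulsatile,
    solve_steady,
)
from vbsflow.waveforms import FlowWaveform

from conftest import TUBE_FLOW, TUBE_RADIUS


def _const_waveform(q_m3s, period=1.0, label=None):
    t = np.arange(500) / 500.0 * period
    return FlowWaveform(t, np.full(500, q_m3s * 1e6), period, label=label)


class TestSolverConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(steps_per_cycle=10)
        with pytest.raises(ValueError):
            SolverConfig(n_cycles=0)
        with pytest.raises(ValueError):
            SolverConfig(inlet_profile_kind="flat")
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0)


class TestInletBoundary:
    def test_grid_summed_flux_equals_requested_flow_exactly(self, fluid):
        g = make_tube_geometry(radius=TUBE_RADIUS, length=12e-3)
        dom = build_computational_domain(g, 2 * TUBE_RADIUS / 10)
        for q in (3e-6, 0.7e-6):
            zone, vel = inlet_velocity_bc(dom, "LV", q, fluid=fluid)
            assert zone.measured_flux(vel) == pytest.approx(q, rel=1e-12)

    def test_zero_flow_gives_zero_velocity(self, fluid):
        g = make_tube_geometry(radius=TUBE_RADIUS, length=12e-3)
        dom = build_computational_domain(g, 2 * TUBE_RADIUS / 10)
        zone, vel = inlet_velocity_bc(dom, "LV", 0.0, fluid=fluid)
        assert all(np.allclose(v, 0.0) for v in vel)

    def test_poiseuille_profile_peak_to_mean_ratio(self, fluid):
        """Fine grid: max/mean of the sampled parabola -> 2 within 2%."""
        g = make_tube_geometry(radius=TUBE_RADIUS, length=12e-3)
        dom = build_computational_domain(g, 2 * TUBE_RADIUS / 20)
        zone, vel = inlet_velocity_bc(dom, "LV", 3e-6, fluid=fluid)
        sel = zone.faces[2][0]
        k_disc = sel[2].max()  # one full disc of faces at the zone end
        on_disc = sel[2] == k_disc
        wvals = vel[2][sel[0][on_disc], sel[1][on_disc], sel[2][on_disc]]
        wvals = wvals[np.abs(wvals) > 0]
        ratio = np.abs(wvals).max() / np.abs(wvals).mean()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_under_resolved_inlet_is_an_error(self, fluid):
        g = make_tube_geometry(radius=TUBE_RADIUS, length=12e-3)
        dom = build_computational_domain(g, 2 * TUBE_RADIUS / 4.5,
                                         min_cells_per_diameter=4)
        with pytest.raises(ValueError, match="under-resolved"):
            inlet_velocity_bc(dom, "LV", 1e-6, fluid=fluid)


class TestSteadyPoiseuille:
    def test_centerline_velocity_within_5_percent(self, poiseuille_solution):
        dom = poiseuille_solution["domain"]
        field = poiseuille_solution["field"]
        R, Q = poiseuille_solution["radius"], poiseuille_solution["flow"]
        cs = sample_cross_sections(
            dom.geometry, "BAS", [0.5 * dom.geometry.branches["BAS"].length]
        )[0]
        u0 = 2 * Q / (np.pi * R**2)
        assert fit_axis_velocity(field, cs) == pytest.approx(u0, rel=0.05)

    def test_wall_shear_within_10_percent(self, poiseuille_solution, fluid):
        dom = poiseuille_solution["domain"]
        field = poiseuille_solution["field"]
        R, Q = poiseuille_solution["radius"], poiseuille_solution["flow"]
        pos = dom.wall_verts[dom.wall_valid]
        nrm = dom.wall_normals[dom.wall_valid]
        tau, ok = wall_shear_vector(field, pos, nrm, fluid.viscosity)
        wss = np.median(np.linalg.norm(tau, axis=1)[ok])
        assert wss == pytest.approx(4 * fluid.viscosity * Q / (np.pi * R**3),
                                    rel=0.10)

    def test_mass_balance_of_converged_field(self, poiseuille_solution):
        imb = mass_balance(poiseuille_solution["field"],
                           poiseuille_solution["domain"])
        assert abs(imb) <= 1e-6

    def test_spatial_convergence_is_monotone(self, fluid):
        """Axis-velocity error shrinks across 6, 10, 14 cells/diameter."""
        R, Q = TUBE_RADIUS, TUBE_FLOW
        u0 = 2 * Q / (np.pi * R**2)
        errs = []
        for ncd in (6, 10, 14):
            g = make_tube_geometry(radius=R, length=12e-3)
            dom = build_computational_domain(g, 2 * R / ncd)
            f = solve_steady(dom, {"LV": Q}, fluid)
            itp = f.interpolator(method="cubic")
            u = float(itp(np.array([[0.0, 0.0, 0.0]]))[0][2])
            errs.append(abs(u - u0) / u0)
        assert errs[0] > errs[1] > errs[2]

    def test_two_inlet_flows_sum_at_the_outlet(self, symmetric_merge_control):
        """Conservation: 2 + 2 ml/s in -> 4 ml/s out."""
        imb = mass_balance(symmetric_merge_control["field"],
                           symmetric_merge_control["domain"])
        assert abs(imb) <= 1e-6

    def test_energy_is_bounded(self, poiseuille_solution, fluid):
        ke = poiseuille_solution["field"].kinetic_energy(fluid.density)
        # bounded by rho * volume * u_center^2 (loose physical bound)
        dom = poiseuille_solution["domain"]
        u0 = 2 * TUBE_FLOW / (np.pi * TUBE_RADIUS**2)
        assert 0 < ke < fluid.density * dom.lumen_volume() * u0**2


class TestPulsatile:
    def test_single_harmonic_matches_womersley_amplitude_and_phase(
        self, womersley_run, fluid
    ):
        """alpha ~ 2 oscillatory tube flow vs the analytic solution."""
        from vbsflow.womersley import flow_harmonics, womersley_profile

        wr = womersley_run
        T = wr["period"]
        ts, ws = wr["probe_t"], wr["probe_w"]
        c1 = 2 * np.sum(ws * np.exp(-2j * np.pi * ts / T)) / len(ws)
        ana = womersley_profile(
            wr["radius"], flow_harmonics(wr["flow_ml_s"] * 1e-6, 2), fluid, T
        )
        a_t = ana.velocity(0.0, wr["times_dense"])
        a1 = 2 * np.sum(
            a_t * np.exp(-2j * np.pi * wr["times_dense"] / T)
        ) / len(a_t)
        assert abs(c1) == pytest.approx(abs(a1), rel=0.05)
        assert np.degrees(abs(np.angle(c1) - np.angle(a1))) < 5.0
        # converged periodic state
        ok, metric = check_cycle_convergence(wr["diagnostics"], 1e-3)
        assert ok

    def test_constant_waveform_reproduces_the_steady_solution(self, fluid):
        R, Q = TUBE_RADIUS, 2.0e-6
        g = make_tube_geometry(radius=R, length=8e-3)
        dom = build_computational_domain(g, 2 * R / 8)
        steady = solve_steady(dom, {"LV": Q}, fluid)
        cfg = SolverConfig(steps_per_cycle=50, n_cycles=1, field_stride=25,
                           inlet_profile_kind="poiseuille")
        fields, diag = solve_pulsatile(dom, {"LV": _const_waveform(Q)}, fluid, cfg)
        final = fields[-1]
        ref = np.abs(steady.w).max()
        assert np.abs(final.w - steady.w).max() / ref < 5e-3
        assert np.max(np.abs(diag.mass_imbalance)) < 1e-9

    def test_cycle_convergence_checker(self):
        d = CycleDiagnostics(inter_cycle_difference=[1e-2, 1e-5])
        ok, metric = check_cycle_convergence(d)
        assert ok and metric == 1e-5
        bad = CycleDiagnostics(inter_cycle_difference=[1e-2, 5e-1])
        assert not check_cycle_convergence(bad)[0]
        with pytest.raises(ValueError):
            check_cycle_convergence(CycleDiagnostics())


class TestGalileanSanity:
    def test_rotated_domain_gives_rotated_solution(self, fluid):
        """Solve in a tilted frame; velocities agree after back-rotation."""
        R, Q = TUBE_RADIUS, 2.5e-6
        g0 = make_tube_geometry(radius=R, length=9e-3)
        dom0 = build_computational_domain(g0, 2 * R / 8)
        f0 = solve_steady(dom0, {"LV": Q}, fluid)
        Rm = rotation_matrix([1.0, 0.4, 0.2], 0.7)
        g1 = make_tube_geometry(radius=R, length=9e-3,
                                direction=Rm @ np.array([0.0, 0.0, 1.0]))
        dom1 = build_computational_domain(g1, 2 * R / 8)
        f1 = solve_steady(dom1, {"LV": Q}, fluid)
        # the domain builder rotates the outlet back to +z, so the two
        # solutions live in the same canonical frame
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2e-3], [0.5e-3, 0.0, 0.0]])
        v0 = f0.interpolator(method="cubic")(pts)
        v1 = f1.interpolator(method="cubic")(pts)
        u_ref = 2 * Q / (np.pi * R**2)
        assert np.abs(v0 - v1).max() / u_ref < 0.05
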
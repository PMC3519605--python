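"""Shared fixtures: expensive flow solutions are solved once per session."""

import warnings

import numpy as np
import pytest

from vbsflow.fixtures import (
    generate_confluence_geometry,
    generate_vertebral_waveforms,
    make_subject_fixture,
)
from vbsflow.geometry import (
    build_class_geometry,
    build_computational_domain,
    extrude_flow_extensions,
    make_tube_geometry,
)
from vbsflow.hemodynamics import WallShearRecorder
from vbsflow.solver import (
    FluidProperties,
    MaskedGridSolver,
    SolverConfig,
    solve_steady,
)

warnings.filterwarnings("ignore", category=FutureWarning)

TUBE_RADIUS = 1.5e-3
TUBE_FLOW = 3e-6  # m^3/s


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def poiseuille_solution(fluid):
    """Steady flow in a straight tube at 10 cells/diameter."""
    geom = make_tube_geometry(radius=TUBE_RADIUS, length=12e-3)
    domain = build_computational_domain(geom, 2 * TUBE_RADIUS / 10)
    field = solve_steady(domain, {"LV": TUBE_FLOW}, fluid)
    return {
        "domain": domain,
        "field": field,
        "radius": TUBE_RADIUS,
        "flow": TUBE_FLOW,
    }


def run_subject_fixture(subject: str, n_cycles: int, fluid,
                        cells_per_diameter: int = 6,
                        steps_per_cycle: int = 100):
    """Coarse pulsatile run of one subject fixture with WSS recording."""
    fx = make_subject_fixture(subject)
    lv, rv = generate_vertebral_waveforms(fx)
    geom = generate_confluence_geometry(fx)
    i = int(np.argmax(lv.values + rv.values))
    peak = {"LV": lv.values[i] * 1e-6, "RV": rv.values[i] * 1e-6}
    ext = extrude_flow_extensions(geom, peak, fluid, policy="profile")
    rmin = min(float(c.radius.min()) for c in ext.branches.values())
    domain = build_computational_domain(ext, 2 * rmin / cells_per_diameter)
    cfg = SolverConfig(
        steps_per_cycle=steps_per_cycle, n_cycles=n_cycles, field_stride=10
    )
    solver = MaskedGridSolver(domain, fluid, cfg)
    rec = WallShearRecorder(domain, fluid.viscosity)
    fields, diag = solver.run_pulsatile({"LV": lv, "RV": rv}, on_output_step=rec)
    return {
        "fixture": fx,
        "waveforms": {"LV": lv, "RV": rv},
        "domain": domain,
        "fields": fields,
        "diagnostics": diag,
        "wss_series": rec.series(period=fx.cycle_period),
    }


@pytest.fixture(scope="session")
def womersley_run(fluid):
    """Oscillatory tube flow at alpha ~ 2 vs the analytic solution."""
    from vbsflow.solver import solve_pulsatile
    from vbsflow.waveforms import FlowWaveform

    R = TUBE_RADIUS
    T = R**2 * 2 * np.pi * fluid.density / (fluid.viscosity * 4.0)  # alpha = 2
    t500 = np.arange(500) / 500.0 * T
    q = (2.0e-6 + 1.0e-6 * np.cos(2 * np.pi * t500 / T)) * 1e6  # ml/s
    wf = FlowWaveform(t500, q, T, label="LV")
    geom = make_tube_geometry(radius=R, length=8e-3)
    domain = build_computational_domain(geom, 2 * R / 10)
    cfg = SolverConfig(steps_per_cycle=100, n_cycles=2, n_harmonics=2)
    probes = []

    def rec(f, step):
        itp = f.interpolator(method="cubic")
        probes.append((f.time, float(itp(np.array([[0.0, 0.0, 0.0]]))[0][2])))

    fields, diag = solve_pulsatile(domain, {"LV": wf}, fluid, cfg,
                                   on_output_step=rec)
    return {
        "radius": R, "period": T, "flow_ml_s": q, "times_dense": t500,
        "probe_t": np.array([p[0] for p in probes]),
        "probe_w": np.array([p[1] for p in probes]),
        "diagnostics": diag,
    }


@pytest.fixture(scope="session")
def fixture_c_run(fluid):
    """Three-cycle pulsatile solution of the subject-C fixture (coarse)."""
    return run_subject_fixture("C", n_cycles=3, fluid=fluid)


@pytest.fixture(scope="session")
def symmetric_merge_control(fluid):
    """Steady symmetric confluence with equal inflows and straight basilar."""
    geom = build_class_geometry(
        "TuningFork",
        radii={"LV": 1.5e-3, "RV": 1.5e-3, "BAS": 1.6e-3},
        basilar_arc_deg=0.5,
    )
    flows = {"LV": 2.0e-6, "RV": 2.0e-6}
    ext = extrude_flow_extensions(geom, flows, fluid, policy="profile")
    domain = build_computational_domain(ext, 2 * 1.5e-3 / 8)
    field = solve_steady(domain, flows, fluid)
    return {"domain": domain, "field": field, "flows": flows}
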
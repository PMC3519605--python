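"""Case orchestration: fixture -> flow quantification -> simulation -> metrics.

A *case* is one subject fixture (or an externally supplied geometry) pushed
through the whole analysis in stage order, with every stage persisting its
outputs in the case directory so a run can resume after any stage.  Reports
are plain JSON; re-running an identical configuration and seed reproduces
the same content hash (wall-clock timings are excluded from the hash).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .fixtures import (
    PCMRImagingSpec,
    SubjectFixture,
    generate_confluence_geometry,
    generate_pcmr_series,
    generate_vertebral_waveforms,
    make_subject_fixture,
    write_fixture_bundle,
)
from .geometry import build_computational_domain, confluence_angle, extrude_flow_extensions
from .hemodynamics import (
    WallShearRecorder,
    hemodynamic_maps,
    low_wss_regions,
    trace_pathlines,
    velocity_profile_metrics,
)
from .io import (
    read_waveform_csv,
    write_json,
    write_vtk_polydata,
    write_waveform_csv,
)
from .solver import (
    FluidProperties,
    MaskedGridSolver,
    SolverConfig,
    check_cycle_convergence,
)
from .waveforms import (
    compute_flow_samples,
    detect_cycle_features,
    flow_ratio_summary,
    resample_waveform,
    segment_lumen,
)

STAGES = ("generate", "flow", "simulate", "metrics")


class ConfigError(ValueError):
    """Invalid or inconsistent case configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CaseConfig:
    """Full configuration of one case run (YAML-serialisable).

    Every field has a default and is echoed into the report, so a report
    never depends on silent parameters.
    """

    subject: str = "C"
    output_dir: str = "case_out"
    seed: int = 0
    geometry_path: Optional[str] = None
    # imaging
    noise_sd: Optional[float] = 0.0  # m/s; None -> 2% of VENC
    # solver
    mode: str = "pulsatile"  # 'steady' solves only at peak systole
    cells_per_diameter: int = 6
    steps_per_cycle: int = 100
    n_cycles: int = 2
    inlet_profile_kind: str = "womersley"
    entrance_policy: str = "profile"
    # metrics
    pathlines: bool = True
    n_stations: int = 5
    low_wss_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("steady", "pulsatile"):
            raise ConfigError(f"mode must be steady or pulsatile, got {self.mode!r}")
        if self.entrance_policy not in ("developed", "profile"):
            raise ConfigError("entrance_policy must be 'developed' or 'profile'")
        if self.geometry_path is not None and not Path(self.geometry_path).exists():
            raise ConfigError(f"geometry file not found: {self.geometry_path}")

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        import yaml

        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def content_hash(report: dict) -> str:
    """Hash of the scientific content of a report (timings excluded)."""

    # timings and filesystem paths are provenance, not content
    skip = ("seconds", "timings", "content_hash", "output_dir", "config_hash")

    def strip(obj):
        if isinstance(obj, dict):
            return {
                k: strip(v) for k, v in sorted(obj.items()) if k not in skip
            }
        if isinstance(obj, list):
            return [strip(x) for x in obj]
        if isinstance(obj, float):
            return float(f"{obj:.12e}")
        return obj

    return hashlib.sha256(
        json.dumps(strip(report), sort_keys=True).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

class CaseState:
    """In-memory carrier of stage products within one run_case call."""

    def __init__(self, config: CaseConfig):
        self.config = config
        self.dir = Path(config.output_dir)
        self.fixture: Optional[SubjectFixture] = None
        self.geometry = None
        self.series = None
        self.waveforms = None
        self.ratio_summary = None
        self.features = None
        self.fields = None
        self.domain = None
        self.diagnostics = None
        self.wss_series = None
        self.report = {"stages": {}}


def _fixture_from_config(cfg: CaseConfig) -> SubjectFixture:
    imaging_kw = {}
    if cfg.noise_sd is not None:
        imaging_kw["noise_sd"] = cfg.noise_sd
    fx = make_subject_fixture(cfg.subject, seed=cfg.seed)
    if imaging_kw:
        fx = make_subject_fixture(
            cfg.subject, seed=cfg.seed,
            imaging=PCMRImagingSpec(
                n_phases=fx.imaging.n_phases, **imaging_kw
            ),
        )
    return fx


def stage_generate(state: CaseState) -> None:
    cfg = state.config
    state.dir.mkdir(parents=True, exist_ok=True)
    fx = _fixture_from_config(cfg)
    lv, rv = generate_vertebral_waveforms(fx)
    geometry = generate_confluence_geometry(fx)
    rng = np.random.SeedSequence(cfg.seed)
    seeds = rng.generate_state(2)
    series = {}
    for wf, s in zip((lv, rv), seeds):
        series[wf.label] = generate_pcmr_series(
            wf, fx.vessel_radii[wf.label], fx.imaging, seed=int(s % (2**31)),
        )
    manifest = write_fixture_bundle(
        fx, geometry, series, state.dir / "fixture",
        waveforms={"LV": lv, "RV": rv},
    )
    state.fixture = fx
    state.geometry = geometry
    state.series = series
    state.report["geometry"] = {
        "class": geometry.geometry_class,
        "confluence_angle_deg": confluence_angle(geometry),
        "dominant_side": fx.dominant_side,
    }
    state.report["manifest"] = {
        "subject_id": manifest["subject_id"],
        "geometry_class": manifest["geometry_class"],
    }


def stage_flow(state: CaseState) -> None:
    cfg = state.config
    fx = state.fixture or _fixture_from_config(cfg)
    state.fixture = fx
    wfs = {}
    for label in ("LV", "RV"):
        ser = state.series[label]
        mask = segment_lumen(ser)
        t, q = compute_flow_samples(ser, mask)
        wfs[label] = resample_waveform(t, q, fx.cycle_period, label=label)
        write_waveform_csv(wfs[label], state.dir / f"flow_{label}.csv")
    state.waveforms = wfs
    summary = flow_ratio_summary(wfs["LV"], wfs["RV"])
    total = wfs["LV"] + wfs["RV"]
    features = detect_cycle_features(total)
    state.ratio_summary = summary
    state.features = features
    write_json(summary.to_dict(), state.dir / "ratio_summary.json")
    write_json(features.to_dict(), state.dir / "cycle_features.json")
    state.report["ratio_summary"] = summary.to_dict()
    state.report["cycle_features"] = features.to_dict()


def _build_case_domain(state: CaseState):
    cfg = state.config
    fx = state.fixture
    wfs = state.waveforms
    fluid = FluidProperties()
    i_pk = int(np.argmax(wfs["LV"].values + wfs["RV"].values))
    peak = {b: wfs[b].values[i_pk] * 1e-6 for b in ("LV", "RV")}
    geom = state.geometry or generate_confluence_geometry(fx)
    ext = extrude_flow_extensions(geom, peak, fluid, policy=cfg.entrance_policy)
    rmin = min(float(c.radius.min()) for c in ext.branches.values())
    h = 2.0 * rmin / cfg.cells_per_diameter
    return build_computational_domain(ext, h), peak, fluid


def stage_simulate(state: CaseState) -> None:
    cfg = state.config
    fx = state.fixture
    wfs = state.waveforms
    domain, peak, fluid = _build_case_domain(state)
    sc = SolverConfig(
        steps_per_cycle=cfg.steps_per_cycle,
        n_cycles=cfg.n_cycles,
        inlet_profile_kind=cfg.inlet_profile_kind,
    )
    solver = MaskedGridSolver(domain, fluid, sc)
    rec = WallShearRecorder(domain, fluid.viscosity)
    if cfg.mode == "steady":
        fld = solver.run_steady(peak)
        rec(fld, 0)
        state.fields = [fld]
        state.diagnostics = None
        diag_dict = {"mode": "steady"}
    else:
        fields, diag = solver.run_pulsatile(wfs, on_output_step=rec)
        state.fields = fields
        state.diagnostics = diag
        diag_dict = {
            "mode": "pulsatile",
            "max_abs_mass_imbalance": float(np.max(np.abs(diag.mass_imbalance))),
            "inter_cycle_difference": [float(x) for x in diag.inter_cycle_difference],
        }
        if diag.inter_cycle_difference:
            ok, metric = check_cycle_convergence(diag, 1e-3)
            diag_dict["cycle_converged"] = bool(ok)
    state.domain = domain
    state.wss_series = rec.series(
        period=fx.cycle_period if cfg.mode == "pulsatile" else None
    )
    from .io import write_fields_h5, write_wss_h5

    write_fields_h5(state.fields, state.dir / "fields.h5")
    write_wss_h5(state.wss_series, state.dir / "wss_series.h5")
    write_json(diag_dict, state.dir / "diagnostics.json")
    state.report["diagnostics"] = diag_dict
    state.report["simulation"] = {
        "lumen_cells": domain.n_lumen_cells,
        "grid_spacing": domain.h,
        "peak_flows_ml_s": {b: q * 1e6 for b, q in peak.items()},
    }


def stage_metrics(state: CaseState) -> None:
    cfg = state.config
    domain = state.domain
    ser = state.wss_series
    maps = hemodynamic_maps(ser)
    regions = low_wss_regions(
        maps.tawss, domain, cfg.low_wss_threshold, valid=maps.valid
    )
    apex_area = sum(r.area for r in regions if "apex-adjacent" in r.tags)
    bas = domain.geometry.branches["BAS"]
    from .geometry import sample_cross_sections

    D = 2.0 * float(bas.radius.mean())
    stations = np.concatenate([
        [0.15 * D, 0.5 * D],
        np.linspace(0.15, 0.85, max(1, cfg.n_stations - 2)) * bas.length,
    ])
    cs = sample_cross_sections(domain.geometry, "BAS", stations)
    ke = [float(np.sum(f.u**2) + np.sum(f.v**2) + np.sum(f.w**2))
          for f in state.fields]
    f_peak = state.fields[int(np.argmax(ke))]
    profiles = velocity_profile_metrics(f_peak, cs)
    mixing = None
    if cfg.pathlines:
        mixing = trace_pathlines(f_peak, seed=state.config.seed)
    metrics = {
        "max_tawss": float(maps.tawss[maps.valid].max()),
        "mean_tawss": float(maps.tawss[maps.valid].mean()),
        "max_osi": float(maps.osi[maps.valid].max()),
        "low_wss_regions": [
            {"area_mm2": r.area * 1e6, "tags": r.tags} for r in regions
        ],
        "apex_low_wss_area_mm2": apex_area * 1e6,
        "profiles": [
            {
                "station_m": p.station,
                "peak_count": p.peak_count,
                "skew_index": p.skew_index,
                "peak_velocity": p.peak_value,
            }
            for p in profiles
        ],
    }
    if mixing is not None:
        metrics["mixing"] = {
            f"{s:.5f}": fr for s, fr in mixing.origin_fractions.items()
        }
        metrics["helicity_index"] = [float(x) for x in mixing.helicity_index]
    write_json(metrics, state.dir / "metrics.json")
    write_vtk_polydata(
        state.dir / "wall_maps.vtk",
        domain.wall_verts,
        domain.wall_faces,
        point_data={
            "TAWSS": maps.tawss,
            "OSI": maps.osi,
            "valid": maps.valid.astype(float),
        },
    )
    state.report["metrics"] = metrics


def _load_generate(state: CaseState) -> None:
    from .fixtures import read_fixture_bundle, read_fixture_manifest

    cfg = state.config
    fx = _fixture_from_config(cfg)
    manifest = read_fixture_manifest(state.dir / "fixture")
    state.fixture = fx
    state.geometry = generate_confluence_geometry(fx)
    state.series = read_fixture_bundle(state.dir / "fixture", fx)
    if set(state.series) != {"LV", "RV"}:
        raise FileNotFoundError("incomplete fixture bundle")
    state.report["geometry"] = {
        "class": manifest["geometry_class"],
        "confluence_angle_deg": manifest["confluence_angle_deg"],
        "dominant_side": manifest["dominant_side"],
    }
    state.report["manifest"] = {
        "subject_id": manifest["subject_id"],
        "geometry_class": manifest["geometry_class"],
    }


def _load_flow(state: CaseState) -> None:
    fx = state.fixture or _fixture_from_config(state.config)
    state.fixture = fx
    state.waveforms = {
        label: read_waveform_csv(state.dir / f"flow_{label}.csv",
                                 period=fx.cycle_period, label=label)
        for label in ("LV", "RV")
    }
    state.report["ratio_summary"] = json.loads(
        (state.dir / "ratio_summary.json").read_text()
    )
    state.report["cycle_features"] = json.loads(
        (state.dir / "cycle_features.json").read_text()
    )


def _load_simulate(state: CaseState) -> None:
    from .io import read_fields_h5, read_wss_h5

    domain, peak, fluid = _build_case_domain(state)
    state.domain = domain
    state.fields = read_fields_h5(domain, state.dir / "fields.h5")
    state.wss_series = read_wss_h5(state.dir / "wss_series.h5")
    diag_dict = json.loads((state.dir / "diagnostics.json").read_text())
    state.report["diagnostics"] = diag_dict
    state.report["simulation"] = {
        "lumen_cells": domain.n_lumen_cells,
        "grid_spacing": domain.h,
        "peak_flows_ml_s": {b: q * 1e6 for b, q in peak.items()},
    }


_STAGE_FUNCS = {
    "generate": stage_generate,
    "flow": stage_flow,
    "simulate": stage_simulate,
    "metrics": stage_metrics,
}

_STAGE_LOADERS = {
    "generate": _load_generate,
    "flow": _load_flow,
    "simulate": _load_simulate,
}

#: Minimal schema of a complete case report: required keys per section.
REPORT_SCHEMA = {
    "config": dict,
    "provenance": dict,
    "stages": dict,
    "geometry": dict,
    "ratio_summary": dict,
    "cycle_features": dict,
    "diagnostics": dict,
    "metrics": dict,
    "content_hash": str,
}


def validate_report(report: dict) -> None:
    """Raise ValueError if a report misses a section or has a wrong type."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report section {key!r} has wrong type")
    for need in ("ratio_min", "ratio_max", "ratio_at_peak_systole"):
        if need not in report["ratio_summary"]:
            raise ValueError(f"ratio_summary missing {need!r}")
    for need in ("max_tawss", "max_osi", "apex_low_wss_area_mm2"):
        if need not in report["metrics"]:
            raise ValueError(f"metrics missing {need!r}")


def _marker(state: CaseState, name: str) -> Path:
    return state.dir / f"stage_{name}.json"


def run_case(config, stages=None, resume: bool = False) -> dict:
    """Run a case through the pipeline stages in order; returns the report.

    Any stage error aborts the run with the stage named; outputs of the
    completed stages remain in the case directory.  With ``resume=True`` a
    stage whose outputs already exist for this exact configuration is
    reloaded from disk instead of recomputed.
    """
    if isinstance(config, (str, Path)):
        config = CaseConfig.from_yaml(config)
    state = CaseState(config)
    report = state.report
    report["config"] = config.to_dict()
    report["provenance"] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    for name in stages or STAGES:
        t0 = time.time()
        try:
            resumed = False
            if resume and name in _STAGE_LOADERS and _marker(state, name).exists():
                marker = json.loads(_marker(state, name).read_text())
                if marker.get("config_hash") == config.config_hash():
                    _STAGE_LOADERS[name](state)
                    resumed = True
            if not resumed:
                _STAGE_FUNCS[name](state)
                state.dir.mkdir(parents=True, exist_ok=True)
                if name in _STAGE_LOADERS:
                    write_json({"config_hash": config.config_hash(),
                                "stage": name}, _marker(state, name))
        except Exception as exc:  # noqa: BLE001 - stage boundary
            report["stages"][name] = {
                "status": "failed", "seconds": time.time() - t0,
                "error": str(exc),
            }
            _write_report(state)
            raise StageError(name, exc) from exc
        report["stages"][name] = {
            "status": "resumed" if resumed else "ok",
            "seconds": time.time() - t0,
        }
    report["content_hash"] = content_hash(report)
    if all(s in report["stages"] for s in STAGES):
        validate_report(report)
    _write_report(state)
    return report


def _write_report(state: CaseState) -> None:
    state.dir.mkdir(parents=True, exist_ok=True)
    write_json(state.report, state.dir / "report.json")


def load_report(path) -> dict:
    p = Path(path)
    if p.is_dir():
        p = p / "report.json"
    return json.loads(p.read_text())


def summarize_cases(reports) -> "pandas.DataFrame":  # noqa: F821
    """One comparison row per case report (dicts or report paths)."""
    import pandas as pd

    if not reports:
        raise ValueError("no case reports to summarize")
    rows = []
    for r in reports:
        if not isinstance(r, dict):
            r = load_report(r)
        try:
            rows.append(
                {
                    "subject": r["config"]["subject"],
                    "class": r["geometry"]["class"],
                    "confluence_angle_deg": r["geometry"]["confluence_angle_deg"],
                    "ratio_min": r["ratio_summary"]["ratio_min"],
                    "ratio_max": r["ratio_summary"]["ratio_max"],
                    "max_tawss": r["metrics"]["max_tawss"],
                    "max_osi": r["metrics"]["max_osi"],
                    "apex_low_wss_area_mm2": r["metrics"]["apex_low_wss_area_mm2"],
                }
            )
        except KeyError as exc:
            raise ValueError(f"report missing required field: {exc}") from exc
    return pd.DataFrame(rows)
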
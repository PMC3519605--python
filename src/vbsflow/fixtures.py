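"""Synthetic study inputs with known ground truth.

The real study measured everything from MRI in five subjects (A-E): lumen
geometry from time-of-flight angiography, and vertebral flow waveforms from
phase-contrast MR (PCMR).  No subject data were released, so this module
generates every input synthetically, parameterised by the published
per-subject characteristics: the geometric configuration class of each
subject (Walking, Tuning Fork, Lambda), the vertebral flow-ratio extremes
over the cardiac cycle, and the ratio at peak systole.

Three generators are provided:

* :func:`generate_vertebral_waveforms` -- a left/right vertebral flow-rate
  pair whose pointwise dominant/non-dominant ratio attains the prescribed
  extremes and peak-systole value exactly;
* :func:`generate_confluence_geometry` -- a classified centerline-tube
  confluence geometry of the fixture's class;
* :func:`generate_pcmr_series` -- a PCMR-like through-plane velocity image
  stack synthesised from the analytic pulsatile (Womersley) profile, with
  stored ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .waveforms import FlowWaveform, periodic_interpolator, DEFAULT_N_POINTS
from .womersley import flow_harmonics, womersley_profile

SUBJECT_IDS = ("A", "B", "C", "D", "E")

# Published per-subject pulse-cycle characteristics: geometric class,
# dominant vertebral side, and (ratio_min, ratio_max, ratio_at_peak_systole)
# of the dominant/non-dominant vertebral flow ratio.
_SUBJECT_TABLE = {
    "A": ("Walking", "RV", 1.18, 2.22, 2.22),
    "B": ("Walking", "LV", 2.07, 3.20, 2.22),
    "C": ("TuningFork", "LV", 1.34, 1.90, 1.47),
    "D": ("TuningFork", "RV", 1.13, 2.13, 1.13),
    "E": ("Lambda", "RV", 1.44, 1.95, 1.13),
}

# 21 cardiac phases were acquired in some subjects, 25 in others.
_SUBJECT_N_PHASES = {"A": 21, "B": 21, "C": 21, "D": 25, "E": 25}


@dataclass(frozen=True)
class PCMRImagingSpec:
    """Acquisition parameters of the synthetic PCMR series.

    pixel_size and slice_thickness in mm (reconstructed in-plane pixels of
    0.31 mm); venc in cm/s; noise_sd is the velocity noise standard
    deviation in m/s (default 2% of VENC).
    """

    n_phases: int = 21
    pixel_size: float = 0.31
    slice_thickness: float = 5.0
    venc: float = 100.0
    noise_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_phases not in (21, 25):
            warnings.warn(f"unusual cardiac phase count {self.n_phases}", stacklevel=2)
        if self.venc <= 0 or self.pixel_size <= 0:
            raise ValueError("venc and pixel_size must be positive")

    @property
    def venc_ms(self) -> float:
        return self.venc / 100.0

    @property
    def noise_sd_ms(self) -> float:
        return 0.02 * self.venc_ms if self.noise_sd is None else self.noise_sd


@dataclass(frozen=True)
class RatioSpec:
    """(dominant side, cycle min, cycle max, value at peak systole)."""

    dominant_side: str
    ratio_min: float
    ratio_max: float
    ratio_at_peak_systole: float

    def __post_init__(self) -> None:
        if self.dominant_side not in ("LV", "RV"):
            raise ValueError("dominant_side must be 'LV' or 'RV'")
        if self.ratio_min < 1.0:
            raise ValueError("ratio_min must be >= 1 (dominant/non-dominant)")
        if self.ratio_max < self.ratio_min:
            raise ValueError("ratio_max must be >= ratio_min")


@dataclass(frozen=True)
class SubjectFixture:
    """Parameter set standing in for one subject's MRI-derived inputs."""

    subject_id: str
    geometry_class: str
    ratio_spec: RatioSpec
    cycle_period: float = 1.0
    vessel_radii: dict = field(
        default_factory=lambda: {"LV": 1.5e-3, "RV": 1.5e-3, "BAS": 1.6e-3}
    )
    seed: int = 0
    imaging: PCMRImagingSpec = field(default_factory=PCMRImagingSpec)
    # combined (LV+RV) flow-pulse parameters, ml/s
    diastolic_flow: float = 1.6
    systolic_amplitude: float = 3.4
    systolic_width: float = 9.0  # von-Mises concentration of the systolic bump
    peak_systole_fraction: float = 0.16

    def __post_init__(self) -> None:
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        if any(r <= 0 for r in self.vessel_radii.values()):
            raise ValueError("vessel radii must be positive")

    @property
    def dominant_side(self) -> str:
        return self.ratio_spec.dominant_side


def make_subject_fixture(subject_id: str, **overrides) -> SubjectFixture:
    """Fixture for one of the five published subjects A-E.

    Geometry class, dominant vertebral side, and ratio extremes follow the
    published per-subject table; vessel radii give the dominant vertebral a
    slightly larger calibre, as is typical.
    """
    if subject_id not in _SUBJECT_TABLE:
        raise KeyError(
            f"unknown subject {subject_id!r}; expected one of {SUBJECT_IDS}"
        )
    cls, side, rmin, rmax, rps = _SUBJECT_TABLE[subject_id]
    other = "LV" if side == "RV" else "RV"
    radii = {side: 1.7e-3, other: 1.4e-3, "BAS": 1.62e-3}
    defaults = dict(
        subject_id=subject_id,
        geometry_class=cls,
        ratio_spec=RatioSpec(side, rmin, rmax, rps),
        vessel_radii=radii,
        seed=ord(subject_id),
        imaging=PCMRImagingSpec(n_phases=_SUBJECT_N_PHASES[subject_id]),
    )
    defaults.update(overrides)
    return SubjectFixture(**defaults)


# ---------------------------------------------------------------------------
# vertebral waveform pair
# ---------------------------------------------------------------------------

def _snap(fraction: float, n_phases: int) -> float:
    """Snap a cycle fraction onto the cardiac phase grid."""
    return round(fraction * n_phases) / n_phases


def _ratio_curve(fixture: SubjectFixture, peak_ratio_policy: str):
    """Periodic ratio curve r(t) meeting the fixture's ratio specification.

    Built as a periodic monotone (PCHIP) interpolant through control points
    at the ratio extremes and at peak systole: between control points the
    interpolant is monotone, so the cycle min/max equal the prescribed
    extremes exactly.  Control instants are snapped onto the cardiac phase
    grid so that extremes survive the imaging round trip.
    """
    rs = fixture.ratio_spec
    rmin, rmax, rps = rs.ratio_min, rs.ratio_max, rs.ratio_at_peak_systole
    T = fixture.cycle_period
    n = fixture.imaging.n_phases
    if not (rmin - 1e-12 <= rps <= rmax + 1e-12):
        if peak_ratio_policy == "strict":
            raise ValueError(
                f"infeasible ratio spec: peak-systole ratio {rps} outside "
                f"[{rmin}, {rmax}]"
            )
        rps = float(np.clip(rps, rmin, rmax))
    f_ps = _snap(fixture.peak_systole_fraction, n)
    if rmax - rmin < 1e-12:
        return (lambda t: np.full_like(np.asarray(t, dtype=float), rmin)), f_ps * T
    mid = 0.5 * (rmin + rmax)
    pts = [(0.0, mid), (f_ps, rps)]
    if rmax - rps > 1e-9:
        pts.append((_snap(0.44, n), rmax))
    if rps - rmin > 1e-9:
        pts.append((_snap(0.76, n) if rmax - rps > 1e-9 else _snap(0.72, n), rmin))
    pts.sort()
    t_ctl = np.array([p[0] for p in pts]) * T
    v_ctl = np.array([p[1] for p in pts])
    return periodic_interpolator(t_ctl, v_ctl, T, kind="pchip"), f_ps * T


def _total_flow(fixture: SubjectFixture, t: np.ndarray, t_peak: float) -> np.ndarray:
    """Combined (LV+RV) pulse: diastolic plateau plus periodic systolic bump."""
    T = fixture.cycle_period
    bump = np.exp(
        fixture.systolic_width * (np.cos(2 * np.pi * (t - t_peak) / T) - 1.0)
    )
    return fixture.diastolic_flow + fixture.systolic_amplitude * bump


def generate_vertebral_waveforms(
    fixture: SubjectFixture,
    n_points: int = DEFAULT_N_POINTS,
    peak_ratio_policy: str = "clamp",
) -> tuple[FlowWaveform, FlowWaveform]:
    """Left and right vertebral flow waveforms for a subject fixture.

    Returns ``(lv, rv)``.  Both are strictly positive and periodic; the
    pointwise dominant/non-dominant ratio attains the fixture's ratio_min
    and ratio_max over the cycle and equals ratio_at_peak_systole at the
    instant of maximum combined flow.

    ``peak_ratio_policy`` controls handling of a peak-systole ratio outside
    the [min, max] band (one published subject's table row is internally
    inconsistent this way): 'clamp' (default) pulls it to the nearest band
    edge, 'strict' raises.
    """
    if peak_ratio_policy not in ("clamp", "strict"):
        raise ValueError("peak_ratio_policy must be 'clamp' or 'strict'")
    T = fixture.cycle_period
    ratio_fn, t_peak = _ratio_curve(fixture, peak_ratio_policy)
    t = np.arange(n_points) * (T / n_points)
    q_tot = _total_flow(fixture, t, t_peak)
    r = ratio_fn(t)
    q_dom = q_tot * r / (1.0 + r)
    q_non = q_tot / (1.0 + r)
    side = fixture.dominant_side
    waves = {
        side: FlowWaveform(t, q_dom, T, label=side),
        ("LV" if side == "RV" else "RV"): FlowWaveform(
            t, q_non, T, label="LV" if side == "RV" else "RV"
        ),
    }
    return waves["LV"], waves["RV"]


# ---------------------------------------------------------------------------
# PCMR image synthesis
# ---------------------------------------------------------------------------

@dataclass
class SeriesTruth:
    """Ground truth stored with a synthetic PCMR series."""

    mask: np.ndarray
    times: np.ndarray
    flow_ml_s: np.ndarray
    radius: float
    center_px: tuple


@dataclass
class VelocityImageSeries:
    """Synthetic PCMR stack: (phases, ny, nx) through-plane velocity in m/s."""

    data: np.ndarray
    spec: PCMRImagingSpec
    phase_times: np.ndarray
    period: float
    truth: SeriesTruth

    @property
    def n_phases(self) -> int:
        return self.data.shape[0]


def generate_pcmr_series(
    waveform: FlowWaveform,
    radius: float,
    spec: PCMRImagingSpec,
    seed: Optional[int] = None,
    noise_sd: Optional[float] = None,
    aliasing: bool = False,
    n_pixels: Optional[int] = None,
    center_offset_px: tuple = (0.23, -0.17),
    n_harmonics: Optional[int] = None,
) -> VelocityImageSeries:
    """Synthesise a PCMR-like velocity image series for one vessel.

    Each phase map is the analytic pulsatile (Womersley-superposition)
    profile of the waveform in a rigid circular tube of the given radius,
    sampled at the pixel centres, plus zero-mean Gaussian velocity noise.
    ``noise_sd`` (m/s) overrides the imaging-spec default; pass 0 for a noiseless
    series (then the output is deterministic and independent of ``seed``).
    With ``aliasing=True`` velocities beyond VENC wrap around, as in a
    phase-difference reconstruction.
    """
    pixel_m = spec.pixel_size * 1e-3
    radius_px = radius / pixel_m
    if radius_px < 2.0:
        raise ValueError(
            f"lumen unresolvable: radius spans {radius_px:.2f} pixels (< 2)"
        )
    if radius_px < 4.0:
        warnings.warn(
            f"lumen radius spans only {radius_px:.2f} pixels; flow "
            "quantification will be coarse",
            stacklevel=2,
        )
    if n_pixels is None:
        n_pixels = max(32, int(np.ceil(4 * radius_px + 8)))
    if n_harmonics is None:
        n_harmonics = min(10, (spec.n_phases - 1) // 2)

    # analytic pulsatile profile; fluid constants match the simulation stage
    from .solver import FluidProperties

    fluid = FluidProperties()
    harm = flow_harmonics(waveform.values * 1e-6, n_harmonics)  # m^3/s
    profile = womersley_profile(radius, harm, fluid, waveform.period)

    cy = (n_pixels / 2.0 + center_offset_px[1]) * pixel_m
    cx = (n_pixels / 2.0 + center_offset_px[0]) * pixel_m
    yy = (np.arange(n_pixels) + 0.5) * pixel_m
    xx = (np.arange(n_pixels) + 0.5) * pixel_m
    rr = np.hypot(yy[:, None] - cy, xx[None, :] - cx)

    times = np.arange(spec.n_phases) * (waveform.period / spec.n_phases)
    data = np.stack([profile.velocity(rr, t) for t in times])

    sd = spec.noise_sd_ms if noise_sd is None else noise_sd
    if sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, sd, size=data.shape)
    if aliasing:
        venc = spec.venc_ms
        data = np.mod(data + venc, 2 * venc) - venc

    truth = SeriesTruth(
        mask=rr <= radius,
        times=times,
        flow_ml_s=profile.flow_rate(times) * 1e6,
        radius=radius,
        center_px=(cx / pixel_m, cy / pixel_m),
    )
    return VelocityImageSeries(
        data=data, spec=spec, phase_times=times, period=waveform.period, truth=truth
    )


def generate_confluence_geometry(fixture: SubjectFixture, **shape_params):
    """Confluence geometry of the fixture's class with ground-truth labels.

    Thin front-end over :func:`vbsflow.geometry.build_class_geometry`; the
    fixture supplies the class, vessel radii and dominant side, while
    ``shape_params`` (confluence angle, curvatures, lengths) override the
    per-class defaults.
    """
    from .geometry import build_class_geometry

    return build_class_geometry(
        fixture.geometry_class,
        radii=fixture.vessel_radii,
        dominant_side=fixture.dominant_side,
        **shape_params,
    )


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    fixture: SubjectFixture,
    geometry,
    series: dict,
    path,
    waveforms: Optional[dict] = None,
) -> dict:
    """Persist a fixture (manifest, surface, image series, truth tables).

    ``series`` maps vessel labels ('LV', 'RV') to VelocityImageSeries.
    Writes: ``manifest.json``, per-vessel NIfTI image stacks and truth JSON,
    optional waveform CSVs, and the geometry surface as ASCII STL.  Returns
    the manifest dictionary.
    """
    import nibabel as nib

    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    path.mkdir(exist_ok=True)

    manifest = {
        "subject_id": fixture.subject_id,
        "geometry_class": fixture.geometry_class,
        "dominant_side": fixture.dominant_side,
        "ratio_spec": asdict(fixture.ratio_spec),
        "cycle_period": fixture.cycle_period,
        "vessel_radii": dict(fixture.vessel_radii),
        "seed": fixture.seed,
        "imaging": asdict(fixture.imaging),
        "files": {},
    }

    for label, s in series.items():
        img = nib.Nifti1Image(
            np.transpose(s.data, (2, 1, 0))[:, :, None, :].astype(np.float32),
            affine=np.diag([s.spec.pixel_size, s.spec.pixel_size,
                            s.spec.slice_thickness, 1.0]),
        )
        nii = path / f"pcmr_{label}.nii"
        nib.save(img, nii)
        truth_file = path / f"truth_{label}.json"
        truth_file.write_text(
            json.dumps(
                {
                    "times": s.truth.times.tolist(),
                    "flow_ml_s": s.truth.flow_ml_s.tolist(),
                    "radius": s.truth.radius,
                    "center_px": list(s.truth.center_px),
                    "mask_rle": _rle_encode(s.truth.mask),
                    "mask_shape": list(s.truth.mask.shape),
                },
                indent=1,
            )
        )
        manifest["files"][f"pcmr_{label}"] = nii.name
        manifest["files"][f"truth_{label}"] = truth_file.name

    if waveforms:
        for label, wf in waveforms.items():
            csv = path / f"waveform_{label}.csv"
            arr = np.column_stack([wf.times, wf.values])
            np.savetxt(csv, arr, delimiter=",", header="time_s,Q_ml_per_s", comments="")
            manifest["files"][f"waveform_{label}"] = csv.name

    if geometry is not None:
        from .io import write_stl, write_centerlines_csv

        stl = path / "surface.stl"
        write_stl(geometry, stl)
        manifest["files"]["surface"] = stl.name
        cl = path / "centerlines.csv"
        write_centerlines_csv(geometry, cl)
        manifest["files"]["centerlines"] = cl.name
        manifest["confluence_angle_deg"] = geometry.confluence_angle_deg
        manifest["geometry_class"] = geometry.geometry_class

    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_fixture_manifest(path) -> dict:
    return json.loads((Path(path) / "manifest.json").read_text())


def read_fixture_bundle(path, fixture: SubjectFixture) -> dict:
    """Reload the per-vessel PCMR series of a written fixture bundle."""
    import nibabel as nib

    path = Path(path)
    series = {}
    for label in ("LV", "RV"):
        nii = path / f"pcmr_{label}.nii"
        if not nii.exists():
            continue
        img = nib.load(nii)
        data = np.transpose(np.asarray(img.dataobj)[:, :, 0, :], (2, 1, 0))
        truth_raw = json.loads((path / f"truth_{label}.json").read_text())
        mask = _rle_decode(
            truth_raw["mask_rle"], tuple(truth_raw["mask_shape"])
        )
        times = np.asarray(truth_raw["times"], dtype=float)
        series[label] = VelocityImageSeries(
            data=data.astype(float),
            spec=fixture.imaging,
            phase_times=times,
            period=fixture.cycle_period,
            truth=SeriesTruth(
                mask=mask,
                times=times,
                flow_ml_s=np.asarray(truth_raw["flow_ml_s"], dtype=float),
                radius=truth_raw["radius"],
                center_px=tuple(truth_raw["center_px"]),
            ),
        )
    return series


def _rle_decode(runs: list, shape: tuple) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    val = False
    for run in runs:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


def _rle_encode(mask: np.ndarray) -> list:
    """Run-length encode a flattened boolean mask (starts False)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.nonzero(np.diff(flat))[0] + 1
    runs = np.diff(np.concatenate([[0], changes, [flat.size]]))
    out = runs.tolist()
    if flat[0]:
        out = [0] + out
    return out
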
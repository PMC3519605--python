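"""File formats: surfaces (STL, legacy VTK polydata), tables, fields.

Surfaces are written as ASCII STL (via trimesh) and legacy ASCII VTK
polydata (hand-rolled writer for the simple legacy text format, so results
open directly in ParaView-class viewers).  Waveforms and centerlines go to
CSV, hemodynamic summaries to JSON, and gridded fields/domains to HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def write_stl(geometry_or_mesh, path, h: Optional[float] = None) -> None:
    """Write a lumen surface as ASCII STL.

    Accepts a ConfluenceGeometry (surface extracted from its signed
    distance) or a ``(vertices, faces)`` tuple.
    """
    import trimesh

    if hasattr(geometry_or_mesh, "surface"):
        verts, faces, _ = geometry_or_mesh.surface(h=h)
    else:
        verts, faces = geometry_or_mesh[:2]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    Path(path).write_bytes(trimesh.exchange.stl.export_stl_ascii(mesh).encode())


def read_stl(path):
    import trimesh

    mesh = trimesh.load_mesh(path, file_type="stl")
    return np.asarray(mesh.vertices), np.asarray(mesh.faces)


def write_vtk_polydata(path, verts: np.ndarray, faces: np.ndarray,
                       point_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Legacy ASCII VTK polydata with optional per-vertex scalar arrays."""
    verts = np.asarray(verts, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        "vbsflow surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(verts)} float",
    ]
    lines += [" ".join(f"{x:.8e}" for x in v) for v in verts]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += ["3 " + " ".join(str(int(i)) for i in f) for f in faces]
    if point_data:
        lines.append(f"POINT_DATA {len(verts)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.8e}" for x in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_imagedata(path, origin, spacing: float,
                        cell_arrays: Dict[str, np.ndarray]) -> None:
    """Legacy ASCII VTK structured points with cell-centred scalar arrays."""
    first = next(iter(cell_arrays.values()))
    nx, ny, nz = first.shape[:3]
    lines = [
        "# vtk DataFile Version 3.0",
        "vbsflow field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {origin[0]:.8e} {origin[1]:.8e} {origin[2]:.8e}",
        f"SPACING {spacing:.8e} {spacing:.8e} {spacing:.8e}",
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, arr in cell_arrays.items():
        arr = np.asarray(arr)
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.transpose(2, 1, 0).ravel()
            lines += [f"{x:.6e}" for x in flat]
        else:  # (nx, ny, nz, 3) vector
            lines.append(f"VECTORS {name} float")
            flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
            lines += [" ".join(f"{x:.6e}" for x in v) for v in flat]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_centerlines_csv(geometry, path) -> None:
    rows = ["branch,x,y,z,radius"]
    for b in geometry.branch_names:
        c = geometry.branches[b]
        for p, r in zip(c.points, c.radius):
            rows.append(f"{b},{p[0]:.9e},{p[1]:.9e},{p[2]:.9e},{r:.9e}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_centerlines_csv(path) -> dict:
    """Read back per-branch centerlines as {branch: (points, radii)}."""
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for b, grp in df.groupby("branch", sort=False):
        out[str(b)] = (grp[["x", "y", "z"]].to_numpy(), grp["radius"].to_numpy())
    return out


def write_waveform_csv(waveform, path) -> None:
    arr = np.column_stack([waveform.times, waveform.values])
    np.savetxt(path, arr, delimiter=",", header="time_s,Q_ml_per_s", comments="")


def read_waveform_csv(path, period: Optional[float] = None, label=None):
    from .waveforms import FlowWaveform

    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    t, q = arr[:, 0], arr[:, 1]
    if period is None:
        period = float(t[-1] + (t[1] - t[0]))
    return FlowWaveform(times=t, values=q, period=period, label=label)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# gridded data (HDF5)
# ---------------------------------------------------------------------------

def write_domain_h5(domain, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["h"] = domain.h
        f.attrs["origin"] = domain.origin
        f.attrs["shape"] = domain.shape
        f.create_dataset("phi", data=domain.phi, compression="gzip")
        f.create_dataset("cell_type", data=domain.cell_type, compression="gzip")
        f.create_dataset("branch_id", data=domain.branch_id, compression="gzip")
        f.create_dataset("arc_s", data=domain.arc_s, compression="gzip")


def write_fields_h5(fields, path) -> None:
    """Store a sequence of flow fields (velocity faces + pressure)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["n_fields"] = len(fields)
        f.attrs["times"] = [fl.time for fl in fields]
        for i, fl in enumerate(fields):
            g = f.create_group(f"field_{i:04d}")
            for name in ("u", "v", "w", "p"):
                g.create_dataset(name, data=getattr(fl, name).astype(np.float32),
                                 compression="gzip")


def read_fields_h5(domain, path) -> list:
    """Reload a flow-field sequence written by :func:`write_fields_h5`."""
    import h5py

    from .solver import FlowField

    out = []
    with h5py.File(path, "r") as f:
        times = list(f.attrs["times"])
        for i in range(int(f.attrs["n_fields"])):
            g = f[f"field_{i:04d}"]
            out.append(
                FlowField(
                    u=np.asarray(g["u"], dtype=float),
                    v=np.asarray(g["v"], dtype=float),
                    w=np.asarray(g["w"], dtype=float),
                    p=np.asarray(g["p"], dtype=float),
                    time=float(times[i]),
                    domain=domain,
                )
            )
    return out


def write_wss_h5(series, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        if series.period is not None:
            f.attrs["period"] = series.period
        f.create_dataset("positions", data=series.positions)
        f.create_dataset("normals", data=series.normals)
        f.create_dataset("times", data=series.times)
        f.create_dataset("tau", data=series.tau.astype(np.float32),
                         compression="gzip")
        f.create_dataset("valid", data=series.valid)


def read_wss_h5(path):
    import h5py

    from .hemodynamics import WallShearSeries

    with h5py.File(path, "r") as f:
        return WallShearSeries(
            positions=np.asarray(f["positions"]),
            normals=np.asarray(f["normals"]),
            times=np.asarray(f["times"]),
            tau=np.asarray(f["tau"], dtype=float),
            valid=np.asarray(f["valid"], dtype=bool),
            period=float(f.attrs["period"]) if "period" in f.attrs else None,
        )
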
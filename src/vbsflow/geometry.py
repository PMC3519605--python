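"""Vessel geometry: centerline trees, classification, and computational domains.

A vertebrobasilar confluence is represented by three labelled centerlines
(left vertebral LV, right vertebral RV, basilar BAS) carrying per-point
radii.  The vertebrals terminate at a common apex from which the basilar
originates; the lumen surface is the smooth union of tubes around the
centerlines, so the junction blends naturally.

The module provides the measurement/classification stage (configuration
class, confluence angle, curvature and outer-wall orientation), flow
extensions, and conversion to a signed-distance computational domain on a
uniform Cartesian grid for the flow solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.interpolate import interp1d
from scipy.spatial import cKDTree

BRANCHES = ("LV", "RV", "BAS")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = _unit(np.asarray(axis, dtype=float))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    a, b = _unit(np.asarray(a, float)), _unit(np.asarray(b, float))
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_matrix(perp, np.pi)
    return rotation_matrix(v, np.arctan2(np.linalg.norm(v), c))


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    """Ordered 3-D centerline with per-point radius (metres).

    Tangents and curvature vectors are discrete Frenet estimates on the
    (uniformly resampled) polyline; ``arc_length`` is cumulative.
    """

    points: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.radius = np.broadcast_to(
            np.asarray(self.radius, dtype=float), (self.points.shape[0],)
        ).copy()
        if self.points.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if np.any(self.radius <= 0):
            raise ValueError("radii must be positive")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("arc length must be strictly increasing")
        self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def resampled(self, n: Optional[int] = None, spacing: Optional[float] = None) -> "Centerline":
        """Uniform-arc-length resampling (cubic in each coordinate)."""
        if n is None:
            n = max(2, int(np.ceil(self.length / spacing)) + 1)
        s = np.linspace(0.0, self.length, n)
        kind = "cubic" if self.n_points >= 4 else "linear"
        pts = interp1d(self.arc_length, self.points, axis=0, kind=kind)(s)
        rad = interp1d(self.arc_length, self.radius, kind="linear")(s)
        return Centerline(pts, rad)

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points, self.arc_length, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def curvature_vectors(self, smooth_window: int = 5) -> np.ndarray:
        """dT/ds per point, lightly smoothed to stabilise the discrete estimate."""
        t = self.tangents()
        if smooth_window >= 3 and self.n_points > smooth_window:
            from scipy.signal import savgol_filter

            w = smooth_window + (smooth_window + 1) % 2  # force odd
            t = savgol_filter(t, w, 2, axis=0)
            t = t / np.linalg.norm(t, axis=1, keepdims=True)
        return np.gradient(t, self.arc_length, axis=0)

    def point_at(self, s: float) -> np.ndarray:
        return interp1d(self.arc_length, self.points, axis=0)(np.clip(s, 0, self.length))

    def radius_at(self, s: float) -> float:
        return float(interp1d(self.arc_length, self.radius)(np.clip(s, 0, self.length)))

    def tangent_at(self, s: float) -> np.ndarray:
        t = interp1d(self.arc_length, self.tangents(), axis=0)(
            np.clip(s, 0, self.length)
        )
        return _unit(t)

    def mean_tangent(self, s0: float, s1: float) -> np.ndarray:
        """Arc-length-averaged unit tangent over [s0, s1]."""
        sel = (self.arc_length >= s0 - 1e-12) & (self.arc_length <= s1 + 1e-12)
        if sel.sum() < 2:
            return self.tangent_at(0.5 * (s0 + s1))
        return _unit(self.tangents()[sel].mean(axis=0))

    def transformed(self, R: np.ndarray = None, t: np.ndarray = None) -> "Centerline":
        pts = self.points
        if R is not None:
            pts = pts @ np.asarray(R, float).T
        if t is not None:
            pts = pts + np.asarray(t, float)
        return Centerline(pts, self.radius.copy())


# ---------------------------------------------------------------------------
# confluence geometry
# ---------------------------------------------------------------------------

@dataclass
class ConfluenceGeometry:
    """Labelled LV/RV/BAS centerline tree with a tube-union lumen surface.

    LV and RV run downstream and terminate at the apex; BAS originates at
    the apex.  ``geometry_class`` and ``construction_angle_deg`` store the
    generator's ground truth where the geometry was constructed; imported
    geometries may leave them None.
    """

    branches: Dict[str, Centerline]
    apex: np.ndarray
    geometry_class: Optional[str] = None
    construction_angle_deg: Optional[float] = None
    dominant_side: Optional[str] = None
    extension_lengths: Dict[str, float] = field(default_factory=dict)
    _tree_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float)
        if "BAS" not in self.branches or not any(
            b in self.branches for b in ("LV", "RV")
        ):
            raise ValueError("need a BAS branch and at least one vertebral branch")
        for b in ("LV", "RV"):
            if b in self.branches and np.linalg.norm(
                self.branches[b].points[-1] - self.apex
            ) > 1e-9:
                raise ValueError(f"{b} must terminate at the apex")
        if np.linalg.norm(self.branches["BAS"].points[0] - self.apex) > 1e-9:
            raise ValueError("BAS must originate at the apex")

    @property
    def branch_names(self) -> tuple:
        return tuple(b for b in BRANCHES if b in self.branches)

    @property
    def inlet_branches(self) -> tuple:
        return tuple(b for b in ("LV", "RV") if b in self.branches)

    @property
    def confluence_angle_deg(self) -> float:
        return confluence_angle(self)

    def max_radius(self) -> float:
        return max(float(c.radius.max()) for c in self.branches.values())

    def _dense_samples(self, spacing: float):
        key = ("dense", round(spacing, 12))
        if key not in self._tree_cache:
            pts, rad, bid, arcs = [], [], [], []
            for i, b in enumerate(self.branch_names):
                c = self.branches[b].resampled(spacing=spacing)
                pts.append(c.points)
                rad.append(c.radius)
                bid.append(np.full(c.n_points, i))
                arcs.append(c.arc_length)
            pts = np.vstack(pts)
            self._tree_cache[key] = (
                cKDTree(pts),
                np.concatenate(rad),
                np.concatenate(bid),
                np.concatenate(arcs),
            )
        return self._tree_cache[key]

    def signed_distance(
        self, points: np.ndarray, spacing: Optional[float] = None, info: bool = False
    ):
        """Signed distance to the tube-union surface (negative inside).

        ``spacing`` controls the centerline sampling density of the distance
        query (default: min radius / 8).  With ``info=True`` also returns the
        nearest branch index (into BRANCHES) and its arc-length station.
        """
        if spacing is None:
            spacing = min(float(c.radius.min()) for c in self.branches.values()) / 8.0
        tree, rad, bid, arcs = self._dense_samples(spacing)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d, idx = tree.query(pts, workers=-1)
        phi = d - rad[idx]
        if info:
            return phi, bid[idx], arcs[idx]
        return phi

    def surface(self, h: Optional[float] = None):
        """Triangulated lumen surface via marching cubes on the SDF.

        Returns ``(vertices, faces, normals)`` with outward unit normals.
        ``h`` is the sampling grid spacing (default: min radius / 5).
        """
        from skimage.measure import marching_cubes

        if h is None:
            h = min(float(c.radius.min()) for c in self.branches.values()) / 5.0
        lo, hi = self.bounds(margin=3 * h)
        shape = np.ceil((hi - lo) / h).astype(int) + 1
        axes = [lo[i] + np.arange(shape[i]) * h for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        phi = self.signed_distance(grid).reshape(shape)
        verts, faces, normals, _ = marching_cubes(phi, level=0.0, spacing=(h, h, h))
        verts = verts + lo
        # marching_cubes normals point down-gradient (inward); flip outward
        normals = -normals / np.linalg.norm(normals, axis=1, keepdims=True)
        return verts, faces, normals

    def bounds(self, margin: float = 0.0):
        pts = np.vstack([c.points for c in self.branches.values()])
        rmax = self.max_radius()
        return pts.min(axis=0) - rmax - margin, pts.max(axis=0) + rmax + margin

    def transformed(self, R: np.ndarray = None, t: np.ndarray = None) -> "ConfluenceGeometry":
        """Rigid (or mirror) transform of the whole tree."""
        apex = self.apex
        if R is not None:
            apex = np.asarray(R, float) @ apex
        if t is not None:
            apex = apex + np.asarray(t, float)
        return ConfluenceGeometry(
            branches={b: c.transformed(R, t) for b, c in self.branches.items()},
            apex=apex,
            geometry_class=self.geometry_class,
            construction_angle_deg=self.construction_angle_deg,
            dominant_side=self.dominant_side,
            extension_lengths=dict(self.extension_lengths),
        )


# ---------------------------------------------------------------------------
# construction of class geometries
# ---------------------------------------------------------------------------

def _integrate_arc(
    end_point: np.ndarray,
    end_tangent: np.ndarray,
    length: float,
    arc_angle: float,
    bend_axis: np.ndarray,
    n: int = 161,
    downstream_of_end: bool = False,
    straight_run: float = 0.0,
) -> np.ndarray:
    """Points of a circular-arc branch, built backwards from its downstream end.

    The downstream tangent is ``end_tangent``; moving upstream the tangent
    rotates by ``-arc_angle`` about ``bend_axis`` in total.  A
    ``straight_run`` adjacent to ``end_point`` carries no curvature (so
    junction tangents are well defined there).  With
    ``downstream_of_end=True`` the curve is instead grown forwards from
    ``end_point`` (used for the basilar).
    """
    s = np.linspace(0.0, length, n)
    arc_len = max(length - straight_run, 1e-9)
    kappa = arc_angle / arc_len
    axis = _unit(np.asarray(bend_axis, float))
    if downstream_of_end:
        # straight head at the start, arc beyond it
        ang = np.clip(s - straight_run, 0.0, None) * kappa
        tangents = np.stack([rotation_matrix(axis, a) @ end_tangent for a in ang])
        disp = np.zeros((n, 3))
        for i in range(1, n):
            disp[i] = disp[i - 1] + 0.5 * (tangents[i - 1] + tangents[i]) * (s[i] - s[i - 1])
        return end_point + disp
    ang = np.clip(s - (length - straight_run), None, 0.0)
    ang = np.where(s >= length - straight_run, 0.0, (s - (length - straight_run)) * kappa)
    tangents = np.stack([rotation_matrix(axis, a) @ end_tangent for a in ang])
    disp = np.zeros((n, 3))
    for i in range(1, n):
        disp[i] = disp[i - 1] + 0.5 * (tangents[i - 1] + tangents[i]) * (s[i] - s[i - 1])
    return end_point + (disp - disp[-1])


_CLASS_DEFAULTS = {
    # per class: (confluence angle deg, vertebral arc angles deg (dom, non),
    #             basilar arc deg, dominant end-tangent offset deg)
    "Walking": dict(angle_deg=74.0, arc_dom=40.0, arc_non=40.0, same_side=True,
                    basilar_arc_deg=45.0),
    "TuningFork": dict(angle_deg=74.0, arc_dom=35.0, arc_non=-35.0, same_side=False,
                       basilar_arc_deg=45.0),
    "Lambda": dict(angle_deg=52.0, arc_dom=8.0, arc_non=-30.0, same_side=False,
                   basilar_arc_deg=40.0, dominant_offset_deg=2.0),
}


def build_class_geometry(
    geometry_class: str,
    radii: Optional[Dict[str, float]] = None,
    dominant_side: str = "RV",
    angle_deg: Optional[float] = None,
    vertebral_length: float = 28e-3,
    basilar_length: float = 22e-3,
    basilar_arc_deg: Optional[float] = None,
    vertebral_arc_deg: Optional[tuple] = None,
    n_points: int = 161,
) -> ConfluenceGeometry:
    """Construct a confluence geometry of one of the three classes.

    Classes are realised in a canonical frame (basilar starts along +z at
    the apex; vertebral approach plane is x-z; bends are about the y axis):

    * Walking: both vertebrals arc in the same direction and the basilar
      continues out of their arcs;
    * TuningFork: mirror-symmetric vertebral approach angles, opposite
      bends;
    * Lambda: the dominant vertebral is nearly collinear with the basilar
      (< 5 deg); the minor vertebral abuts at a wide angle, a pseudo
      T-junction.

    The basilar carries a gentle planar curve (its arc angle is a
    parameter) so Dean-type secondary flow develops as it does in vivo.
    Raises if the requested parameters give self-intersecting vertebral
    tubes away from the junction.
    """
    if geometry_class not in _CLASS_DEFAULTS:
        raise ValueError(f"unknown geometry class {geometry_class!r}")
    if dominant_side not in ("LV", "RV"):
        raise ValueError("dominant_side must be 'LV' or 'RV'")
    p = dict(_CLASS_DEFAULTS[geometry_class])
    if angle_deg is not None:
        p["angle_deg"] = angle_deg
    if basilar_arc_deg is not None:
        p["basilar_arc_deg"] = basilar_arc_deg
    if vertebral_arc_deg is not None:
        p["arc_dom"], p["arc_non"] = vertebral_arc_deg
    radii = dict(radii or {})
    r_dom = radii.get(dominant_side, 1.7e-3)
    r_non = radii.get("LV" if dominant_side == "RV" else "RV", 1.4e-3)
    r_bas = radii.get("BAS", 1.62e-3)

    apex = np.zeros(3)
    b0 = np.array([0.0, 0.0, 1.0])
    theta = np.radians(p["angle_deg"])
    y = np.array([0.0, 1.0, 0.0])

    if geometry_class == "Lambda":
        off = np.radians(p.get("dominant_offset_deg", 2.0))
        d_dom = rotation_matrix(y, off) @ b0
        d_non = rotation_matrix(y, -(theta - off)) @ b0
    else:
        d_dom = rotation_matrix(y, theta / 2.0) @ b0
        d_non = rotation_matrix(y, -theta / 2.0) @ b0

    arc_dom = np.radians(p["arc_dom"])
    arc_non = np.radians(p["arc_non"])
    if geometry_class == "Walking":
        arc_non = abs(arc_non) * np.sign(arc_dom if arc_dom != 0 else 1.0)

    # keep the terminal two diameters straight so the approach tangents (and
    # hence the confluence angle) are well defined at the junction
    tail_dom = 4.0 * r_dom
    tail_non = 4.0 * r_non
    pts_dom = _integrate_arc(
        apex, d_dom, vertebral_length, arc_dom, y, n_points, straight_run=tail_dom
    )
    pts_non = _integrate_arc(
        apex, d_non, vertebral_length, arc_non, y, n_points, straight_run=tail_non
    )
    bas_arc = np.radians(p["basilar_arc_deg"])
    pts_bas = _integrate_arc(
        apex, b0, basilar_length, bas_arc, y, n_points,
        downstream_of_end=True, straight_run=2.0 * r_bas,
    )

    dom_label, non_label = dominant_side, ("LV" if dominant_side == "RV" else "RV")
    branches = {
        dom_label: Centerline(pts_dom, r_dom),
        non_label: Centerline(pts_non, r_non),
        "BAS": Centerline(pts_bas, r_bas),
    }
    geom = ConfluenceGeometry(
        branches=branches,
        apex=apex,
        geometry_class=geometry_class,
        construction_angle_deg=float(
            np.degrees(np.arccos(np.clip(np.dot(d_dom, d_non), -1, 1)))
        ),
        dominant_side=dominant_side,
    )
    _check_self_intersection(geom)
    return geom


def make_tube_geometry(
    radius: float = 1.5e-3,
    length: float = 12e-3,
    direction: np.ndarray = (0.0, 0.0, 1.0),
    n_points: int = 81,
) -> ConfluenceGeometry:
    """Single straight tube as a one-inlet geometry (solver validation)."""
    d = _unit(np.asarray(direction, dtype=float))
    apex = np.zeros(3)
    s = np.linspace(0.0, length / 2.0, n_points)
    pts_in = apex + (s - length / 2.0)[:, None] * d
    pts_out = apex + s[:, None] * d
    return ConfluenceGeometry(
        branches={
            "LV": Centerline(pts_in, radius),
            "BAS": Centerline(pts_out, radius),
        },
        apex=apex,
    )


def make_curved_tube_geometry(
    radius: float = 1.5e-3,
    bend_radius: float = 7.5e-3,
    arc_deg: float = 90.0,
    entry_length: float = 6e-3,
    exit_length: float = 6e-3,
    n_points: int = 121,
) -> ConfluenceGeometry:
    """Straight entry, circular bend, straight exit ending along +z.

    The classical curved-pipe (Dean flow) validation geometry: flow enters
    along +x, turns ``arc_deg`` about the y axis, and leaves along +z
    (ready for the solver's outlet convention).
    """
    arc = np.radians(arc_deg)
    y = np.array([0.0, 1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    # build backwards from the outlet: straight exit along +z, then the arc
    bas_pts = _integrate_arc(
        np.zeros(3), z, bend_radius * arc + exit_length, -arc, y,
        n_points, downstream_of_end=False, straight_run=exit_length,
    )
    # apex is the start of the arc; entry runs straight along the arc's
    # initial tangent
    apex = bas_pts[0]
    t0 = _unit(bas_pts[1] - bas_pts[0])
    s = np.linspace(-entry_length, 0.0, max(2, n_points // 2))
    lv_pts = apex + s[:, None] * t0
    bas = Centerline(bas_pts - apex, radius)
    lv = Centerline(lv_pts - apex, radius)
    return ConfluenceGeometry(branches={"LV": lv, "BAS": bas}, apex=np.zeros(3))


def _check_self_intersection(geom: ConfluenceGeometry) -> None:
    """Vertebral tubes must not overlap away from the junction blend."""
    lv, rv = geom.branches["LV"], geom.branches["RV"]
    clearance = 2.0 * (lv.radius.max() + rv.radius.max())
    sel_l = lv.arc_length < lv.length - clearance
    sel_r = rv.arc_length < rv.length - clearance
    if sel_l.sum() < 2 or sel_r.sum() < 2:
        return
    d = cKDTree(lv.points[sel_l]).query(rv.points[sel_r])[0]
    min_allowed = 0.95 * (float(lv.radius.max()) + float(rv.radius.max()))
    if d.min() < min_allowed:
        raise ValueError(
            "self-intersecting tubes: vertebral centerlines approach within "
            f"{d.min():.2e} m away from the junction"
        )


# ---------------------------------------------------------------------------
# classification and measurement
# ---------------------------------------------------------------------------

def classify_configuration(
    geom: ConfluenceGeometry,
    lambda_tight_deg: float = 20.0,
    lambda_wide_deg: float = 40.0,
    curvature_floor: float = 2.0,
) -> str:
    """Classify a confluence as Walking, TuningFork, or Lambda.

    Decision rules, evaluated in fixed precedence:

    1. Lambda if one vertebral's terminal tangent deviates less than
       ``lambda_tight_deg`` from the basilar's initial tangent while the
       other deviates more than ``lambda_wide_deg``;
    2. Walking if the two vertebrals bend the same way over their distal
       thirds (signs of their binormals, projected on a shared reference
       normal, agree) with curvature above ``curvature_floor`` (1/m);
    3. otherwise TuningFork.

    The rules use only relative tangents and curvature signs, so the result
    is invariant under rigid motion and mirror reflection.
    """
    if set(geom.branch_names) != set(BRANCHES):
        raise ValueError("classification needs all three branches (LV, RV, BAS)")
    for b in BRANCHES:
        c = geom.branches[b]
        if c.n_points < 10:
            raise ValueError(f"branch {b} has fewer than 10 centerline points")
        if c.length < 4 * float(c.radius.mean()):
            raise ValueError(f"branch {b} is degenerately short")
    bas0 = geom.branches["BAS"].tangent_at(0.0)
    dev = {}
    for b in ("LV", "RV"):
        t_end = geom.branches[b].mean_tangent(
            geom.branches[b].length - 2 * float(geom.branches[b].radius.mean()),
            geom.branches[b].length,
        )
        dev[b] = np.degrees(np.arccos(np.clip(np.dot(t_end, bas0), -1, 1)))
    lo, hi = min(dev.values()), max(dev.values())
    if lo < lambda_tight_deg and hi > lambda_wide_deg:
        return "Lambda"

    t_lv = geom.branches["LV"].tangent_at(geom.branches["LV"].length)
    t_rv = geom.branches["RV"].tangent_at(geom.branches["RV"].length)
    n_ref = np.cross(t_lv, t_rv)
    if np.linalg.norm(n_ref) < 1e-6:
        n_ref = np.cross(t_lv, bas0)
    if np.linalg.norm(n_ref) < 1e-6:
        return "TuningFork"
    n_ref = _unit(n_ref)

    signs = []
    for b in ("LV", "RV"):
        c = geom.branches[b].resampled(n=90)
        third = c.arc_length >= 2.0 * c.length / 3.0
        t = c.tangents()[third]
        k = c.curvature_vectors()[third]
        binormal = np.cross(t, k).mean(axis=0)
        mean_curv = np.linalg.norm(k, axis=1).mean()
        if mean_curv < curvature_floor:
            signs.append(0.0)
        else:
            signs.append(np.sign(np.dot(binormal, n_ref)))
    if signs[0] != 0 and signs[0] == signs[1]:
        return "Walking"
    return "TuningFork"


def confluence_angle(geom: ConfluenceGeometry, n_diameters: float = 2.0) -> float:
    """Angle (degrees) between the LV and RV flow directions at the junction.

    Each vertebral's tangent is averaged over the segment of length
    ``n_diameters`` local diameters ending at the apex, which stabilises the
    estimate against discrete noise.
    """
    t = {}
    for b in ("LV", "RV"):
        c = geom.branches[b]
        seg = n_diameters * 2.0 * float(c.radius[-1])
        if seg > c.length:
            raise ValueError(
                f"averaging segment {seg:.1e} m exceeds branch {b} length {c.length:.1e} m"
            )
        t[b] = c.mean_tangent(c.length - seg, c.length)
    return float(np.degrees(np.arccos(np.clip(np.dot(t["LV"], t["RV"]), -1.0, 1.0))))


def curvature_and_wall_orientation(
    geom: ConfluenceGeometry, branch: str, curvature_floor: float = 0.5
):
    """Per-station curvature magnitude and outer-wall direction of a branch.

    Returns ``(stations, curvature, outer_dir, flat)``: arc-length stations,
    discrete Frenet curvature (1/m), the unit outer-wall direction
    (-principal normal; the wall the flow is flung towards), and a flag
    marking stations whose curvature is below ``curvature_floor`` (1/m),
    where the outer-wall direction is undefined.
    """
    if branch not in geom.branches:
        raise KeyError(f"no branch {branch!r}")
    c = geom.branches[branch].resampled(n=max(90, geom.branches[branch].n_points))
    k = c.curvature_vectors()
    mag = np.linalg.norm(k, axis=1)
    flat = mag < curvature_floor
    outer = np.zeros_like(k)
    nz = ~flat
    outer[nz] = -k[nz] / mag[nz, None]
    return c.arc_length, mag, outer, flat


# ---------------------------------------------------------------------------
# flow extensions and computational domain
# ---------------------------------------------------------------------------

def reynolds_number(flow: float, diameter: float, fluid) -> float:
    """Tube Reynolds number rho U D / mu at mean velocity U = Q / (pi D^2/4)."""
    area = np.pi * diameter**2 / 4.0
    return fluid.density * (flow / area) * diameter / fluid.viscosity


def extrude_flow_extensions(
    geom: ConfluenceGeometry,
    peak_flows: Dict[str, float],
    fluid,
    policy: str = "developed",
    outlet_diameters: float = 3.0,
) -> ConfluenceGeometry:
    """Append straight entrance/exit segments so boundary flow is developed.

    Inlet extensions run upstream along each vertebral's initial tangent
    with length ``max(0.06 Re D, 3D)`` (laminar development length) under
    the default 'developed' policy, or the 3-diameter floor under the
    'profile' policy (appropriate when the inlet carries an analytic
    fully-developed profile).  The basilar outlet gets ``outlet_diameters``
    diameters.  ``peak_flows`` maps 'LV'/'RV' to peak systolic flow in
    m^3/s.
    """
    if policy not in ("developed", "profile"):
        raise ValueError("policy must be 'developed' or 'profile'")
    new = {}
    ext = {}
    for b in geom.inlet_branches:
        c = geom.branches[b]
        D = 2.0 * float(c.radius[0])
        if policy == "developed":
            q = peak_flows[b]
            if q < 0:
                raise ValueError("peak flows must be nonnegative")
            L = max(0.06 * reynolds_number(q, D, fluid) * D, 3.0 * D)
        else:
            L = 3.0 * D
        t0 = c.tangent_at(0.0)
        n_ext = max(4, int(np.ceil(L / (c.length / c.n_points))))
        s_ext = np.linspace(-L, 0.0, n_ext, endpoint=False)
        pts = np.vstack([c.points[0] + s_ext[:, None] * t0, c.points])
        rad = np.concatenate([np.full(n_ext, c.radius[0]), c.radius])
        new[b] = Centerline(pts, rad)
        ext[b] = L
    c = geom.branches["BAS"]
    D = 2.0 * float(c.radius[-1])
    L = outlet_diameters * D
    t1 = c.tangent_at(c.length)
    n_ext = max(4, int(np.ceil(L / (c.length / c.n_points))))
    s_ext = np.linspace(0.0, L, n_ext + 1)[1:]
    pts = np.vstack([c.points, c.points[-1] + s_ext[:, None] * t1])
    rad = np.concatenate([c.radius, np.full(n_ext, c.radius[-1])])
    new["BAS"] = Centerline(pts, rad)
    ext["BAS"] = L
    return ConfluenceGeometry(
        branches=new,
        apex=geom.apex.copy(),
        geometry_class=geom.geometry_class,
        construction_angle_deg=geom.construction_angle_deg,
        dominant_side=geom.dominant_side,
        extension_lengths=ext,
    )


@dataclass
class Disc:
    """Circular inlet/outlet plane: center, unit normal (downstream), radius."""

    center: np.ndarray
    normal: np.ndarray
    radius: float
    branch: str


@dataclass
class ComputationalDomain:
    """Masked uniform-grid domain for the flow solver.

    ``phi`` is the signed distance at cell centres (negative inside the
    lumen); ``cell_type`` is 0 solid, 1 fluid, 2 inlet (prescribed
    velocity), 3 outlet (reference pressure).  The geometry stored here has
    been rigidly rotated so the basilar outlet points along +z and the
    outlet cap coincides with the top grid face.
    """

    origin: np.ndarray
    h: float
    shape: tuple
    phi: np.ndarray
    cell_type: np.ndarray
    branch_id: np.ndarray  # nearest-branch index into BRANCHES per cell
    arc_s: np.ndarray  # arc-length station of the nearest branch point per cell
    geometry: ConfluenceGeometry
    rotation: np.ndarray
    inlet_discs: Dict[str, Disc]
    outlet_disc: Disc
    wall_verts: np.ndarray
    wall_faces: np.ndarray
    wall_normals: np.ndarray
    wall_branch: np.ndarray
    wall_s: np.ndarray
    wall_valid: np.ndarray

    CELL_SOLID, CELL_FLUID, CELL_INLET, CELL_OUTLET = 0, 1, 2, 3

    @property
    def n_lumen_cells(self) -> int:
        return int((self.cell_type > 0).sum())

    def lumen_volume(self) -> float:
        return self.n_lumen_cells * self.h**3

    def cell_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.h

    def wall_sample_areas(self) -> np.ndarray:
        """Per-vertex surface area (one third of each incident triangle)."""
        v, f = self.wall_verts, self.wall_faces
        tri = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        a = 0.5 * np.linalg.norm(tri, axis=1)
        areas = np.zeros(v.shape[0])
        np.add.at(areas, f.ravel(), np.repeat(a / 3.0, 3))
        return areas


def build_computational_domain(
    geom: ConfluenceGeometry,
    grid_spacing: float,
    inlet_zone_cells: int = 4,
    min_cells_per_diameter: int = 5,
) -> ComputationalDomain:
    """Discretise an (extended) confluence geometry onto a uniform grid.

    The geometry is rotated so the basilar terminal tangent aligns with +z
    and the grid top face caps the outlet.  Raises when the grid cannot
    resolve the smallest vessel with ``min_cells_per_diameter`` cells.
    """
    h = float(grid_spacing)
    rmin = min(float(c.radius.min()) for c in geom.branches.values())
    if 2.0 * rmin / h < min_cells_per_diameter:
        raise ValueError(
            f"grid spacing {h:.2e} m under-resolves diameter {2*rmin:.2e} m; "
            f"need spacing <= {2*rmin/min_cells_per_diameter:.2e} m"
        )
    bas = geom.branches["BAS"]
    R = rotation_aligning(bas.tangent_at(bas.length), np.array([0.0, 0.0, 1.0]))
    g = geom.transformed(R)

    lo, hi = g.bounds(margin=3 * h)
    # cap the top exactly at the basilar end plane
    z_top = g.branches["BAS"].points[-1][2]
    hi[2] = z_top
    shape = tuple(np.ceil((hi - lo) / h).astype(int))
    origin = hi - np.array(shape) * h  # anchor the top face at z_top
    axes = [origin[i] + (np.arange(shape[i]) + 0.5) * h for i in range(3)]
    cc = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    phi, bid, arcs = g.signed_distance(cc, info=True)
    phi = phi.reshape(shape)
    bid = bid.reshape(shape)
    arcs = arcs.reshape(shape)

    names = g.branch_names
    bas_idx = names.index("BAS")
    cell_type = np.zeros(shape, dtype=np.uint8)
    fluid = phi < 0
    cell_type[fluid] = ComputationalDomain.CELL_FLUID
    zone = inlet_zone_cells * h
    for b in g.inlet_branches:
        sel = fluid & (bid == names.index(b)) & (arcs <= zone)
        cell_type[sel] = ComputationalDomain.CELL_INLET
    bas_len = g.branches["BAS"].length
    sel = fluid & (bid == bas_idx) & (arcs >= bas_len - 1.5 * h)
    cell_type[sel] = ComputationalDomain.CELL_OUTLET

    inlet_discs = {}
    for b in g.inlet_branches:
        c = g.branches[b]
        s0 = zone
        inlet_discs[b] = Disc(
            center=c.point_at(s0),
            normal=c.tangent_at(s0),
            radius=c.radius_at(s0),
            branch=b,
        )
    outlet_disc = Disc(
        center=g.branches["BAS"].point_at(bas_len),
        normal=np.array([0.0, 0.0, 1.0]),
        radius=g.branches["BAS"].radius_at(bas_len),
        branch="BAS",
    )

    verts, faces, normals = _wall_mesh(phi, origin, h)
    _, vb, vs = g.signed_distance(verts, info=True)
    valid = np.ones(verts.shape[0], dtype=bool)
    for b in g.inlet_branches:
        guard = zone + 2.0 * float(g.branches[b].radius[0])
        valid &= ~((vb == names.index(b)) & (vs <= guard))
    valid &= ~(
        (vb == bas_idx) & (vs >= bas_len - 2.0 * float(g.branches["BAS"].radius[-1]))
    )
    # drop cap artefacts: vertices on the boundary box faces
    eps = 0.51 * h
    top = origin + np.array(shape) * h
    for ax in range(3):
        valid &= verts[:, ax] > origin[ax] + eps
        valid &= verts[:, ax] < top[ax] - eps

    return ComputationalDomain(
        origin=origin,
        h=h,
        shape=shape,
        phi=phi,
        cell_type=cell_type,
        branch_id=bid,
        arc_s=arcs,
        geometry=g,
        rotation=R,
        inlet_discs=inlet_discs,
        outlet_disc=outlet_disc,
        wall_verts=verts,
        wall_faces=faces,
        wall_normals=normals,
        wall_branch=vb,
        wall_s=vs,
        wall_valid=valid,
    )


def _wall_mesh(phi: np.ndarray, origin: np.ndarray, h: float):
    from skimage.measure import marching_cubes

    verts, faces, normals, _ = marching_cubes(phi, level=0.0, spacing=(h, h, h))
    verts = verts + origin + 0.5 * h  # phi sampled at cell centres
    # marching_cubes normals point down-gradient (inward); flip outward
    normals = -normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return verts, faces, normals


# ---------------------------------------------------------------------------
# cross sections
# ---------------------------------------------------------------------------

@dataclass
class CrossSection:
    """In-plane lumen sampling at one station along a branch."""

    branch: str
    station: float
    center: np.ndarray
    normal: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    coords: np.ndarray  # (n, n, 3) world coordinates of the plane grid
    mask: np.ndarray
    pixel_size: float
    outer_wall_dir: Optional[np.ndarray]  # 3-D unit vector, None where flat

    @property
    def area(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2

    def in_plane(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.center
        return np.stack([rel @ self.e1, rel @ self.e2], axis=-1)


def sample_cross_sections(
    geom: ConfluenceGeometry,
    branch: str,
    stations: Sequence[float],
    n: int = 41,
    half_width_factor: float = 2.2,
) -> list:
    """Planes orthogonal to a branch centerline with in-plane lumen masks.

    Stations are arc lengths along the branch; a station out of range
    raises.  The outer-wall direction (towards the outside of the local
    curve) is attached where the local curvature is significant.
    """
    c = geom.branches[branch]
    s_arr, curv, outer, flat = curvature_and_wall_orientation(geom, branch)
    out = []
    for s in stations:
        if s < -1e-12 or s > c.length + 1e-12:
            raise ValueError(f"station {s} outside branch length {c.length}")
        center = c.point_at(s)
        normal = c.tangent_at(s)
        i = int(np.argmin(np.abs(s_arr - s)))
        odir = None if flat[i] else outer[i]
        if odir is not None:
            e1 = _unit(odir - np.dot(odir, normal) * normal)
        else:
            trial = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(trial, normal)) > 0.9:
                trial = np.array([0.0, 1.0, 0.0])
            e1 = _unit(trial - np.dot(trial, normal) * normal)
        e2 = np.cross(normal, e1)
        half = half_width_factor * c.radius_at(s)
        px = 2 * half / (n - 1)
        u = np.linspace(-half, half, n)
        uu, vv = np.meshgrid(u, u, indexing="ij")
        coords = center + uu[..., None] * e1 + vv[..., None] * e2
        mask = (geom.signed_distance(coords.reshape(-1, 3)) < 0).reshape(n, n)
        out.append(
            CrossSection(
                branch=branch,
                station=float(s),
                center=center,
                normal=normal,
                e1=e1,
                e2=e2,
                coords=coords,
                mask=mask,
                pixel_size=px,
                outer_wall_dir=odir,
            )
        )
    return out
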
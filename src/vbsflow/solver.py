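"""Pulsatile incompressible Newtonian flow on a masked Cartesian grid.

A from-scratch fractional-step (projection) solver with the boundary
conditions of the study it emulates: rigid no-slip walls, prescribed
(fully developed) velocity at the two vertebral inlets, and a traction-free
basilar outlet (zero normal velocity gradient with a fixed reference
pressure).  Space is discretised on a uniform staggered (MAC) grid whose
cells come from the signed-distance computational domain; viscous stencils
next to the wall use the sub-grid wall distance from the signed-distance
field, while advection is second-order upwind.  Time stepping is explicit
with internal sub-cycling to the advective CFL limit: at blood viscosity
and the resolutions used here the diffusive limit is never the binding one,
so implicit viscosity would buy nothing.

Pulsatile runs mirror the study protocol: initialisation from a steady
solve at the cycle-start flows, a fixed number of output steps per cardiac
cycle (default 500), and several cycles (default 3) whose inter-cycle
velocity difference verifies periodic convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu

from . import _kernels as K
from .geometry import ComputationalDomain
from .waveforms import FlowWaveform
from .womersley import WomersleyProfile, flow_harmonics, womersley_profile


@dataclass(frozen=True)
class FluidProperties:
    """Blood-like Newtonian fluid constants (SI units)."""

    density: float = 1053.0  # kg/m^3
    viscosity: float = 0.00368  # kg/(m s)

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass
class SolverConfig:
    """Numerical settings of the flow solver.

    ``steps_per_cycle`` and ``n_cycles`` follow the study protocol (500
    steps over the pulse cycle, three cycles).  ``steady_tolerance`` is the
    dimensionless residual max|du|/(dt U^2/D) below which a steady march is
    accepted.  ``field_stride`` controls how many of the final cycle's
    fields are retained (every ``field_stride``-th output step).
    """

    steps_per_cycle: int = 500
    n_cycles: int = 3
    inlet_profile_kind: str = "womersley"
    pressure_tolerance: float = 1e-10
    steady_tolerance: float = 1e-3
    cfl_limit: float = 0.4
    grid_spacing: Optional[float] = None
    max_steady_iters: int = 40000
    field_stride: int = 10
    n_harmonics: int = 10

    def __post_init__(self) -> None:
        if self.steps_per_cycle < 50:
            raise ValueError("steps_per_cycle must be >= 50")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if min(self.pressure_tolerance, self.steady_tolerance, self.cfl_limit) <= 0:
            raise ValueError("tolerances and cfl_limit must be positive")
        if self.inlet_profile_kind not in ("poiseuille", "womersley"):
            raise ValueError("inlet_profile_kind must be 'poiseuille' or 'womersley'")


@dataclass
class FlowField:
    """Velocity + pressure snapshot on the staggered grid at one time."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    time: float
    domain: ComputationalDomain

    def copy(self) -> "FlowField":
        return FlowField(
            self.u.copy(), self.v.copy(), self.w.copy(), self.p.copy(),
            self.time, self.domain,
        )

    def cell_center_velocity(self) -> np.ndarray:
        """(nx, ny, nz, 3) velocity averaged to cell centres."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return np.stack([uc, vc, wc], axis=-1)

    def interpolator(self, method: str = "linear"):
        """Velocity interpolator: callable points(N,3) -> (N,3).

        ``method='cubic'`` reproduces smooth profiles without the chord
        bias of trilinear interpolation (used for profile measurements).
        """
        from scipy.interpolate import RegularGridInterpolator

        d = self.domain
        h, o = d.h, d.origin
        nx, ny, nz = d.shape
        xc = o[0] + (np.arange(nx) + 0.5) * h
        yc = o[1] + (np.arange(ny) + 0.5) * h
        zc = o[2] + (np.arange(nz) + 0.5) * h
        xf = o[0] + np.arange(nx + 1) * h
        yf = o[1] + np.arange(ny + 1) * h
        zf = o[2] + np.arange(nz + 1) * h
        fu = RegularGridInterpolator((xf, yc, zc), self.u, method=method,
                                     bounds_error=False, fill_value=0.0)
        fv = RegularGridInterpolator((xc, yf, zc), self.v, method=method,
                                     bounds_error=False, fill_value=0.0)
        fw = RegularGridInterpolator((xc, yc, zf), self.w, method=method,
                                     bounds_error=False, fill_value=0.0)

        def _eval(points):
            pts = np.atleast_2d(np.asarray(points, dtype=float))
            return np.stack([fu(pts), fv(pts), fw(pts)], axis=-1)

        return _eval

    def kinetic_energy(self, density: float = 1053.0) -> float:
        d = self.domain
        vel = self.cell_center_velocity()
        inside = d.cell_type > 0
        return float(
            0.5 * density * (np.sum(vel[inside] ** 2)) * d.h**3
        )


@dataclass
class CycleDiagnostics:
    """Per-cycle convergence bookkeeping of a pulsatile run."""

    mass_imbalance: list = field(default_factory=list)  # per output step, final cycle
    inter_cycle_difference: list = field(default_factory=list)  # per cycle >= 2
    steady_residual_history: Optional[np.ndarray] = None


class SolverError(RuntimeError):
    def __init__(self, message: str, history: Optional[np.ndarray] = None):
        super().__init__(message)
        self.history = history


# ---------------------------------------------------------------------------
# inlet machinery
# ---------------------------------------------------------------------------

class InletZone:
    """Prescribed-velocity realisation of a mass-flow inlet.

    The first cells of an inlet extension carry an analytic fully developed
    axial profile (Poiseuille or Womersley); after sampling on the grid the
    face velocities are rescaled so the discrete flux crossing into the
    free fluid equals the requested flow rate exactly.
    """

    def __init__(self, solver: "MaskedGridSolver", branch: str):
        self.branch = branch
        d = solver.domain
        disc = d.inlet_discs[branch]
        if 2.0 * disc.radius / d.h < 5.0:
            raise ValueError(
                f"inlet {branch} under-resolved: "
                f"{2*disc.radius/d.h:.1f} cells across the diameter (< 5)"
            )
        self.direction = np.asarray(disc.normal, dtype=float)
        self.radius = float(disc.radius)
        c = d.geometry.branches[branch]
        p0 = c.points[0]
        axis = c.tangent_at(0.0)
        bi = d.geometry.branch_names.index(branch)
        self.faces = {}
        for comp in range(3):
            st = solver.face_state[comp]
            sel = np.nonzero(
                (st == K.FACE_PRESCRIBED) & (solver.face_branch[comp] == bi)
            )
            pos = solver._face_positions(comp, sel)
            rel = pos - p0
            axial = rel @ axis
            rad = np.linalg.norm(rel - axial[:, None] * axis, axis=1)
            self.faces[comp] = (sel, rad, self.direction[comp])
        # interface faces: prescribed faces adjacent to a free-fluid cell
        self.interface = zone_interface_faces(d, K.CELL_INLET, bi)
        self._harm_coefs = None
        self._profile: Optional[WomersleyProfile] = None

    def set_waveform(self, waveform: FlowWaveform, fluid: FluidProperties,
                     n_harmonics: int, kind: str) -> None:
        harm = flow_harmonics(waveform.values * 1e-6, n_harmonics)  # m^3/s
        self._profile = womersley_profile(self.radius, harm, fluid, waveform.period)
        self.kind = kind
        self._q_interp = waveform.interpolator()
        if kind == "womersley":
            self._harm_coefs = {}
            for comp, (sel, rad, dcomp) in self.faces.items():
                rr = np.minimum(rad, self.radius)
                prof = self._profile
                base = 2.0 * harm[0].real / (np.pi * self.radius**2) * (
                    1.0 - (rr / self.radius) ** 2
                )
                coefs = [
                    (harm[k] / prof._flux_factor(k)) * prof._shape(k, rr)
                    for k in range(1, harm.size)
                ]
                self._harm_coefs[comp] = (np.array(coefs), base)

    def target_flow(self, t: float) -> float:
        """Requested flow (m^3/s) at time t of the configured waveform."""
        if self.kind == "womersley" and self._profile is not None:
            return float(self._profile.flow_rate(np.asarray(t)))
        return float(self._q_interp(t)) * 1e-6

    def raw_values(self, comp: int, t: float) -> np.ndarray:
        """Unscaled profile sample at the faces of one component."""
        sel, rad, dcomp = self.faces[comp]
        if self.kind == "womersley":
            coefs, base = self._harm_coefs[comp]
            vals = base.copy()
            if coefs.shape[0]:
                omega = self._profile.omega
                ks = np.arange(1, coefs.shape[0] + 1)
                phases = np.exp(1j * ks * omega * t)
                vals = vals + 2.0 * np.real(phases @ coefs)
        else:
            q = self.target_flow(t)
            rr = np.minimum(rad, self.radius)
            vals = 2.0 * q / (np.pi * self.radius**2) * (1.0 - (rr / self.radius) ** 2)
        vals = np.where(rad <= self.radius, vals, 0.0)
        return dcomp * vals

    def apply(self, vel: list, t: float, flow_override: Optional[float] = None) -> float:
        """Write scaled profile values into the face arrays; returns Q used."""
        raws = {comp: self.raw_values(comp, t) for comp in range(3)}
        q_target = flow_override if flow_override is not None else self.target_flow(t)
        flux = self._interface_flux_from_raw(raws)
        scale = q_target / flux if abs(flux) > 1e-300 else 0.0
        for comp in range(3):
            sel, rad, dcomp = self.faces[comp]
            vel[comp][sel] = scale * raws[comp]
        return q_target

    def _interface_flux_from_raw(self, raws: dict) -> float:
        h2 = self._h2
        total = 0.0
        for comp, idx, sign in self.interface_compact:
            # map interface faces into this zone's prescribed-face ordering
            vals = raws[comp][idx]
            total += np.sum(sign * vals) * h2
        return total

    def finalize(self, solver: "MaskedGridSolver") -> None:
        """Precompute the interface-face positions within the zone arrays."""
        self._h2 = solver.domain.h**2
        self.interface_compact = []
        for comp in range(3):
            sel, rad, dcomp = self.faces[comp]
            key = {(a, b, c): n for n, (a, b, c) in enumerate(zip(*sel))}
            idx, signs = [], []
            for fcomp, i, j, k, sign in self.interface:
                if fcomp != comp:
                    continue
                n = key.get((i, j, k))
                if n is not None:
                    idx.append(n)
                    signs.append(sign)
            self.interface_compact.append(
                (comp, np.array(idx, dtype=int), np.array(signs, dtype=float))
            )

    def measured_flux(self, vel: list) -> float:
        """Discrete flux (m^3/s) crossing from the zone into the free fluid."""
        h2 = self._h2
        total = 0.0
        for comp, i, j, k, sign in self.interface:
            total += sign * vel[comp][i, j, k] * h2
        return total


def inlet_velocity_bc(
    domain: ComputationalDomain,
    branch: str,
    flow: float,
    kind: str = "poiseuille",
    fluid: Optional[FluidProperties] = None,
    waveform: Optional[FlowWaveform] = None,
    t: float = 0.0,
    config: Optional[SolverConfig] = None,
):
    """Prescribed inlet face velocities for one inlet at one instant.

    Returns ``(zone, velocities)`` where ``velocities`` is the [u, v, w]
    face-array list holding the profile (zero elsewhere) whose grid-summed
    flux into the domain equals ``flow`` (m^3/s) exactly.
    """
    fluid = fluid or FluidProperties()
    config = config or SolverConfig()
    solver = MaskedGridSolver(domain, fluid, config)
    zone = solver.inlets[branch]
    if waveform is None:
        period = 1.0
        waveform = FlowWaveform(
            times=np.arange(500) / 500.0 * period,
            values=np.full(500, flow * 1e6),
            period=period,
        )
    zone.set_waveform(waveform, fluid, config.n_harmonics, kind)
    vel = [np.zeros_like(solver.u), np.zeros_like(solver.v), np.zeros_like(solver.w)]
    zone.apply(vel, t, flow_override=flow)
    return zone, vel


# ---------------------------------------------------------------------------
# main solver
# ---------------------------------------------------------------------------

def zone_interface_faces(d: ComputationalDomain, zone_cell_type: int,
                         branch_index: int) -> list:
    """Faces separating zone cells (of one branch) from free fluid cells.

    Returns ``(component, i, j, k, sign)`` tuples where ``sign`` makes
    ``sign * velocity`` positive for flow leaving the zone.
    """
    ct = d.cell_type
    bid = d.branch_id
    out = []
    for comp in range(3):
        for shift, sign in ((0, 1.0), (1, -1.0)):
            # face f sits between cells f-1 (low side) and f (high side)
            lo_sl = [slice(None)] * 3
            hi_sl = [slice(None)] * 3
            lo_sl[comp] = slice(0, -1)
            hi_sl[comp] = slice(1, None)
            a = ct[tuple(lo_sl)]
            b = ct[tuple(hi_sl)]
            if shift == 0:
                ba = bid[tuple(lo_sl)]
                selc = (a == zone_cell_type) & (ba == branch_index) & (
                    b == K.CELL_FLUID
                )
            else:
                bb = bid[tuple(hi_sl)]
                selc = (b == zone_cell_type) & (bb == branch_index) & (
                    a == K.CELL_FLUID
                )
            ii, jj, kk = np.nonzero(selc)
            idx = [ii, jj, kk]
            idx[comp] = idx[comp] + 1
            for i, j, k in zip(*idx):
                out.append((comp, int(i), int(j), int(k), sign))
    return out


class MaskedGridSolver:
    """Fractional-step solver bound to one computational domain."""

    def __init__(self, domain: ComputationalDomain, fluid: FluidProperties,
                 config: SolverConfig):
        self.domain = domain
        self.fluid = fluid
        self.config = config
        nx, ny, nz = domain.shape
        self.u = np.zeros((nx + 1, ny, nz))
        self.v = np.zeros((nx, ny + 1, nz))
        self.w = np.zeros((nx, ny, nz + 1))
        self.p = np.zeros(domain.shape)
        self._build_face_data()
        self._build_poisson()
        self.inlets = {b: InletZone(self, b) for b in domain.inlet_discs}
        for z in self.inlets.values():
            z.finalize(self)
        self._div = np.zeros(domain.shape)
        self._rhs_bufs = [np.zeros_like(self.u), np.zeros_like(self.v),
                          np.zeros_like(self.w)]
        self._prepare_transposed()

    # -- setup ------------------------------------------------------------

    def _face_positions(self, comp: int, sel) -> np.ndarray:
        d = self.domain
        o, h = d.origin, d.h
        idx = np.stack(sel, axis=-1).astype(float)
        offs = np.full(3, 0.5)
        offs[comp] = 0.0
        return o + (idx + offs) * h

    def _build_face_data(self) -> None:
        d = self.domain
        ct = d.cell_type
        self.face_state = []
        self.face_phi = []
        self.face_branch = []
        for comp in range(3):
            pad_shape = list(ct.shape)
            pad_shape[comp] += 2
            padded = np.zeros(pad_shape, dtype=np.uint8)  # CELL_SOLID outside
            sl = [slice(None)] * 3
            sl[comp] = slice(1, -1)
            padded[tuple(sl)] = ct
            lo = [slice(None)] * 3
            lo[comp] = slice(0, -1)
            hi = [slice(None)] * 3
            hi[comp] = slice(1, None)
            a, b = padded[tuple(lo)], padded[tuple(hi)]
            st = np.full(a.shape, K.FACE_SOLID, dtype=np.uint8)
            both_free = (a > 0) & (b > 0)
            st[both_free] = K.FACE_ACTIVE
            st[both_free & ((a == K.CELL_INLET) | (b == K.CELL_INLET))] = K.FACE_PRESCRIBED
            if comp == 2:
                # top outflow faces above outlet cells
                st[:, :, -1][ct[:, :, -1] == K.CELL_OUTLET] = K.FACE_OUTFLOW
            # signed distance and nearest branch at every face centre (solid
            # faces included: wall stencils read the neighbour's distance)
            sel = np.nonzero(np.ones(st.shape, dtype=bool))
            pos = self._face_positions(comp, sel)
            ph, bi, _ = d.geometry.signed_distance(pos, info=True)
            phi = ph.reshape(st.shape)
            bidf = bi.reshape(st.shape).astype(np.int8)
            # faces whose centre lies outside the lumen surface are walls,
            # even when both neighbour cell centres are inside (tight mask)
            st[(st == K.FACE_ACTIVE) & (phi >= 0.0)] = K.FACE_SOLID
            self.face_state.append(st)
            self.face_phi.append(phi)
            self.face_branch.append(bidf)
        self._outflow_idx = np.nonzero(
            self.face_state[2][:, :, -1] == K.FACE_OUTFLOW
        )

    def _build_poisson(self) -> None:
        d = self.domain
        ct = d.cell_type
        fluid_cells = np.nonzero(ct == K.CELL_FLUID)
        n = fluid_cells[0].size
        if n == 0:
            raise ValueError("domain has no free fluid cells")
        dof = -np.ones(ct.shape, dtype=np.int64)
        dof[fluid_cells] = np.arange(n)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        for comp in range(3):
            for dirn in (-1, 1):
                shift = np.zeros(3, dtype=int)
                shift[comp] = dirn
                ni = fluid_cells[0] + shift[0]
                nj = fluid_cells[1] + shift[1]
                nk = fluid_cells[2] + shift[2]
                inb = (
                    (ni >= 0) & (ni < ct.shape[0])
                    & (nj >= 0) & (nj < ct.shape[1])
                    & (nk >= 0) & (nk < ct.shape[2])
                )
                ntype = np.zeros(n, dtype=np.uint8)
                ntype[inb] = ct[ni[inb], nj[inb], nk[inb]]
                # the pressure link exists only through an ACTIVE face, so the
                # discrete Laplacian mirrors the correction stencil exactly
                fi = fluid_cells[0] + (shift[0] if dirn == 1 else 0)
                fj = fluid_cells[1] + (shift[1] if dirn == 1 else 0)
                fk = fluid_cells[2] + (shift[2] if dirn == 1 else 0)
                factive = self.face_state[comp][fi, fj, fk] == K.FACE_ACTIVE
                link = inb & (ntype == K.CELL_FLUID) & factive
                dirich = inb & (ntype == K.CELL_OUTLET) & factive
                diag += (link | dirich).astype(float)
                src = np.nonzero(link)[0]
                rows.append(src)
                cols.append(dof[ni[src], nj[src], nk[src]])
                vals.append(-np.ones(src.size))
        diag[diag == 0.0] = 1.0  # isolated cells: harmless identity rows
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ) / d.h**2
        self._dof = dof
        self._fluid_cells = fluid_cells
        self._lu = splu(A.tocsc())

    # -- stepping ---------------------------------------------------------

    def _apply_bcs(self, t: float, steady_flows: Optional[Dict[str, float]] = None):
        vel = [self.u, self.v, self.w]
        for comp in range(3):
            vel[comp][self.face_state[comp] == K.FACE_SOLID] = 0.0
        for b, zone in self.inlets.items():
            if steady_flows is not None:
                zone.apply(vel, t, flow_override=steady_flows[b])
            else:
                zone.apply(vel, t)
        ii, jj = self._outflow_idx
        self.w[ii, jj, -1] = self.w[ii, jj, -2]

    def _momentum(self, dt: float) -> None:
        nu = self.fluid.kinematic_viscosity
        h = self.domain.h
        u, v, w = self.u, self.v, self.w
        ru, rv, rw = self._rhs_bufs
        K.momentum_rhs(u, v, w, self.face_state[0], self.face_phi[0], h, nu, ru)
        K.momentum_rhs(
            np.ascontiguousarray(v.transpose(1, 0, 2)),
            np.ascontiguousarray(u.transpose(1, 0, 2)),
            np.ascontiguousarray(w.transpose(1, 0, 2)),
            self._st_t1, self._phi_t1, h, nu, self._buf_t1,
        )
        K.momentum_rhs(
            np.ascontiguousarray(w.transpose(2, 0, 1)),
            np.ascontiguousarray(u.transpose(2, 0, 1)),
            np.ascontiguousarray(v.transpose(2, 0, 1)),
            self._st_t2, self._phi_t2, h, nu, self._buf_t2,
        )
        rv[...] = self._buf_t1.transpose(1, 0, 2)
        rw[...] = self._buf_t2.transpose(1, 2, 0)
        self.u += dt * ru
        self.v += dt * rv
        self.w += dt * rw

    def _project(self, dt: float) -> None:
        d = self.domain
        K.divergence(self.u, self.v, self.w, d.cell_type, d.h, self._div)
        # matrix is assembled as -laplacian (positive definite)
        rhs = -self._div[self._fluid_cells] / dt
        phi = self._lu.solve(rhs)
        pc = np.zeros(d.shape)
        pc[self._fluid_cells] = phi
        K.correct_u(self.u, self.face_state[0], pc, d.h, dt)
        K.correct_v(self.v, self.face_state[1], pc, d.h, dt)
        K.correct_w(self.w, self.face_state[2], pc, d.h, dt)
        self.p = pc * self.fluid.density

    def _prepare_transposed(self) -> None:
        self._st_t1 = np.ascontiguousarray(self.face_state[1].transpose(1, 0, 2))
        self._phi_t1 = np.ascontiguousarray(self.face_phi[1].transpose(1, 0, 2))
        self._buf_t1 = np.zeros_like(self._st_t1, dtype=float)
        self._st_t2 = np.ascontiguousarray(self.face_state[2].transpose(2, 0, 1))
        self._phi_t2 = np.ascontiguousarray(self.face_phi[2].transpose(2, 0, 1))
        self._buf_t2 = np.zeros_like(self._st_t2, dtype=float)

    def _stable_dt(self) -> float:
        h = self.domain.h
        nu = self.fluid.kinematic_viscosity
        speed = max(
            float(np.abs(self.u).max()),
            float(np.abs(self.v).max()),
            float(np.abs(self.w).max()),
            1e-6,
        )
        # corner flows carry at most ~sqrt(3) of the largest component
        return self.config.cfl_limit * min(
            h / (np.sqrt(3.0) * speed), h**2 / (6.0 * nu)
        )

    def substep(self, t: float, dt: float,
                steady_flows: Optional[Dict[str, float]] = None) -> None:
        self._momentum(dt)
        self._apply_bcs(t + dt, steady_flows)
        self._project(dt)
        self._apply_bcs(t + dt, steady_flows)

    def field(self, t: float) -> FlowField:
        return FlowField(self.u.copy(), self.v.copy(), self.w.copy(),
                         self.p.copy(), t, self.domain)

    # -- initialisation ---------------------------------------------------

    def initialize_poiseuille(self, inlet_flows: Dict[str, float]) -> None:
        """Per-branch fully developed axial guess (then projected)."""
        d = self.domain
        q_b = dict(inlet_flows)
        q_b["BAS"] = sum(inlet_flows.values())
        tangents = {}
        for b in d.geometry.branch_names:
            c = d.geometry.branches[b].resampled(n=200)
            tangents[b] = (c.arc_length, c.tangents(), c)
        vel = [self.u, self.v, self.w]
        for comp in range(3):
            st = self.face_state[comp]
            sel = np.nonzero(st == K.FACE_ACTIVE)
            if sel[0].size == 0:
                continue
            pos = self._face_positions(comp, sel)
            phi, bi, ss = d.geometry.signed_distance(pos, info=True)
            vals = np.zeros(sel[0].size)
            for ib, b in enumerate(d.geometry.branch_names):
                m = bi == ib
                if not m.any():
                    continue
                s_arr, t_arr, c = tangents[b]
                tcomp = np.interp(ss[m], s_arr, t_arr[:, comp])
                R = np.interp(ss[m], c.arc_length, c.radius)
                r = np.clip(phi[m] + R, 0.0, R)  # distance from centerline
                vals[m] = tcomp * 2.0 * q_b[b] / (np.pi * R**2) * (1.0 - (r / R) ** 2)
            vel[comp][sel] = vals

    # -- top-level runs ---------------------------------------------------

    def run_steady(self, inlet_flows: Dict[str, float],
                   quiet: bool = True) -> FlowField:
        cfg = self.config
        d = self.domain
        U_ref = max(
            inlet_flows[b] / (np.pi * self.inlets[b].radius**2) for b in self.inlets
        )
        U_ref = max(U_ref, 1e-9)
        D_ref = 2.0 * min(self.inlets[b].radius for b in self.inlets)
        re = self.fluid.density * U_ref * D_ref / self.fluid.viscosity
        if re > 2000:
            warnings.warn(f"inlet Reynolds number {re:.0f} beyond laminar range")
        for b in self.inlets:
            self.inlets[b].set_waveform(
                FlowWaveform(np.arange(500) / 500.0, np.full(500, inlet_flows[b] * 1e6), 1.0),
                self.fluid, 1, "poiseuille",
            )
        self.initialize_poiseuille(inlet_flows)
        self._apply_bcs(0.0, steady_flows=inlet_flows)
        self._project(1.0)
        self._apply_bcs(0.0, steady_flows=inlet_flows)
        accel = U_ref**2 / D_ref
        history = []
        t = 0.0
        prev = None
        for it in range(cfg.max_steady_iters):
            dt = self._stable_dt()
            u_old = self.u.copy()
            self.substep(t, dt, steady_flows=inlet_flows)
            t += dt
            res = float(np.abs(self.u - u_old).max() / (dt * accel))
            history.append(res)
            if not np.isfinite(res):
                raise SolverError("steady march diverged (non-finite residual)",
                                  np.array(history))
            if res < cfg.steady_tolerance:
                return self.field(t)
            prev = res
        raise SolverError(
            f"steady solve did not converge in {cfg.max_steady_iters} iterations "
            f"(final residual {history[-1]:.3e})",
            np.array(history),
        )

    def run_pulsatile(
        self,
        inlet_waveforms: Dict[str, FlowWaveform],
        on_output_step: Optional[Callable] = None,
        store_stride: Optional[int] = None,
    ):
        cfg = self.config
        T = next(iter(inlet_waveforms.values())).period
        stride = store_stride or cfg.field_stride
        for b in self.inlets:
            self.inlets[b].set_waveform(
                inlet_waveforms[b], self.fluid, cfg.n_harmonics,
                cfg.inlet_profile_kind,
            )
        # steady initialisation at the cycle-start flows
        q0 = {b: self.inlets[b].target_flow(0.0) for b in self.inlets}
        steady = self.run_steady(q0)
        for b in self.inlets:
            self.inlets[b].set_waveform(
                inlet_waveforms[b], self.fluid, cfg.n_harmonics,
                cfg.inlet_profile_kind,
            )
        self._apply_bcs(0.0)

        dt_out = T / cfg.steps_per_cycle
        diags = CycleDiagnostics(steady_residual_history=getattr(steady, "history", None))
        prev_cycle_fields = None
        this_cycle_fields = []
        final_fields = []
        ke_limit = None
        for cycle in range(cfg.n_cycles):
            this_cycle_fields = []
            for step in range(cfg.steps_per_cycle):
                t0 = cycle * T + step * dt_out
                t1 = t0 + dt_out
                t = t0
                while t < t1 - 1e-15:
                    dt = min(self._stable_dt(), t1 - t)
                    self.substep(t, dt)
                    t += dt
                if not np.isfinite(self.u).all():
                    raise SolverError(
                        f"pulsatile run diverged at cycle {cycle}, step {step}"
                    )
                if (step + 1) % stride == 0:
                    this_cycle_fields.append(
                        (self.u.copy(), self.v.copy(), self.w.copy())
                    )
                last_cycle = cycle == cfg.n_cycles - 1
                if last_cycle:
                    diags.mass_imbalance.append(self.mass_imbalance())
                    fld = self.field(t1 - cycle * T)
                    final_fields.append(fld if (step + 1) % stride == 0 else None)
                    if on_output_step is not None:
                        on_output_step(self.field(t1 - cycle * T), step)
            if prev_cycle_fields is not None:
                num = den = 0.0
                for (ua, va, wa), (ub, vb, wb) in zip(prev_cycle_fields, this_cycle_fields):
                    num += np.sum((ua - ub) ** 2) + np.sum((va - vb) ** 2) + np.sum((wa - wb) ** 2)
                    den += np.sum(ub**2) + np.sum(vb**2) + np.sum(wb**2)
                diags.inter_cycle_difference.append(float(np.sqrt(num / max(den, 1e-300))))
            prev_cycle_fields = this_cycle_fields
        fields = [f for f in final_fields if f is not None]
        return fields, diags

    # -- diagnostics ------------------------------------------------------

    def mass_imbalance(self) -> float:
        vel = [self.u, self.v, self.w]
        q_in = sum(z.measured_flux(vel) for z in self.inlets.values())
        q_out = self._outlet_flux(vel)
        if abs(q_in) < 1e-300:
            return 0.0
        return float((q_in - q_out) / q_in)

    def _outlet_flux(self, vel: list) -> float:
        if not hasattr(self, "_outlet_interface"):
            self._outlet_interface = zone_interface_faces(
                self.domain, K.CELL_OUTLET,
                self.domain.geometry.branch_names.index("BAS"),
            )
        h2 = self.domain.h**2
        total = 0.0
        for comp, i, j, k, sign in self._outlet_interface:
            total += -sign * vel[comp][i, j, k] * h2  # sign flips: flux INTO outlet zone
        return total


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def solve_steady(
    domain: ComputationalDomain,
    inlet_flows: Dict[str, float],
    fluid: Optional[FluidProperties] = None,
    config: Optional[SolverConfig] = None,
) -> FlowField:
    """Steady flow at fixed inlet flow rates (m^3/s per inlet branch)."""
    fluid = fluid or FluidProperties()
    config = config or SolverConfig()
    solver = MaskedGridSolver(domain, fluid, config)
    return solver.run_steady(inlet_flows)


def solve_pulsatile(
    domain: ComputationalDomain,
    inlet_waveforms: Dict[str, FlowWaveform],
    fluid: Optional[FluidProperties] = None,
    config: Optional[SolverConfig] = None,
    on_output_step: Optional[Callable] = None,
):
    """Pulsatile run: steady initialisation, then n_cycles of the pulse.

    Returns ``(fields, diagnostics)``: the final cycle's stored fields
    (every ``config.field_stride``-th output step) and per-cycle
    diagnostics.  ``on_output_step(field, step)`` is called at every output
    step of the final cycle (e.g. to record wall shear stress).
    """
    fluid = fluid or FluidProperties()
    config = config or SolverConfig()
    solver = MaskedGridSolver(domain, fluid, config)
    return solver.run_pulsatile(inlet_waveforms, on_output_step=on_output_step)


def mass_balance(field: FlowField, domain: ComputationalDomain) -> float:
    """Relative (inflow - outflow)/inflow of a flow field; 0 for zero flow."""
    solver = getattr(field, "_solver", None)
    tmp = MaskedGridSolver(domain, FluidProperties(), SolverConfig())
    tmp.u, tmp.v, tmp.w = field.u, field.v, field.w
    return tmp.mass_imbalance()


def check_cycle_convergence(diagnostics: CycleDiagnostics,
                            tolerance: float = 1e-3):
    """Pass iff the final inter-cycle velocity difference is below tolerance."""
    if not diagnostics.inter_cycle_difference:
        raise ValueError("need at least 2 cycles to assess convergence")
    metric = diagnostics.inter_cycle_difference[-1]
    return metric < tolerance, metric
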
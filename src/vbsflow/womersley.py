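"""Analytic pulsatile pipe flow (Womersley solution).

The rigid-tube solution for fully developed pulsatile flow of a Newtonian
fluid driven by an oscillatory pressure gradient.  Each temporal harmonic k
of the flow rate Q(t) produces an axial velocity profile

    u_k(r) = C_k * [1 - J0(Lambda_k r/R) / J0(Lambda_k)],   Lambda_k = i^{3/2} alpha_k

with Womersley number ``alpha_k = R sqrt(k omega rho / mu)``.  The constant
C_k is fixed so that the cross-sectional integral of u_k reproduces the k-th
flow harmonic exactly.  The k = 0 term is the Poiseuille profile.

This module is the analytic oracle used for inlet boundary conditions, for
synthesising phase-contrast-MR-like velocity images, and for validating the
numerical solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv


def flow_harmonics(values: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Complex Fourier coefficients of a uniformly sampled periodic flow curve.

    Convention: ``Q(t) = c[0] + sum_{k>=1} 2 Re(c[k] exp(i k omega t))`` with
    ``omega = 2 pi / T``.  Input samples are assumed to cover exactly one
    period on a uniform grid starting at t = 0.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    c = np.fft.rfft(values) / n
    k = min(n_harmonics, c.size - 1)
    return c[: k + 1]


@dataclass
class WomersleyProfile:
    """Exact axial velocity field u(r, t) of pulsatile flow in a rigid tube.

    Parameters
    ----------
    radius : tube radius in metres.
    harmonics : complex flow-rate coefficients (ml-free SI units, m^3/s)
        following the :func:`flow_harmonics` convention.
    density, viscosity : fluid properties in SI units.
    period : cardiac period in seconds.
    """

    radius: float
    harmonics: np.ndarray
    density: float
    viscosity: float
    period: float
    _shape_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.period <= 0:
            raise ValueError("radius and period must be positive")
        self.harmonics = np.asarray(self.harmonics, dtype=complex)

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    def alpha(self, k: int = 1) -> float:
        """Womersley number of harmonic k: R sqrt(k omega rho / mu)."""
        return self.radius * np.sqrt(k * self.omega * self.density / self.viscosity)

    def _lambda(self, k: int) -> complex:
        # i^{3/2} alpha_k
        return 1j ** 1.5 * self.alpha(k)

    def _shape(self, k: int, r: np.ndarray) -> np.ndarray:
        """Unit-coefficient profile shape S_k(r) = 1 - J0(L r/R)/J0(L)."""
        lam = self._lambda(k)
        return 1.0 - jv(0, lam * r / self.radius) / jv(0, lam)

    def _flux_factor(self, k: int) -> complex:
        """Integral of S_k over the cross-section: pi R^2 (1 - 2 J1(L)/(L J0(L)))."""
        lam = self._lambda(k)
        return np.pi * self.radius**2 * (1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam)))

    def velocity(self, r, t) -> np.ndarray:
        """Axial velocity at radial position(s) r (m) and time(s) t (s).

        Broadcasting: returns an array of shape ``np.broadcast(r, t).shape``.
        Positions with r > R return 0 (outside the lumen).
        """
        r = np.asarray(r, dtype=float)
        t = np.asarray(t, dtype=float)
        rho_clip = np.minimum(r, self.radius)
        q0 = self.harmonics[0].real
        u = 2.0 * q0 / (np.pi * self.radius**2) * (1.0 - (rho_clip / self.radius) ** 2)
        u = np.broadcast_to(u, np.broadcast(r, t).shape).copy()
        for k in range(1, self.harmonics.size):
            ck = self.harmonics[k] / self._flux_factor(k)
            sk = self._shape(k, rho_clip)
            u += 2.0 * np.real(ck * sk * np.exp(1j * k * self.omega * t))
        u[np.broadcast_to(r > self.radius, u.shape)] = 0.0
        return u

    def flow_rate(self, t) -> np.ndarray:
        """Exact flow rate of the truncated harmonic series at time(s) t (m^3/s)."""
        t = np.asarray(t, dtype=float)
        q = np.full(t.shape, self.harmonics[0].real)
        for k in range(1, self.harmonics.size):
            q += 2.0 * np.real(self.harmonics[k] * np.exp(1j * k * self.omega * t))
        return q


def womersley_profile(
    radius: float,
    flow_harmonics: np.ndarray,
    fluid,
    period: float,
) -> WomersleyProfile:
    """Build the analytic pulsatile profile for a harmonic flow decomposition.

    ``fluid`` is any object with ``density`` and ``viscosity`` attributes
    (see :class:`vbsflow.solver.FluidProperties`).
    """
    return WomersleyProfile(
        radius=radius,
        harmonics=np.asarray(flow_harmonics, dtype=complex),
        density=fluid.density,
        viscosity=fluid.viscosity,
        period=period,
    )
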
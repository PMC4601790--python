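"""Linear stability analysis of the homogeneous steady state.

For an idealized geometry (infinite slab of given thickness, membrane on both
flat faces; or an infinite cylinder, membrane on the lateral wall) the
homogeneous-in-plane steady state of the five reaction-diffusion equations is
found under the constraint that the total MinD and MinE content matches the
prescribed totals.  Small harmonic perturbations ``exp(i q x)`` in the
unbounded direction(s) are then applied: the growth rate of a perturbation
with half-wavelength ``l`` (wavenumber ``q = pi/l``) is the largest real part
of the eigenvalues of the Jacobian of the dynamics, with ``-D q^2`` acting on
the diffusing (cytoplasmic) species.  The system is stable at ``l`` when all
eigenvalue real parts are negative; the largest stable half-wavelength is
found by bisection on the leading real part.

The thin dimension (slab thickness, cylinder radius) is resolved with a 1D
grid; membrane exchange enters the adjacent grid cell through the area-per-
volume factor that discretizes the wall delta function.  A ``well_mixed=True``
variant collapses the thin dimension to a single cell; for the 0.4 um slab
the two give limits within a few hundredths of a micron (cytoplasmic
diffusion across 0.4 um is fast compared with every reaction time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from .params import RateParameters

__all__ = [
    "SteadyState",
    "DispersionResult",
    "solve_steady_state",
    "growth_spectrum",
    "max_stable_half_wavelength",
]


@dataclass
class _Discretization:
    """1D resolved thin dimension: cells plus membrane faces."""

    kind: str
    coords: np.ndarray       # cell-center coordinates across the thin dimension
    volumes: np.ndarray      # cell volume per unit (area | length)
    diff_coupling: np.ndarray  # face conductances between cells j and j+1
    mem_cells: np.ndarray    # index of the cytoplasm cell adjacent to each face
    mem_weight: np.ndarray   # membrane area per unit (area | length), per face
    # per-face exchange factor a/v in the adjacent cell:
    @property
    def g(self) -> np.ndarray:
        return self.mem_weight / self.volumes[self.mem_cells]


def _discretize(kind: str, dimension: float, n: int, well_mixed: bool) -> _Discretization:
    if well_mixed:
        n = 1
    if kind == "slab":
        h = dimension
        dz = h / n
        coords = (np.arange(n) + 0.5) * dz
        volumes = np.full(n, dz)
        cond = np.full(max(n - 1, 0), 1.0 / dz)  # area 1 per unit area, / dz
        mem_cells = np.array([0, n - 1])
        mem_weight = np.array([1.0, 1.0])
    elif kind == "cylinder":
        R = dimension
        dr = R / n
        faces = np.arange(n + 1) * dr
        coords = 0.5 * (faces[:-1] + faces[1:])
        volumes = np.pi * (faces[1:] ** 2 - faces[:-1] ** 2)
        cond = 2 * np.pi * faces[1:-1] / dr
        mem_cells = np.array([n - 1])
        mem_weight = np.array([2 * np.pi * R])
    else:
        raise ValueError(f"unknown geometry kind {kind!r}")
    return _Discretization(kind, coords, volumes, cond, mem_cells, mem_weight)


@dataclass
class SteadyState:
    kind: str
    dimension: float
    totals: tuple[float, float]
    rho: np.ndarray           # (3, n) cytoplasmic densities (/um^3)
    sigma: np.ndarray         # (2, n_faces) membrane densities (/um^2)
    residual: float
    disc: _Discretization = field(repr=False)
    params: RateParameters = field(repr=False)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.rho.ravel(), self.sigma.ravel()])


def _rhs(u: np.ndarray, disc: _Discretization, p: RateParameters, q: float) -> np.ndarray:
    n = len(disc.volumes)
    nf = len(disc.mem_cells)
    r = u[: 3 * n].reshape(3, n)
    s = u[3 * n :].reshape(2, nf)
    f = np.zeros_like(r)
    D = (p.D_D, p.D_D, p.D_E)
    for k in range(3):
        flux = disc.diff_coupling * (r[k, 1:] - r[k, :-1]) if n > 1 else np.zeros(0)
        div = np.zeros(n)
        if n > 1:
            div[:-1] += flux
            div[1:] -= flux
        f[k] = D[k] * (div / disc.volumes - q * q * r[k])
    f[0] -= p.k_exchange * r[0]
    f[1] += p.k_exchange * r[0]
    fs = np.zeros_like(s)
    for j in range(nf):
        c = disc.mem_cells[j]
        g = disc.mem_weight[j] / disc.volumes[c]
        att = p.k_D + p.k_dD * (s[0, j] + s[1, j])
        f[0, c] += g * p.k_de * s[1, j]
        f[1, c] -= g * att * r[1, c]
        f[2, c] += g * (p.k_de * s[1, j] - p.k_E * s[0, j] * r[2, c])
        fs[0, j] = att * r[1, c] - p.k_E * s[0, j] * r[2, c]
        fs[1, j] = p.k_E * s[0, j] * r[2, c] - p.k_de * s[1, j]
    return np.concatenate([f.ravel(), fs.ravel()])


def solve_steady_state(
    params: RateParameters,
    geometry_kind: str,
    dimension: float,
    totals: tuple[float, float],
    n_points: int = 16,
    well_mixed: bool = False,
) -> SteadyState:
    """Steady state of the five equations across the thin dimension.

    ``totals`` are total MinD and MinE per unit slab area (kind="slab") or
    per unit cylinder length (kind="cylinder").
    """
    tot_d, tot_e = totals
    if tot_d < 0 or tot_e < 0:
        raise ValueError("totals must be nonnegative")
    disc = _discretize(geometry_kind, dimension, n_points, well_mixed)
    n = len(disc.volumes)
    nf = len(disc.mem_cells)
    vtot = disc.volumes.sum()
    if tot_d == 0 and tot_e == 0:
        return SteadyState(
            geometry_kind, dimension, totals,
            np.zeros((3, n)), np.zeros((2, nf)), 0.0, disc, params,
        )

    u0 = np.concatenate(
        [
            np.full(n, 0.7 * tot_d / vtot),
            np.full(n, 0.3 * tot_d / vtot),
            np.full(n, tot_e / vtot),
            np.zeros(2 * nf),
        ]
    )
    sol = solve_ivp(
        lambda t, u: _rhs(u, disc, params, 0.0),
        (0.0, 5000.0),
        u0,
        method="BDF",
        rtol=1e-10,
        atol=1e-8,
    )
    u = sol.y[:, -1]

    def eqs(w: np.ndarray) -> np.ndarray:
        f = _rhs(w, disc, params, 0.0).copy()
        r = w[: 3 * n].reshape(3, n)
        s = w[3 * n :].reshape(2, nf)
        # the dynamics conserve both totals, so two equations are redundant;
        # replace one from each conserved group with the constraint itself
        f[0] = (r[0] + r[1]) @ disc.volumes + (s[0] + s[1]) @ disc.mem_weight - tot_d
        f[2 * n] = r[2] @ disc.volumes + s[1] @ disc.mem_weight - tot_e
        return f

    u = fsolve(eqs, u, xtol=1e-13)
    resid = float(np.max(np.abs(_rhs(u, disc, params, 0.0))))
    scale = max(params.k_de * max(u.max(), 1.0), 1.0)
    if resid > 1e-8 * scale:
        raise RuntimeError(
            f"steady-state solve did not converge: residual {resid:.3e}"
        )
    return SteadyState(
        geometry_kind, dimension, totals,
        u[: 3 * n].reshape(3, n).copy(), u[3 * n :].reshape(2, nf).copy(),
        resid, disc, params,
    )


def _jacobian(ss: SteadyState, q: float) -> np.ndarray:
    u0 = ss.as_vector()
    f0 = _rhs(u0, ss.disc, ss.params, q)
    n = len(u0)
    J = np.empty((n, n))
    for j in range(n):
        du = np.zeros(n)
        du[j] = 1e-6 * max(1.0, abs(u0[j]))
        J[:, j] = (_rhs(u0 + du, ss.disc, ss.params, q) - f0) / du[j]
    return J


@dataclass
class DispersionResult:
    half_wavelengths: np.ndarray
    growth_rates: np.ndarray       # leading eigenvalue real part (1/s)
    leading_eigenvalues: np.ndarray  # complex

    @property
    def stable(self) -> np.ndarray:
        return self.growth_rates < 0


def growth_spectrum(
    ss: SteadyState, params: RateParameters, half_wavelengths
) -> DispersionResult:
    """Leading growth rate for harmonic perturbations at each half-wavelength
    ``l`` (wavenumber q = pi/l)."""
    hw = np.asarray(half_wavelengths, dtype=float)
    lead_re = np.empty_like(hw)
    lead = np.empty(len(hw), dtype=complex)
    for i, l in enumerate(hw):
        ev = np.linalg.eigvals(_jacobian(ss, np.pi / l))
        k = int(np.argmax(ev.real))
        lead[i] = ev[k]
        lead_re[i] = ev[k].real
    return DispersionResult(hw, lead_re, lead)


def max_stable_half_wavelength(
    params: RateParameters,
    geometry_kind: str,
    dimension: float,
    totals: tuple[float, float],
    n_points: int = 16,
    well_mixed: bool = False,
    bracket: tuple[float, float] = (0.5, 8.0),
    xtol: float = 0.005,
) -> float:
    """Largest half-wavelength at which the steady state is linearly stable,
    bracketed by bisection on the leading eigenvalue's real part."""
    ss = solve_steady_state(
        params, geometry_kind, dimension, totals, n_points, well_mixed
    )

    def lead(l: float) -> float:
        return float(np.max(np.linalg.eigvals(_jacobian(ss, np.pi / l)).real))

    lo, hi = bracket
    flo, fhi = lead(lo), lead(hi)
    if flo * fhi > 0:
        word = "stable" if flo < 0 else "unstable"
        raise RuntimeError(
            f"unconditionally {word} in the bracket [{lo}, {hi}] um"
        )
    return float(brentq(lead, lo, hi, xtol=xtol))
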
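"""Glucose diffusion within tissue.

The tissue is treated as a semi-infinite one-dimensional bar fed at the
capillary wall (x = 0).  For a constant boundary concentration ``C_b`` and
uniform initial concentration ``C0`` the solution of the diffusion
equation is

    C(x, t) = C_b - (C_b - C0) * erf(x / (2 * sqrt(D * t)))

For a time-varying boundary two evaluation modes are offered:

``quasi_static``
    evaluates the constant-source solution at each instant with the
    current boundary value — a snapshot approximation;
``superposition``
    applies Duhamel's principle (convolution of boundary increments with
    the step response), the exact solution for a time-varying Dirichlet
    boundary.  This is the default.

A finite-difference solver (`fd_oracle`) provides an independent check of
both the analytic step response and the superposition mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf as _erf, erfc as _erfc

from .errors import ConfigurationError, InvalidInputError
from .series import GlucoseTimeSeries

__all__ = [
    "TissueParams",
    "BoundarySeries",
    "erf_value",
    "erf_step_response",
    "erf_series_response",
    "fd_oracle",
]

#: The boundary trace C(x=0, t) is an ordinary concentration series.
BoundarySeries = GlucoseTimeSeries


@dataclass(frozen=True)
class TissueParams:
    """Diffusion coefficient, evaluation distance and initial concentration.

    ``x_um`` is the effective distance from the capillary centre to the
    interstitial evaluation point; the capillary wall is treated as x = 0,
    with wall thickness and radius absorbed into the single fitted
    distance.  ``d_um2_per_min`` defaults to 600 um^2/min, an
    order-of-magnitude literature-typical value for glucose in tissue — a
    package default, not a measured constant.
    """

    d_um2_per_min: float = 600.0
    x_um: float = 24.0
    c_isf0: float = 100.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.d_um2_per_min) or self.d_um2_per_min <= 0:
            raise InvalidInputError(f"D must be positive, got {self.d_um2_per_min}")
        if not np.isfinite(self.x_um) or self.x_um < 0:
            raise InvalidInputError(f"x must be nonnegative, got {self.x_um}")
        if not np.isfinite(self.c_isf0) or self.c_isf0 < 0:
            raise InvalidInputError(f"C_ISF0 must be nonnegative, got {self.c_isf0}")


def erf_value(z: float | np.ndarray) -> float | np.ndarray:
    """Error function (2/sqrt(pi)) * integral_0^z exp(-u^2) du."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("erf argument must be finite")
    out = _erf(z)
    return float(out) if out.ndim == 0 else out


def _step_kernel(x: float, d: float, t: np.ndarray) -> np.ndarray:
    """erfc(x / (2 sqrt(D t))) with the t<=0 limit 0 (for x>0)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if x == 0:
        out[pos] = 1.0
    else:
        out[pos] = _erfc(x / (2.0 * np.sqrt(d * t[pos])))
    return out


def erf_step_response(
    boundary_value: float, tissue: TissueParams, t: float | np.ndarray
) -> float | np.ndarray:
    """Concentration at distance ``x`` and time ``t`` for a constant boundary.

    Returns ``C_b - (C_b - C0) * erf(x / (2 sqrt(D t)))``; at ``t = 0``
    the initial condition ``C0`` applies, and at ``x = 0`` the boundary
    value applies for all ``t > 0``.
    """
    if boundary_value < 0:
        raise InvalidInputError("boundary concentration must be nonnegative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("time must be nonnegative")
    c0 = tissue.c_isf0
    s = _step_kernel(tissue.x_um, tissue.d_um2_per_min, t_arr)
    out = c0 + (boundary_value - c0) * s
    return float(out) if out.ndim == 0 else out


def _duhamel(b: np.ndarray, h: float, x: float, d: float, c0: float) -> np.ndarray:
    """Exact-in-the-limit response to a sampled boundary on a uniform grid.

    ``b[n]`` is the boundary at time ``n*h``.  Boundary increments are
    treated as steps applied at interval midpoints and convolved with the
    step-response kernel.
    """
    n = b.size
    t = h * np.arange(n)
    s_at_t = _step_kernel(x, d, t)
    out = c0 + (b[0] - c0) * s_at_t
    if n > 1:
        db = np.diff(b)
        s_half = _step_kernel(x, d, h * (np.arange(n - 1) + 0.5))
        out[1:] += np.convolve(db, s_half)[: n - 1]
    return out


def _quasi_static(b: np.ndarray, h: float, x: float, d: float, c0: float) -> np.ndarray:
    t = h * np.arange(b.size)
    s = _step_kernel(x, d, t)
    return b - (b - c0) * (1.0 - s)


def erf_series_response(
    boundary: BoundarySeries,
    tissue: TissueParams,
    mode: str = "superposition",
    dt: float = 0.1,
) -> GlucoseTimeSeries:
    """Tissue concentration at distance ``x`` driven by a boundary trace.

    The boundary is linearly interpolated onto a uniform internal grid of
    step ``dt`` minutes; the result is sampled back at the boundary's own
    times.  Modes coincide exactly for a constant boundary.
    """
    if mode not in ("superposition", "quasi_static"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    t0, t1 = boundary.times[0], boundary.times[-1]
    n = max(int(np.ceil((t1 - t0) / dt)), 1) + 1
    t_fine = t0 + dt * np.arange(n)
    b = boundary.interp(t_fine)
    x, d, c0 = tissue.x_um, tissue.d_um2_per_min, tissue.c_isf0
    if x == 0:
        c_fine = b
    elif mode == "superposition":
        c_fine = _duhamel(b, dt, x, d, c0)
    else:
        c_fine = _quasi_static(b, dt, x, d, c0)
    out = np.interp(boundary.times, t_fine, c_fine)
    return GlucoseTimeSeries(boundary.times.copy(), out, label="isf")


def fd_oracle(
    boundary: BoundarySeries,
    tissue: TissueParams,
    dx: float | None = None,
    dt: float = 0.05,
    domain_factor: float = 10.0,
    scheme: str = "crank_nicolson",
) -> GlucoseTimeSeries:
    """Finite-difference solution of the tissue diffusion problem.

    Solves dC/dt = D d2C/dx2 on [0, L] with Dirichlet data
    ``C(0, t) = boundary(t)``, far field ``C(L, t) = C0`` and initial
    state ``C0``, and returns the trace at ``x`` sampled at the boundary's
    times.  ``L`` is at least ``domain_factor * x`` and several diffusion
    lengths, so the far boundary is inert.  The spatial grid is chosen so
    that ``x`` falls exactly on a node.

    The default Crank-Nicolson scheme (with two implicit-Euler startup
    half-steps to damp the corner discontinuity) is unconditionally
    stable; ``scheme="explicit"`` uses forward Euler and raises a
    configuration error if ``dt > dx^2 / (2 D)``.
    """
    if scheme not in ("crank_nicolson", "explicit"):
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    x, d, c0 = tissue.x_um, tissue.d_um2_per_min, tissue.c_isf0
    if x == 0:
        return GlucoseTimeSeries(boundary.times.copy(), boundary.values.copy(), "isf")
    if dx is None:
        dx = x / 20.0
    # put the evaluation point on a node
    ix = max(int(round(x / dx)), 1)
    dx = x / ix
    t0 = boundary.times[0]
    horizon = max(boundary.duration, dt)
    length = max(domain_factor * x, 6.0 * np.sqrt(d * horizon) + x)
    nx = int(np.ceil(length / dx))
    nt = max(int(np.ceil(horizon / dt)), 1)
    dt_eff = horizon / nt
    r = d * dt_eff / dx**2
    if scheme == "explicit" and r > 0.5:
        raise ConfigurationError(
            f"explicit scheme unstable: D*dt/dx^2 = {r:.3g} > 0.5"
        )

    t_grid = t0 + dt_eff * np.arange(nt + 1)
    b = boundary.interp(t_grid)
    c = np.full(nx + 1, c0)
    c[0] = b[0]
    trace = np.empty(nt + 1)
    trace[0] = c0

    if scheme == "explicit":
        for n in range(1, nt + 1):
            c_new = c.copy()
            c_new[1:-1] = c[1:-1] + r * (c[2:] - 2 * c[1:-1] + c[:-2])
            c_new[0] = b[n]
            c_new[-1] = c0
            c = c_new
            trace[n] = c[ix]
    else:
        from scipy.sparse import diags
        from scipy.sparse.linalg import splu

        m = nx - 1  # interior unknowns

        def tridiag(theta: float, step: float):
            rr = d * step / dx**2
            main = np.full(m, 1.0 + 2.0 * theta * rr)
            off = np.full(m - 1, -theta * rr)
            return splu(diags([off, main, off], [-1, 0, 1]).tocsc()), rr

        lu_cn, r_cn = tridiag(0.5, dt_eff)
        lu_be, r_be = tridiag(1.0, dt_eff / 2.0)

        def be_step(c_int, b_new):
            rhs = c_int.copy()
            rhs[0] += r_be * b_new
            rhs[-1] += r_be * c0
            return lu_be.solve(rhs)

        c_int = c[1:-1].copy()
        for n in range(1, nt + 1):
            if n <= 2:  # Rannacher startup: two implicit-Euler half-steps
                b_mid = 0.5 * (b[n - 1] + b[n])
                c_int = be_step(c_int, b_mid)
                c_int = be_step(c_int, b[n])
            else:
                rhs = c_int + 0.5 * r_cn * (
                    np.concatenate(([b[n - 1]], c_int[:-1]))
                    - 2 * c_int
                    + np.concatenate((c_int[1:], [c0]))
                )
                rhs[0] += 0.5 * r_cn * b[n]
                rhs[-1] += 0.5 * r_cn * c0
                c_int = lu_cn.solve(rhs)
            trace[n] = c_int[ix - 1]

    out = np.interp(boundary.times, t_grid, trace)
    return GlucoseTimeSeries(boundary.times.copy(), out, label="isf")
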
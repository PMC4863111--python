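"""Transcapillary glucose movement.

Two routes move glucose across the capillary wall:

* concentration-gradient transport (Fick), summarised by the dimensionless
  exchange ratio ``k = P*A/F`` (permeability x area over flow) -- the
  classical permeability-surface-area-product construction in which the
  single-pass extraction tends to ``1 - exp(-k)``;
* pressure-gradient fluid movement (Starling filtration/absorption) along
  a capillary whose hydrostatic pressure falls linearly from the arteriolar
  to the venular end, producing a filtration segment (plasma -> tissue)
  and an absorption segment (tissue -> plasma) whose fluxes mix wall-side
  interstitial fluid with plasma.

Interstitial hydrostatic and oncotic pressures are taken as negligible and
are not parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import fixed_quad

from .errors import InvalidInputError

__all__ = [
    "CapillaryParams",
    "StarlingParams",
    "StarlingFluxes",
    "extraction",
    "fick_isf_concentration",
    "venous_concentration",
    "starling_fluxes",
    "starling_mix",
]


@dataclass(frozen=True)
class CapillaryParams:
    """Permeability/area/flow triple governing gradient-driven exchange.

    ``permeability`` has units of length/time, ``area`` of area and
    ``flow`` of volume/time; only their dimensionless combination
    ``k = permeability * area / flow`` enters the model, so any consistent
    unit choice works.
    """

    permeability: float
    area: float
    flow: float

    def __post_init__(self) -> None:
        for name in ("permeability", "area", "flow"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidInputError(f"{name} must be positive and finite, got {v}")

    @property
    def k(self) -> float:
        """Dimensionless exchange ratio P*A/F."""
        return self.permeability * self.area / self.flow


@dataclass(frozen=True)
class StarlingParams:
    """Pressures and filtration coefficient for the Starling fluxes.

    The capillary axis is normalised: hydrostatic pressure equals the
    arteriolar pressure ``p_a`` at axial position 0 and the venular
    pressure ``p_v`` at 1.  ``sigma_pi_c`` is the reflection-adjusted
    plasma oncotic pressure; the filtration/absorption crossover where the
    capillary pressure equals it must lie on the capillary, i.e.
    ``p_v <= sigma_pi_c <= p_a``.
    """

    k_f: float
    sigma_pi_c: float
    p_a: float
    p_v: float
    x_axial: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k_f) or self.k_f <= 0:
            raise InvalidInputError(f"k_f must be positive, got {self.k_f}")
        if not self.p_a > self.p_v:
            raise InvalidInputError(
                f"arteriolar pressure must exceed venular pressure "
                f"(p_a={self.p_a}, p_v={self.p_v})"
            )
        if not (self.p_v <= self.sigma_pi_c <= self.p_a):
            raise InvalidInputError(
                f"sigma_pi_c={self.sigma_pi_c} outside [p_v, p_a]="
                f"[{self.p_v}, {self.p_a}]: no filtration/absorption "
                f"crossover on the capillary"
            )
        if not (0.0 <= self.x_axial <= 1.0):
            raise InvalidInputError(f"x_axial must lie in [0, 1], got {self.x_axial}")

    def capillary_pressure(self, x_axial: float | None = None) -> float:
        """Hydrostatic pressure at a normalised axial position (linear profile)."""
        x = self.x_axial if x_axial is None else x_axial
        return self.p_a + (self.p_v - self.p_a) * x

    @property
    def crossover(self) -> float:
        """Axial position where filtration turns into absorption."""
        return (self.p_a - self.sigma_pi_c) / (self.p_a - self.p_v)


@dataclass(frozen=True)
class StarlingFluxes:
    """Filtration (plasma->tissue) and absorption (tissue->plasma) magnitudes."""

    gain: float
    loss: float

    def __post_init__(self) -> None:
        if self.gain < 0 or self.loss < 0:
            raise InvalidInputError("fluxes must be nonnegative")
        if self.gain + self.loss <= 0:
            raise InvalidInputError("gain + loss must be positive")

    @property
    def w_gain(self) -> float:
        """Mixing weight of plasma-derived fluid, gain / (gain + loss)."""
        return self.gain / (self.gain + self.loss)


def extraction(c_arterial: float, c_venous: float) -> float:
    """Single-pass glucose extraction (C_a - C_v) / C_a.

    Negative results (venous above arterial: net tissue-to-blood movement)
    are permitted and returned as-is.
    """
    if not np.isfinite(c_arterial) or c_arterial <= 0:
        raise InvalidInputError(f"arterial concentration must be positive, got {c_arterial}")
    if c_venous < 0:
        raise InvalidInputError(f"venous concentration must be nonnegative, got {c_venous}")
    return (c_arterial - c_venous) / c_arterial


def _expm1_ratio(k: float) -> float:
    # (1 - exp(-k)) / k, stable for small k
    if k == 0:
        return 1.0
    return -np.expm1(-k) / k


def fick_isf_concentration(
    c_blood: float | np.ndarray,
    params: CapillaryParams,
    c_isf: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Wall-side interstitial concentration from gradient-driven exchange.

    Returns ``c_blood - (1 - exp(-k)) * (c_blood - c_isf) / k`` with
    ``k = P*A/F``.  The default ``c_isf=0`` gives the single-pass form in
    which the entire blood-side concentration drives the flux; passing the
    current interstitial concentration gives the gradient-consistent
    generalisation used by the simulation recursion (identical when
    ``c_isf`` is 0, and a convex combination of its two concentration
    arguments in general).

    Applied pointwise over arrays.
    """
    c_blood = np.asarray(c_blood, dtype=float)
    if np.any(c_blood < 0):
        raise InvalidInputError("blood concentration must be nonnegative")
    k = params.k
    if not np.isfinite(k):
        raise InvalidInputError(f"exchange ratio k must be finite, got {k}")
    w = _expm1_ratio(k)
    out = c_blood - w * (c_blood - np.asarray(c_isf, dtype=float))
    return float(out) if out.ndim == 0 else out


def venous_concentration(
    c_arterial: float, params: CapillaryParams, c_isf: float = 0.0
) -> float:
    """Venous concentration after one well-mixed capillary pass.

    ``c_isf + (c_arterial - c_isf) * exp(-k)``; with ``c_isf = 0`` the
    implied extraction is the classical ``1 - exp(-k)`` limit.
    """
    if c_arterial < 0 or c_isf < 0:
        raise InvalidInputError("concentrations must be nonnegative")
    return c_isf + (c_arterial - c_isf) * np.exp(-params.k)


def starling_fluxes(params: StarlingParams, method: str = "closed_form") -> StarlingFluxes:
    """Filtration and absorption flux magnitudes along the capillary.

    With the linear axial pressure profile the filtration segment
    (capillary pressure above ``sigma_pi_c``) and absorption segment
    (below it) are triangles whose areas give

    ``gain = k_f * (p_a - sigma_pi_c)^2 / (2 * (p_a - p_v))``
    ``loss = k_f * (sigma_pi_c - p_v)^2 / (2 * (p_a - p_v))``

    ``method="quadrature"`` integrates the net driving pressure over the
    axial coordinate numerically instead; the two agree to better than
    1e-9 relative.
    """
    kf, spc, pa, pv = params.k_f, params.sigma_pi_c, params.p_a, params.p_v
    if method == "closed_form":
        gain = kf * (pa - spc) ** 2 / (2.0 * (pa - pv))
        loss = kf * (spc - pv) ** 2 / (2.0 * (pa - pv))
    elif method == "quadrature":
        xc = params.crossover

        def net(x):
            return params.capillary_pressure(x) - spc

        # Gauss-Legendre; exact here (linear integrand) yet independent
        # of the closed-form triangle areas
        gain = kf * (fixed_quad(net, 0.0, xc, n=20)[0] if xc > 0 else 0.0)
        loss = -kf * (fixed_quad(net, xc, 1.0, n=20)[0] if xc < 1 else 0.0)
        gain, loss = max(gain, 0.0), max(loss, 0.0)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    return StarlingFluxes(gain=gain, loss=loss)


def starling_mix(
    c_blood: float | np.ndarray,
    c_isf: float | np.ndarray,
    fluxes: StarlingFluxes,
) -> float | np.ndarray:
    """Wall-side concentration after pressure-driven fluid mixing.

    Filtered plasma (carrying ``c_blood``) mixes with resident
    interstitial fluid (carrying ``c_isf``) in proportion to the flux
    magnitudes: ``w * c_blood + (1 - w) * c_isf`` with
    ``w = gain / (gain + loss)``.  Always a convex combination of the two
    inputs.
    """
    c_blood = np.asarray(c_blood, dtype=float)
    c_isf = np.asarray(c_isf, dtype=float)
    if np.any(c_blood < 0) or np.any(c_isf < 0):
        raise InvalidInputError("concentrations must be nonnegative")
    w = fluxes.w_gain
    out = w * c_blood + (1.0 - w) * c_isf
    return float(out) if out.ndim == 0 else out
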
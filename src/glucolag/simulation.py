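"""End-to-end predictor: blood glucose series in, interstitial series out.

Each internal time step forms the wall-side boundary concentration as a
weighted combination of the two transcapillary routes,

    C_boundary(t) = R_fick * C_fick(t) + R_starling * C_starling(t),

with the weights constrained to sum to one, and then propagates the
boundary into the tissue at distance ``x`` through the chosen diffusion
mode.  The interstitial value fed back into the Starling mixing (and,
by default, into the Fick gradient) is the previous internal step's
simulated concentration at ``x``, initialised to ``C_ISF0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .diffusion import TissueParams, _step_kernel
from .errors import ConfigurationError, InvalidInputError
from .series import GlucoseTimeSeries, require_same_grid
from .transport import (
    CapillaryParams,
    StarlingParams,
    fick_isf_concentration,
    starling_fluxes,
    starling_mix,
)

__all__ = ["ModelWeights", "ModelConfig", "boundary_concentration", "simulate_isf"]


@dataclass(frozen=True)
class ModelWeights:
    """Route weights; ``r_fick + r_starling`` must equal 1."""

    r_fick: float = 0.5
    r_starling: float = 0.5

    def __post_init__(self) -> None:
        if self.r_fick < 0 or self.r_starling < 0:
            raise InvalidInputError("weights must be nonnegative")
        if abs(self.r_fick + self.r_starling - 1.0) > 1e-12:
            raise InvalidInputError(
                f"weights must sum to 1, got {self.r_fick + self.r_starling}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """All parameters of the blood-to-interstitial predictor.

    ``fick_feedback`` controls whether the Fick route sees the current
    interstitial concentration as the far side of its gradient (the
    default, which makes a uniform state a fixed point and keeps the
    output inside the convex hull of its inputs) or the literal
    single-pass form in which only the blood concentration drives the
    flux.
    """

    capillary: CapillaryParams = field(
        default_factory=lambda: CapillaryParams(permeability=25.0, area=0.12, flow=3.0)
    )
    starling: StarlingParams = field(
        default_factory=lambda: StarlingParams(k_f=1.0, sigma_pi_c=25.0, p_a=35.0, p_v=15.0)
    )
    tissue: TissueParams = field(default_factory=TissueParams)
    weights: ModelWeights = field(default_factory=ModelWeights)
    diffusion_mode: str = "superposition"
    dt_min: float = 0.1
    fick_feedback: bool = True

    def __post_init__(self) -> None:
        if self.diffusion_mode not in ("superposition", "quasi_static"):
            raise ConfigurationError(f"unknown diffusion mode {self.diffusion_mode!r}")
        if not np.isfinite(self.dt_min) or self.dt_min <= 0:
            raise ConfigurationError(f"time step must be positive, got {self.dt_min}")

    def with_x(self, x_um: float) -> "ModelConfig":
        return replace(self, tissue=replace(self.tissue, x_um=x_um))


def boundary_concentration(
    blood: GlucoseTimeSeries,
    isf_prev: GlucoseTimeSeries,
    config: ModelConfig,
    fick_feedback: bool = False,
) -> GlucoseTimeSeries:
    """Wall-side boundary series combining the Fick and Starling routes.

    Pointwise ``r_fick * C_fick + r_starling * C_starling`` on a shared
    time grid.  By default the Fick term uses the literal single-pass
    form (interstitial concentration not fed back); pass
    ``fick_feedback=True`` for the gradient-consistent variant the
    simulation recursion uses.
    """
    require_same_grid(blood, isf_prev)
    fluxes = starling_fluxes(config.starling)
    c_fick = fick_isf_concentration(
        blood.values, config.capillary,
        c_isf=isf_prev.values if fick_feedback else 0.0,
    )
    c_star = starling_mix(blood.values, isf_prev.values, fluxes)
    w = config.weights
    out = w.r_fick * np.asarray(c_fick) + w.r_starling * np.asarray(c_star)
    return GlucoseTimeSeries(blood.times.copy(), out, label="boundary")


def simulate_isf(blood: GlucoseTimeSeries, config: ModelConfig) -> GlucoseTimeSeries:
    """Simulate the interstitial glucose trace for a blood glucose input.

    The blood series is linearly interpolated onto the internal uniform
    grid; at each step the boundary concentration is formed from the
    current blood value and the previous step's interstitial value, and
    the tissue concentration at distance ``x`` is advanced with the
    configured diffusion mode.  The result is sampled at the input's own
    times.
    """
    if len(blood) == 0:
        raise InvalidInputError("blood series is empty")
    w = config.weights
    fluxes = starling_fluxes(config.starling)
    w_gain = fluxes.w_gain
    k = config.capillary.k
    fick_w = -np.expm1(-k) / k if k > 0 else 1.0  # (1 - e^-k)/k
    tis = config.tissue
    x, d, c0 = tis.x_um, tis.d_um2_per_min, tis.c_isf0
    dt = config.dt_min

    t0, t1 = blood.times[0], blood.times[-1]
    n = max(int(np.ceil((t1 - t0) / dt)), 1) + 1
    t_rel = dt * np.arange(n)
    blood_fine = blood.interp(t0 + t_rel)

    s_at_t = _step_kernel(x, d, t_rel)
    s_half = _step_kernel(x, d, dt * (np.arange(max(n - 1, 1)) + 0.5))

    b = np.empty(n)  # boundary trace
    c = np.empty(n)  # interstitial trace at x
    c_prev = c0
    for i in range(n):
        cb = blood_fine[i]
        if config.fick_feedback:
            c_fick = cb - fick_w * (cb - c_prev)
        else:
            c_fick = cb * (1.0 - fick_w)
        c_star = w_gain * cb + (1.0 - w_gain) * c_prev
        b[i] = w.r_fick * c_fick + w.r_starling * c_star
        if x == 0:
            c[i] = b[i]
        elif config.diffusion_mode == "quasi_static":
            c[i] = b[i] - (b[i] - c0) * (1.0 - s_at_t[i])
        else:  # superposition (Duhamel) with incrementally revealed boundary
            ci = c0 + (b[0] - c0) * s_at_t[i]
            if i > 0:
                ci += np.dot(np.diff(b[: i + 1]), s_half[i - 1 :: -1])
            c[i] = ci
        c_prev = c[i]

    out = np.interp(blood.times, t0 + t_rel, c)
    return GlucoseTimeSeries(blood.times.copy(), out, label="isf")
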
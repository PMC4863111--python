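"""Model-vs-data comparison: error metrics, lag estimation, distance fitting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import FitError, InvalidInputError, NoFeatureError
from .series import GlucoseTimeSeries, require_same_grid
from .simulation import ModelConfig, simulate_isf

__all__ = ["FitResult", "relative_errors", "estimate_lag", "fit_diffusion_distance"]

#: Distance candidates (um) used throughout as the default search grid.
DEFAULT_DISTANCE_GRID = (18.0, 24.0, 30.0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a diffusion-distance grid fit."""

    x_best_um: float
    grid_um: tuple[float, ...]
    lag_min: float
    max_rel_error: float
    mean_rel_error: float
    error_table: dict[float, tuple[float, float]] = field(default_factory=dict)
    x_refined_um: float | None = None

    def __post_init__(self) -> None:
        if self.x_best_um not in self.grid_um:
            raise InvalidInputError("best distance must be a member of the grid")
        if self.max_rel_error < 0 or self.mean_rel_error < 0 or self.lag_min < 0:
            raise InvalidInputError("errors and lag must be nonnegative")


def relative_errors(
    measured: GlucoseTimeSeries, predicted: GlucoseTimeSeries
) -> tuple[float, float]:
    """Maximum and mean pointwise relative error |measured - predicted| / measured."""
    require_same_grid(measured, predicted)
    if np.any(measured.values <= 0):
        raise InvalidInputError("measured values must be positive for relative error")
    e = np.abs(measured.values - predicted.values) / measured.values
    return float(np.max(e)), float(np.mean(e))


def _check_feature(series: GlucoseTimeSeries, name: str) -> None:
    if np.ptp(series.values) <= 1e-12 * max(1.0, float(np.max(series.values))):
        raise NoFeatureError(f"{name} series is constant: no feature to align on")


def estimate_lag(
    blood: GlucoseTimeSeries,
    isf: GlucoseTimeSeries,
    method: str = "shift",
    max_lag: float | None = None,
    resolution: float = 0.1,
) -> float:
    """Delay of the interstitial trace relative to the blood trace, in minutes.

    ``shift`` scans nonnegative lags on a uniform grid (default 0.1-min
    spacing) and returns the lag minimising the mean squared difference
    between ``blood(t)`` and ``isf(t + lag)`` over the shrinking overlap
    window, with linear interpolation between samples; ties break toward
    the smallest lag.  ``peak`` returns the difference of the argmax
    times, floored at zero.
    """
    _check_feature(blood, "blood")
    _check_feature(isf, "isf")
    if method == "peak":
        tb = float(blood.times[np.argmax(blood.values)])
        ti = float(isf.times[np.argmax(isf.values)])
        return max(ti - tb, 0.0)
    if method != "shift":
        raise InvalidInputError(f"unknown lag method {method!r}")
    if resolution <= 0:
        raise InvalidInputError("resolution must be positive")

    lo = max(blood.times[0], isf.times[0])
    hi = min(blood.times[-1], isf.times[-1])
    if hi <= lo:
        raise InvalidInputError("series share no overlap window")
    if max_lag is None:
        max_lag = 0.5 * (hi - lo)
    lags = np.arange(0.0, max_lag + 0.5 * resolution, resolution)
    eval_t = np.arange(lo, hi + 0.5 * resolution, resolution)
    blood_e = blood.interp(eval_t)
    best_lag, best_obj = 0.0, np.inf
    for lag in lags:
        mask = eval_t + lag <= isf.times[-1]
        if mask.sum() < max(3, int(0.25 * eval_t.size)):
            break
        diff = blood_e[mask] - isf.interp(eval_t[mask] + lag)
        obj = float(np.mean(diff**2))
        if obj < best_obj - 1e-15:
            best_obj, best_lag = obj, float(lag)
    return best_lag


def fit_diffusion_distance(
    blood: GlucoseTimeSeries,
    isf_measured: GlucoseTimeSeries,
    config: ModelConfig,
    grid: tuple[float, ...] = DEFAULT_DISTANCE_GRID,
    objective: str = "mean_rel",
    lag_method: str = "shift",
    refine: bool = False,
) -> FitResult:
    """Grid search for the diffusion distance best explaining measured data.

    Each candidate distance is simulated from the blood series and scored
    against the measured interstitial series; the candidate with the
    smallest mean relative error (or RMSE with ``objective="rmse"``) wins.
    The reported lag is that of the winning simulation against the blood
    input.  ``refine=True`` additionally polishes the distance
    continuously within the grid's range by bounded scalar minimisation.
    """
    if len(grid) == 0:
        raise InvalidInputError("candidate grid is empty")
    if objective not in ("mean_rel", "rmse"):
        raise InvalidInputError(f"unknown objective {objective!r}")
    require_same_grid(blood, isf_measured)

    def score(sim: GlucoseTimeSeries) -> tuple[float, float, float]:
        mx, mean = relative_errors(isf_measured, sim)
        if objective == "rmse":
            key = float(np.sqrt(np.mean((isf_measured.values - sim.values) ** 2)))
        else:
            key = mean
        return key, mx, mean

    table: dict[float, tuple[float, float]] = {}
    best: tuple[float, float, GlucoseTimeSeries] | None = None  # (key, x, sim)
    for x in grid:
        try:
            sim = simulate_isf(blood, config.with_x(float(x)))
            key, mx, mean = score(sim)
        except Exception as exc:  # noqa: BLE001 — candidate skipped, fit continues
            warnings.warn(f"candidate x={x} failed: {exc}", UserWarning, stacklevel=2)
            continue
        table[float(x)] = (mx, mean)
        if best is None or key < best[0]:
            best = (key, float(x), sim)
    if best is None:
        raise FitError("every candidate distance failed to simulate")

    _, x_best, sim_best = best
    mx_best, mean_best = table[x_best]
    lag = estimate_lag(blood, sim_best, method=lag_method)

    x_refined = None
    if refine and len(grid) > 1:
        lo, hi = min(grid), max(grid)

        def obj(x: float) -> float:
            return score(simulate_isf(blood, config.with_x(float(x))))[0]

        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": 0.05})
        x_refined = float(res.x)

    return FitResult(
        x_best_um=x_best,
        grid_um=tuple(float(x) for x in grid),
        lag_min=lag,
        max_rel_error=mx_best,
        mean_rel_error=mean_best,
        error_table=table,
        x_refined_um=x_refined,
    )
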
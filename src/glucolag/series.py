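"""Timestamped concentration series, the common currency between pipeline stages.

Units are fixed package-wide: time in minutes, glucose concentration in
mg/dL, pressure in mmHg, distance in micrometres.  Converters, where
needed, live at the I/O boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["GlucoseTimeSeries"]


@dataclass(frozen=True)
class GlucoseTimeSeries:
    """A sampled concentration trace.

    Parameters
    ----------
    times
        Sample times in minutes, strictly increasing.
    values
        Concentrations in mg/dL, nonnegative.  Negative entries (possible
        only through user-supplied data) are clamped to zero with a warning.
    label
        Free-text tag, conventionally ``"blood"`` or ``"isf"``.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1:
            raise InvalidInputError("times and values must be one-dimensional")
        if times.size != values.size:
            raise InvalidInputError(
                f"length mismatch: {times.size} times vs {values.size} values"
            )
        if times.size == 0:
            raise InvalidInputError("empty time series")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise InvalidInputError("times and values must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(values < 0):
            warnings.warn(
                "negative concentrations clamped to 0", UserWarning, stacklevel=3
            )
            values = np.clip(values, 0.0, None)
        times.setflags(write=False)
        values.setflags(write=False)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def interp(self, at: np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace at arbitrary times.

        Values outside the sampled window clamp to the endpoints.
        """
        return np.interp(np.asarray(at, dtype=float), self.times, self.values)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "GlucoseTimeSeries":
        return GlucoseTimeSeries(
            self.times.copy(), np.asarray(values, dtype=float),
            self.label if label is None else label,
        )

    def same_grid(self, other: "GlucoseTimeSeries", atol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.times, other.times, atol=atol)
        )


def require_same_grid(a: GlucoseTimeSeries, b: GlucoseTimeSeries) -> None:
    if not a.same_grid(b):
        raise InvalidInputError("series are not on the same time grid")
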
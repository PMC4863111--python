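"""File formats and configuration: CSV time series, YAML config, JSON results.

Conventions shared by every stage: time is minutes since injection with
t = 0 at injection; CSV files carry the header ``time_min,glucose_mg_dl``
(or ``time_min,counts`` for raw tracer activities) with an optional third
``label`` column; structured results and run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .diffusion import TissueParams
from .errors import ConfigurationError, InvalidInputError, ParseError
from .series import GlucoseTimeSeries
from .simulation import ModelConfig, ModelWeights
from .transport import CapillaryParams, StarlingParams

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "load_model_config",
    "dump_model_config",
    "PipelineConfig",
]

_VALUE_HEADERS = ("glucose_mg_dl", "counts")


def read_timeseries(path: str | Path) -> GlucoseTimeSeries:
    """Parse a CSV time series, enforcing the series invariants.

    Malformed headers, non-numeric cells and non-increasing times raise a
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if (
        len(header) not in (2, 3)
        or header[0] != "time_min"
        or header[1] not in _VALUE_HEADERS
        or (len(header) == 3 and header[2] != "label")
    ):
        raise ParseError(
            f"{path}:1: bad header {lines[0]!r}; expected "
            f"'time_min,glucose_mg_dl[,label]' or 'time_min,counts[,label]'"
        )
    times: list[float] = []
    values: list[float] = []
    label = ""
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}")
        try:
            t, v = float(cells[0]), float(cells[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric cell in {line!r}") from None
        if times and t <= times[-1]:
            raise ParseError(f"{path}:{lineno}: time {t} not strictly increasing")
        times.append(t)
        values.append(v)
        if len(cells) == 3:
            label = cells[2]
    if not times:
        raise ParseError(f"{path}: no data rows")
    try:
        return GlucoseTimeSeries(np.array(times), np.array(values), label=label)
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timeseries(
    series: GlucoseTimeSeries, path: str | Path, value_header: str = "glucose_mg_dl"
) -> None:
    """Write a series as CSV with 6 significant digits; roundtrip-stable."""
    if value_header not in _VALUE_HEADERS:
        raise InvalidInputError(f"unknown value header {value_header!r}")
    path = Path(path)
    with_label = bool(series.label)
    header = f"time_min,{value_header}" + (",label" if with_label else "")
    rows = [header]
    for t, v in zip(series.times, series.values):
        row = f"{t:.6g},{v:.6g}"
        if with_label:
            row += f",{series.label}"
        rows.append(row)
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


# -- model configuration ----------------------------------------------------

_CONFIG_KEYS = {
    "permeability": 25.0,
    "area": 0.12,
    "flow": 3.0,
    "K_f": 1.0,
    "sigma_pi_c": 25.0,
    "P_a": 35.0,
    "P_v": 15.0,
    "D_um2_per_min": 600.0,
    "x_um": 24.0,
    "C_ISF0": 100.0,
    "r_fick": 0.5,
    "r_starling": 0.5,
    "diffusion_mode": "superposition",
    "dt_min": 0.1,
    "fick_feedback": True,
}


def load_model_config(source: str | Path | dict[str, Any]) -> ModelConfig:
    """Build a :class:`ModelConfig` from a YAML file or a mapping.

    Missing keys take the package defaults; unknown keys are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(data) - set(_CONFIG_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**_CONFIG_KEYS, **data}
    return ModelConfig(
        capillary=CapillaryParams(
            permeability=float(cfg["permeability"]),
            area=float(cfg["area"]),
            flow=float(cfg["flow"]),
        ),
        starling=StarlingParams(
            k_f=float(cfg["K_f"]),
            sigma_pi_c=float(cfg["sigma_pi_c"]),
            p_a=float(cfg["P_a"]),
            p_v=float(cfg["P_v"]),
        ),
        tissue=TissueParams(
            d_um2_per_min=float(cfg["D_um2_per_min"]),
            x_um=float(cfg["x_um"]),
            c_isf0=float(cfg["C_ISF0"]),
        ),
        weights=ModelWeights(
            r_fick=float(cfg["r_fick"]), r_starling=float(cfg["r_starling"])
        ),
        diffusion_mode=str(cfg["diffusion_mode"]),
        dt_min=float(cfg["dt_min"]),
        fick_feedback=bool(cfg["fick_feedback"]),
    )


def dump_model_config(config: ModelConfig, path: str | Path) -> None:
    """Write a config as YAML with the canonical flat keys."""
    data = {
        "permeability": config.capillary.permeability,
        "area": config.capillary.area,
        "flow": config.capillary.flow,
        "K_f": config.starling.k_f,
        "sigma_pi_c": config.starling.sigma_pi_c,
        "P_a": config.starling.p_a,
        "P_v": config.starling.p_v,
        "D_um2_per_min": config.tissue.d_um2_per_min,
        "x_um": config.tissue.x_um,
        "C_ISF0": config.tissue.c_isf0,
        "r_fick": config.weights.r_fick,
        "r_starling": config.weights.r_starling,
        "diffusion_mode": config.diffusion_mode,
        "dt_min": config.dt_min,
        "fick_feedback": config.fick_feedback,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline stage needs beyond the model itself."""

    model: ModelConfig
    seed: int = 0
    species: str = "rat"
    out_dir: Path = Path(".")
    blood_path: Path | None = None
    isf_path: Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError("seed must be a nonnegative integer")
        for p in (self.blood_path, self.isf_path):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")


def write_json(obj: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n",
        encoding="utf-8",
    )


def _jsonable(o: Any) -> Any:
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
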
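"""Synthetic inputs with the statistical structure of the two animal protocols.

Three generators cover everything the pipeline consumes:

* a parametric glucose-tolerance-test (GTT) blood profile — baseline,
  smooth monotone rise to a peak near 20 min, exponential relaxation to a
  stationary phase by 80 min;
* a fluorescence readout (mouse-style): a competitive-binding sensor whose
  intensity decreases hyperbolically with glucose, ``I = I0 * K / (K + C)``,
  sampled every 10 min, with multiplicative lognormal noise and an exact
  noiseless inverse;
* an isotope readout (rat-style): tracer activities proportional to
  concentrations with Poisson counting noise, convertible back through the
  activity-ratio relation ``T_blood / T_isf = C_blood / C_isf``.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .diffusion import TissueParams
from .errors import ConfigurationError, InvalidInputError
from .series import GlucoseTimeSeries, require_same_grid
from .simulation import ModelConfig, simulate_isf

__all__ = [
    "GTTProfileParams",
    "FluorescenceParams",
    "FluorescenceSeries",
    "IsotopeSeries",
    "Scenario",
    "generate_blood_gtt",
    "fluorescence_readout",
    "calibrate_fluorescence",
    "isotope_readout",
    "isotope_to_concentration",
    "make_scenario",
]

#: Effective tissue diffusivity (um^2/min) used by the scenario presets.
#: Chosen so that the step response at 24 um reaches half-rise in about
#: 2.4 min, which places the simulated traces in the multi-minute lag
#: regime the animal experiments exhibit.  A package choice.
SCENARIO_D_UM2_PER_MIN = 264.0


@dataclass(frozen=True)
class GTTProfileParams:
    """Shape parameters of the bolus blood-glucose profile (mg/dL, minutes)."""

    baseline: float = 100.0
    t_injection: float = 0.0
    t_peak: float = 20.0
    c_peak: float = 300.0
    t_stationary: float = 80.0
    c_stationary: float = 120.0

    def __post_init__(self) -> None:
        if not (self.t_injection < self.t_peak < self.t_stationary):
            raise ConfigurationError(
                "times must be ordered: injection < peak < stationary"
            )
        if self.c_peak <= self.baseline:
            raise ConfigurationError("peak concentration must exceed baseline")
        if self.baseline < 0 or self.c_stationary < 0:
            raise ConfigurationError("concentrations must be nonnegative")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Noiseless profile value at arbitrary times."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline)
        # smoothstep rise: monotone, stationary at both ends
        rising = (t >= self.t_injection) & (t <= self.t_peak)
        s = (t[rising] - self.t_injection) / (self.t_peak - self.t_injection)
        out[rising] = self.baseline + (self.c_peak - self.baseline) * s * s * (3 - 2 * s)
        # exponential relaxation; time constant chosen so the residual at
        # t_stationary is 1% of the stationary value (or of the gap when
        # the stationary value is ~0)
        gap = self.c_peak - self.c_stationary
        target = 0.01 * (self.c_stationary if self.c_stationary > 1e-9 else gap)
        tau = (self.t_stationary - self.t_peak) / np.log(max(gap / target, np.e))
        falling = t > self.t_peak
        out[falling] = self.c_stationary + (self.c_peak - self.c_stationary) * np.exp(
            -(t[falling] - self.t_peak) / tau
        )
        return out


@dataclass(frozen=True)
class FluorescenceParams:
    """One-site competitive quenching: intensity I0*K/(K + C)."""

    i0: float = 1000.0
    k_half: float = 50.0
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.i0 <= 0 or self.k_half <= 0:
            raise InvalidInputError("i0 and k_half must be positive")
        if self.noise_cv < 0:
            raise InvalidInputError("noise CV must be nonnegative")


@dataclass(frozen=True)
class FluorescenceSeries:
    """Sensor intensities (arbitrary units) at sample times."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.intensities, dtype=float)
        if t.size != v.size:
            raise InvalidInputError("length mismatch")
        if np.any(v <= 0):
            raise InvalidInputError("intensities must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", v)


@dataclass(frozen=True)
class IsotopeSeries:
    """Tracer activities (counts/min) in one compartment."""

    times: np.ndarray
    activities: np.ndarray
    compartment: str = "blood"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activities, dtype=float)
        if t.size != a.size:
            raise InvalidInputError("length mismatch")
        if np.any(a < 0):
            raise InvalidInputError("activities must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activities", a)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def generate_blood_gtt(
    params: GTTProfileParams = GTTProfileParams(),
    sample_interval: float = 10.0,
    seed: int = 0,
    noise_cv: float = 0.0,
    duration: float | None = None,
    times: np.ndarray | None = None,
) -> GlucoseTimeSeries:
    """Sampled GTT blood-glucose series, deterministic under the seed.

    Sampling starts at the injection time with the given cadence unless an
    explicit ``times`` array is supplied (the rat protocol's first draw at
    5 min, for instance).  Noise is multiplicative lognormal.
    """
    if times is None:
        if sample_interval <= 0:
            raise ConfigurationError("sample interval must be positive")
        if duration is None:
            duration = params.t_stationary + 40.0
        times = params.t_injection + np.arange(
            0.0, duration + 0.5 * sample_interval, sample_interval
        )
    times = np.asarray(times, dtype=float)
    values = params.evaluate(times)
    rng = np.random.default_rng(seed)
    values = values * _lognormal_factors(rng, noise_cv, times.size)
    return GlucoseTimeSeries(times, values, label="blood")


def fluorescence_readout(
    glucose: GlucoseTimeSeries,
    params: FluorescenceParams = FluorescenceParams(),
    seed: int = 0,
    noise: bool = True,
) -> FluorescenceSeries:
    """Fluorescent-sensor intensities for a glucose trace.

    Intensity is strictly decreasing in glucose; multiplicative lognormal
    noise (which cannot produce nonpositive intensities) is applied when
    ``noise`` is set.
    """
    ideal = params.i0 * params.k_half / (params.k_half + glucose.values)
    if noise and params.noise_cv > 0:
        rng = np.random.default_rng(seed)
        ideal = ideal * _lognormal_factors(rng, params.noise_cv, ideal.size)
    return FluorescenceSeries(glucose.times.copy(), ideal)


def calibrate_fluorescence(
    readout: FluorescenceSeries, params: FluorescenceParams
) -> GlucoseTimeSeries:
    """Invert the quenching curve: C = K * (I0 / I - 1), floored at zero."""
    conc = params.k_half * (params.i0 / readout.intensities - 1.0)
    return GlucoseTimeSeries(readout.times.copy(), np.clip(conc, 0.0, None), label="isf")


def isotope_readout(
    c_blood: GlucoseTimeSeries,
    c_isf: GlucoseTimeSeries,
    specific_activity: float = 50.0,
    seed: int = 0,
    noise: bool = True,
) -> tuple[IsotopeSeries, IsotopeSeries]:
    """Tracer activities in both compartments, proportional to concentration.

    Expected counts are ``specific_activity * concentration``; Poisson
    counting noise is applied when ``noise`` is set.  Noiselessly the
    activity ratio equals the concentration ratio at every time point.
    """
    require_same_grid(c_blood, c_isf)
    if specific_activity <= 0:
        raise InvalidInputError("specific activity must be positive")
    lam_blood = specific_activity * c_blood.values
    lam_isf = specific_activity * c_isf.values
    if noise:
        rng = np.random.default_rng(seed)
        act_blood = rng.poisson(lam_blood).astype(float)
        act_isf = rng.poisson(lam_isf).astype(float)
    else:
        act_blood, act_isf = lam_blood, lam_isf
    return (
        IsotopeSeries(c_blood.times.copy(), act_blood, "blood"),
        IsotopeSeries(c_isf.times.copy(), act_isf, "isf"),
    )


def isotope_to_concentration(
    t_blood: float | np.ndarray,
    t_isf: float | np.ndarray,
    c_blood: float | np.ndarray,
) -> float | np.ndarray:
    """Interstitial concentration from the activity-ratio relation.

    ``T_blood / T_isf = C_blood / C_isf`` gives
    ``C_isf = C_blood * T_isf / T_blood``.
    """
    t_blood = np.asarray(t_blood, dtype=float)
    if np.any(t_blood <= 0):
        raise InvalidInputError("blood activity must be positive")
    out = np.asarray(c_blood, dtype=float) * np.asarray(t_isf, dtype=float) / t_blood
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Scenario:
    """A fully seeded synthetic experiment bundle."""

    species: str
    seed: int
    blood_true: GlucoseTimeSeries
    isf_true: GlucoseTimeSeries
    blood_measured: GlucoseTimeSeries
    isf_measured: GlucoseTimeSeries
    config: ModelConfig
    readout: object = None  # FluorescenceSeries or (IsotopeSeries, IsotopeSeries)


def make_scenario(
    species: str,
    seed: int = 0,
    noise_cv: float = 0.05,
    x_um: float = 24.0,
    d_um2_per_min: float = SCENARIO_D_UM2_PER_MIN,
    n_animals: int | None = None,
    gtt: GTTProfileParams | None = None,
    config: ModelConfig | None = None,
) -> Scenario:
    """Build a reproducible mouse- or rat-style experiment.

    The mouse protocol samples every 10 min from injection and reads the
    interstitial trace through the fluorescent sensor (intraperitoneal
    bolus: slower rise); the rat protocol takes its first sample 5 min
    after the intravenous injection and reads both compartments through
    tracer activities, converting the interstitial activity back to
    concentration with the measured blood glucose.  Each animal carries
    independent measurement noise and the reported series are
    across-animal means (defaults: 6 mice, 5 rats, matching the cohort
    sizes of the emulated experiments).  The true interstitial trace is
    simulated at ``x_um`` (default 24 um).
    """
    if species not in ("mouse", "rat"):
        raise InvalidInputError(f"unknown species {species!r}")
    rng = np.random.default_rng(seed)
    if n_animals is None:
        n_animals = 6 if species == "mouse" else 5
    if n_animals < 1:
        raise InvalidInputError("need at least one animal")

    if gtt is None:
        gtt = (
            GTTProfileParams(t_peak=25.0, t_stationary=85.0)
            if species == "mouse"
            else GTTProfileParams()
        )
    if species == "mouse":
        times = np.arange(0.0, 120.0 + 1e-9, 10.0)
    else:
        times = np.arange(5.0, 120.0 + 1e-9, 10.0)

    blood_true = GlucoseTimeSeries(times, gtt.evaluate(times), label="blood")
    if config is None:
        config = ModelConfig()
    config = replace(
        config,
        tissue=TissueParams(
            d_um2_per_min=d_um2_per_min, x_um=x_um, c_isf0=gtt.baseline
        ),
    )
    isf_true = simulate_isf(blood_true, config)

    fparams = FluorescenceParams(noise_cv=noise_cv)
    blood_reps = []
    isf_reps = []
    readout = None
    for _ in range(n_animals):
        blood_a = blood_true.values * _lognormal_factors(rng, noise_cv, len(blood_true))
        if species == "mouse":
            readout = fluorescence_readout(
                isf_true, fparams, seed=int(rng.integers(2**31))
            )
            isf_a = calibrate_fluorescence(readout, fparams).values
        else:
            act_blood, act_isf = isotope_readout(
                blood_true, isf_true, specific_activity=50.0,
                seed=int(rng.integers(2**31)),
            )
            readout = (act_blood, act_isf)
            isf_a = isotope_to_concentration(
                act_blood.activities, act_isf.activities, blood_a
            )
        blood_reps.append(blood_a)
        isf_reps.append(isf_a)

    blood_measured = blood_true.with_values(np.mean(blood_reps, axis=0))
    isf_measured = GlucoseTimeSeries(
        times.copy(), np.mean(isf_reps, axis=0), label="isf"
    )

    return Scenario(
        species=species,
        seed=seed,
        blood_true=blood_true,
        isf_true=isf_true,
        blood_measured=blood_measured,
        isf_measured=isf_measured,
        config=config,
        readout=readout,  # last animal's raw readout, for format examples
    )
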
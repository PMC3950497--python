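"""Seeded generators for synthetic SRM chromatograms and plasma profiles.

These generators emulate the statistical structure the downstream analysis
assumes for a scheduled-SRM stepharine assay:

* three transitions of one precursor with fixed relative intensities, the
  quantifier (m/z 161.2) being the most abundant;
* a Gaussian elution peak inside the scheduled retention-time window
  (11.6 +/- 0.3 min by default) over additive white baseline noise of
  configurable RMS;
* a linear area-concentration response across five orders of magnitude
  with concentration-proportional (heteroscedastic) replicate noise, the
  situation that motivates 1/x weighting in calibration;
* plasma concentration-time profiles following a piecewise first-order
  absorption/elimination model, C0*(1-exp(-K1*t)) up to Tmax and
  C0*exp(-Kel*t) afterwards, with multiplicative lognormal measurement
  noise.  The piecewise model is emitted exactly as defined even though it
  is generally discontinuous at Tmax; a continuity check is available to
  callers that care.

Every generator takes an explicit seed (or an already-constructed
``numpy.random.Generator``); there is no hidden global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import (
    STEPHARINE_TRANSITIONS,
    ChromatogramTrace,
    ConcentrationTimeProfile,
    Transition,
)

#: Blood-sampling schedule of the intramuscular study, minutes post dose.
STUDY_SAMPLING_TIMES: tuple[float, ...] = (0, 15, 30, 60, 90, 120, 180, 480, 720, 1440)

#: Calibration standards, ng/mL (0.0001 .. 100 ug/mL printed as ug/mL).
CALIBRATION_LEVELS_NG_ML: tuple[float, ...] = (1e5, 1e4, 1e3, 1e2, 1e1, 1e0, 1e-1)


@dataclass(frozen=True)
class ChromatogramSimConfig:
    """Geometry and response of the simulated scheduled-SRM acquisition."""

    retention_time_center: float = 11.6  # minutes
    retention_time_jitter_sd: float = 0.03  # minutes, run-to-run apex jitter
    peak_width_sd: float = 0.05  # minutes (Gaussian sigma)
    transition_relative_intensities: tuple[float, float, float] = (1.0, 0.45, 0.25)
    response_slope: float = 2000.0  # area units per (ng/mL), quantifier basis
    baseline_rms: float = 5.0  # intensity units
    sampling_interval: float = 0.01  # minutes
    window_start: float = 11.3  # minutes
    window_end: float = 11.9  # minutes
    seed: int = 0
    peak_shape: str = "gaussian"  # "gaussian" | "emg"
    emg_tau: float = 0.05  # minutes, exponential tail constant for "emg"

    def __post_init__(self) -> None:
        fr = self.transition_relative_intensities
        if len(fr) != 3 or any(f <= 0 for f in fr):
            raise ValueError("three positive transition fractions required")
        if fr[0] < max(fr):
            raise ValueError("quantifier fraction must be the largest")
        if not self.window_start < self.retention_time_center < self.window_end:
            raise ValueError("retention_time_center must lie inside the window")
        if self.baseline_rms < 0:
            raise ValueError("baseline_rms must be non-negative")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.window_end - self.window_start < 6 * self.peak_width_sd:
            raise ValueError("window must span at least 6 peak widths")
        if self.peak_shape not in ("gaussian", "emg"):
            raise ValueError(f"unknown peak_shape {self.peak_shape!r}")

    @property
    def transitions(self) -> tuple[Transition, Transition, Transition]:
        return STEPHARINE_TRANSITIONS


@dataclass(frozen=True)
class PKSimConfig:
    """Parameters of the piecewise absorption/elimination plasma model."""

    C0: float = 15.0  # ng/mL
    K1: float = 0.02  # 1/min, first-order absorption
    Kel: float = 0.006  # 1/min, first-order elimination
    Tmax: float = 90.0  # minutes
    sampling_times: tuple[float, ...] = STUDY_SAMPLING_TIMES
    measurement_cv: float = 0.05  # coefficient of variation, fraction
    seed: int = 0
    animal_id: str = "SIM01"
    dose: float = 0.5  # mg

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.Kel <= 0:
            raise ValueError("rate constants must be positive")
        if any(t < 0 for t in self.sampling_times):
            raise ValueError("sampling times must be non-negative")
        if not (min(self.sampling_times) <= self.Tmax <= max(self.sampling_times)):
            raise ValueError("Tmax must lie within the sampling span")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be non-negative")


def piecewise_concentration(
    t, C0: float, K1: float, Kel: float, Tmax: float
) -> np.ndarray:
    """Noiseless model concentration: rising first-order absorption up to
    Tmax, first-order decay afterwards (evaluated as printed; the two
    branches need not agree at Tmax)."""
    t = np.asarray(t, dtype=float)
    return np.where(
        t <= Tmax,
        C0 * (1.0 - np.exp(-K1 * t)),
        C0 * np.exp(-Kel * t),
    )


def _peak_profile(times: np.ndarray, center: float, config: ChromatogramSimConfig) -> np.ndarray:
    """Unit-area elution profile evaluated on ``times``."""
    sigma = config.peak_width_sd
    if config.peak_shape == "gaussian":
        return np.exp(-0.5 * ((times - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    # exponentially-modified Gaussian (tailing robustness option)
    tau = config.emg_tau
    arg = sigma / tau - (times - center) / sigma
    from scipy.special import erfc  # local import keeps numpy-only fast path

    return (
        1.0
        / (2 * tau)
        * np.exp(0.5 * (sigma / tau) ** 2 - (times - center) / tau)
        * erfc(arg / math.sqrt(2))
    )


def simulate_srm_chromatogram(
    config: ChromatogramSimConfig,
    concentration: float,
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
    trace_pad: float = 0.3,
) -> list[ChromatogramTrace]:
    """Simulate the three transition traces of one injection.

    The traces share one time grid spanning the scheduled window plus
    ``trace_pad`` minutes on each side (the pad provides a peak-free
    region for baseline-noise estimation).  Before noise, the quantifier
    peak area equals ``response_slope * concentration`` and each qualifier
    is scaled by its relative intensity.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t0 = config.window_start - trace_pad
    t1 = config.window_end + trace_pad
    n = int(round((t1 - t0) / config.sampling_interval)) + 1
    times = t0 + config.sampling_interval * np.arange(n)

    center = config.retention_time_center
    if config.retention_time_jitter_sd > 0:
        center += rng.normal(0.0, config.retention_time_jitter_sd)
    fractions = np.asarray(config.transition_relative_intensities, dtype=float)
    profile = _peak_profile(times, center, config)

    traces = []
    for transition, frac in zip(config.transitions, fractions):
        area = config.response_slope * concentration * frac
        signal = area * profile
        if config.baseline_rms > 0:
            signal = signal + rng.normal(0.0, config.baseline_rms, size=n)
        traces.append(
            ChromatogramTrace(
                sample_id=sample_id,
                transition=transition,
                times=times.copy(),
                intensities=signal,
            )
        )
    return traces


@dataclass
class CalibrationInjection:
    """One simulated calibrant injection: nominal level, replicate index
    and its three transition traces."""

    level: float  # ng/mL nominal
    replicate: int
    traces: list[ChromatogramTrace]


def simulate_calibration_series(
    config: ChromatogramSimConfig,
    levels: Sequence[float] = CALIBRATION_LEVELS_NG_ML,
    replicates: int = 5,
    noise_cv: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[CalibrationInjection]:
    """Simulate a calibration series with concentration-proportional noise.

    Replicate-to-replicate variation is applied as a multiplicative
    lognormal factor on the effective concentration, so the per-level
    area SD is approximately ``noise_cv`` times the mean area at every
    level -- the heteroscedastic pattern that justifies 1/x weighting.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(l <= 0 for l in levels):
        raise ValueError("calibration levels must be positive")
    diffs = np.diff(levels)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("levels must be strictly monotone")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    injections = []
    for level in levels:
        for rep in range(replicates):
            eff = level * _lognormal_factor(rng, noise_cv)
            traces = simulate_srm_chromatogram(
                config, eff, sample_id=f"cal_{level:g}_r{rep}", rng=rng
            )
            injections.append(CalibrationInjection(level=level, replicate=rep, traces=traces))
    return injections


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative lognormal noise factor with the given CV."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def simulate_pk_profile(config: PKSimConfig) -> ConcentrationTimeProfile:
    """Simulate one animal's plasma concentration-time profile.

    The noiseless mean follows :func:`piecewise_concentration`; each
    measurement is multiplied by a unit-mean lognormal factor with the
    configured CV.  Zero-mean time points (t = 0) remain exactly zero.
    """
    rng = np.random.default_rng(config.seed)
    mean = piecewise_concentration(
        np.asarray(config.sampling_times, dtype=float),
        config.C0,
        config.K1,
        config.Kel,
        config.Tmax,
    )
    points = []
    for t, c in zip(config.sampling_times, mean):
        obs = c * _lognormal_factor(rng, config.measurement_cv) if c > 0 else 0.0
        points.append((float(t), float(obs)))
    return ConcentrationTimeProfile(
        animal_id=config.animal_id, dose=config.dose, points=points
    )


def simulate_study_profiles(
    configs: Sequence[PKSimConfig], seed: int
) -> list[ConcentrationTimeProfile]:
    """Simulate several animals, deriving one child seed per animal from
    ``seed`` so the batch is reproducible as a whole."""
    ss = np.random.SeedSequence(seed)
    profiles = []
    for cfg, child in zip(configs, ss.spawn(len(configs))):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        profiles.append(simulate_pk_profile(replace(cfg, seed=child_seed)))
    return profiles
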
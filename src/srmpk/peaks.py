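"""Peak detection, integration and quality scoring for scheduled SRM.

The analyte elutes inside a known retention-time window, so detection is
deliberately simple: baseline and noise are estimated on a peak-free
flanking region (root-mean-square about the median), the apex is the
maximum baseline-subtracted intensity inside the window, and the peak is
integrated valley-to-valley by the trapezoidal rule.  SNR is apex height
over RMS noise.  No smoothing is applied by default: smoothing changes
areas, and for a targeted assay with a scheduled window it buys little.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ChromatogramTrace, Transition

#: Peaks below this multiple of the RMS noise are not reported.
DETECTION_FLOOR_SNR = 3.0


@dataclass
class NoiseEstimate:
    """Baseline level and RMS noise measured on a peak-free region."""

    rms: float
    baseline_level: float
    region: tuple[float, float]  # minutes

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("rms must be non-negative")


@dataclass
class Peak:
    """An integrated chromatographic peak for one transition."""

    apex_time: float  # minutes
    apex_height: float  # intensity above baseline
    bounds: tuple[float, float]  # minutes
    area: float  # intensity * minutes
    snr: float
    transition: Transition

    def __post_init__(self) -> None:
        if not (self.bounds[0] <= self.apex_time <= self.bounds[1]):
            raise ValueError("peak bounds must contain the apex")
        if self.area < 0 or self.snr < 0:
            raise ValueError("area and snr must be non-negative")


def estimate_rms_noise(
    trace: ChromatogramTrace,
    region: tuple[float, float],
    peak_window: tuple[float, float] | None = None,
    min_samples: int = 20,
) -> NoiseEstimate:
    """Estimate baseline and noise on ``region`` of the trace.

    The baseline is the median intensity in the region; the noise is the
    root-mean-square deviation about that median.  The region must be
    disjoint from the scheduled peak window (checked when given) and
    contain at least ``min_samples`` points.
    """
    lo, hi = region
    if peak_window is not None and lo < peak_window[1] and hi > peak_window[0]:
        raise ValueError(
            f"noise region {region} overlaps the peak window {peak_window}"
        )
    mask = (trace.times >= lo) & (trace.times <= hi)
    values = trace.intensities[mask]
    if values.size < min_samples:
        raise ValueError(
            f"noise region {region} contains {values.size} samples; "
            f"at least {min_samples} required"
        )
    baseline = float(np.median(values))
    rms = float(np.sqrt(np.mean((values - baseline) ** 2)))
    return NoiseEstimate(rms=rms, baseline_level=baseline, region=(lo, hi))


def _walk_to_bound(signal: np.ndarray, apex_idx: int, step: int) -> int:
    """Walk from the apex until the first valley or baseline crossing."""
    i = apex_idx
    while True:
        j = i + step
        if j < 0 or j >= signal.size:
            return i
        if signal[j] <= 0:  # baseline crossing
            return j
        if signal[j] > signal[i]:  # valley at i
            return i
        i = j


def detect_peak(
    trace: ChromatogramTrace,
    window: tuple[float, float],
    noise: NoiseEstimate,
    detection_floor_snr: float = DETECTION_FLOOR_SNR,
) -> Peak | None:
    """Locate and integrate the analyte peak inside the scheduled window.

    Returns None when the apex is below ``detection_floor_snr`` times the
    RMS noise.  Equal apex intensities are broken toward the earliest
    time.  The area is the trapezoidal integral of the baseline-subtracted
    signal between the bounds, floored at zero point-wise.
    """
    lo, hi = window
    if lo < trace.times[0] or hi > trace.times[-1]:
        raise ValueError(
            f"window {window} extends beyond the trace span "
            f"({trace.times[0]}, {trace.times[-1]})"
        )
    signal = trace.intensities - noise.baseline_level
    in_window = np.nonzero((trace.times >= lo) & (trace.times <= hi))[0]
    if in_window.size == 0:
        raise ValueError(f"window {window} contains no samples")
    apex_idx = int(in_window[np.argmax(signal[in_window])])  # argmax: earliest tie wins
    apex_height = float(signal[apex_idx])

    if noise.rms > 0 and apex_height < detection_floor_snr * noise.rms:
        return None
    if apex_height <= 0:
        return None

    left = _walk_to_bound(signal, apex_idx, -1)
    right = _walk_to_bound(signal, apex_idx, +1)
    seg_t = trace.times[left : right + 1]
    seg_s = np.clip(signal[left : right + 1], 0.0, None)
    area = float(np.trapezoid(seg_s, seg_t)) if seg_t.size > 1 else 0.0

    if noise.rms == 0:
        warnings.warn(
            "zero RMS noise with a nonzero apex: SNR reported as infinity",
            stacklevel=2,
        )
        snr = math.inf
    else:
        snr = apex_height / noise.rms
    return Peak(
        apex_time=float(trace.times[apex_idx]),
        apex_height=apex_height,
        bounds=(float(seg_t[0]), float(seg_t[-1])),
        area=area,
        snr=snr,
        transition=trace.transition,
    )


@dataclass
class QualifierCheck:
    """Identity-confirmation verdict from qualifier/quantifier area ratios."""

    results: dict[str, bool]  # transition_id -> passed
    observed_ratios: dict[str, float | None]
    confirmed: bool  # all qualifiers passed
    flags: list[str] = field(default_factory=list)


def qualifier_ratio_check(
    quantifier: Peak,
    qualifiers: dict[str, Peak | None],
    expected_ratios: dict[str, float],
    tolerance: float = 0.3,
) -> QualifierCheck:
    """Confirm identity by comparing qualifier/quantifier area ratios.

    Each qualifier passes when its observed area ratio is within
    ``tolerance`` (relative) of the expected ratio.  A missing qualifier
    peak fails that qualifier but is not an error: the sample remains
    quantifiable, just flagged unconfirmed.
    """
    if quantifier is None or quantifier.area <= 0:
        raise ValueError("quantifier peak must be present with positive area")
    results: dict[str, bool] = {}
    observed: dict[str, float | None] = {}
    flags: list[str] = []
    for tid, expected in expected_ratios.items():
        peak = qualifiers.get(tid)
        if peak is None:
            results[tid] = False
            observed[tid] = None
            flags.append(f"qualifier-missing:{tid}")
            continue
        ratio = peak.area / quantifier.area
        observed[tid] = ratio
        results[tid] = abs(ratio - expected) / expected <= tolerance
        if not results[tid]:
            flags.append(f"qualifier-ratio-out-of-range:{tid}")
    return QualifierCheck(
        results=results,
        observed_ratios=observed,
        confirmed=all(results.values()) if results else True,
        flags=flags,
    )


def purity_fraction(main_area: float, other_areas: list[float]) -> float:
    """Chromatographic purity: percent of total area in the main peak."""
    if main_area < 0 or any(a < 0 for a in other_areas):
        raise ValueError("areas must be non-negative")
    total = main_area + sum(other_areas)
    if total <= 0:
        raise ValueError("at least one area must be positive")
    return 100.0 * main_area / total
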
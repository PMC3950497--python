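"""Matplotlib views of traces, calibration curves and PK profiles."""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationResult
from .io import ChromatogramTrace, ConcentrationTimeProfile
from .pk import PKResult
from .simulate import piecewise_concentration


def plot_chromatogram(trace: ChromatogramTrace, ax=None, window=None):
    """Plot one transition trace, optionally shading the scheduled window."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.times, trace.intensities, lw=0.8)
    if window is not None:
        ax.axvspan(*window, alpha=0.15, color="tab:orange")
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("intensity")
    ax.set_title(f"{trace.sample_id}  {trace.transition.transition_id}")
    return ax


def plot_calibration(result: CalibrationResult, ax=None):
    """Log-log calibration points with the fitted line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for lv in result.accepted_levels:
        ax.plot([lv.nominal_conc] * len(lv.replicate_areas), lv.replicate_areas,
                "o", ms=4, color="tab:blue")
    concs = np.array([lv.nominal_conc for lv in result.accepted_levels])
    grid = np.geomspace(concs.min(), concs.max(), 50)
    ax.plot(grid, result.slope * grid + result.intercept, "-", color="tab:red",
            label=f"area = {result.slope:.3g}·c + {result.intercept:.3g}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("concentration (ng/mL)")
    ax.set_ylabel("peak area")
    ax.legend()
    return ax


def plot_pk_profile(profile: ConcentrationTimeProfile, result: PKResult | None = None, ax=None):
    """Observed concentration-time points with the fitted piecewise model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.times, profile.concentrations, "o-", ms=4, label="observed")
    if result is not None:
        p = result.params
        if p.c0 is not None and p.k1 is not None and p.kel is not None:
            grid = np.linspace(0, profile.times.max(), 400)
            ax.plot(grid, piecewise_concentration(grid, p.c0, p.k1, p.kel, p.tmax),
                    "--", label="model")
    ax.set_xlabel("time after dose (min)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.set_title(profile.animal_id)
    ax.legend()
    return ax
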
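"""Bioanalytical method-validation metrics.

Four quantities, each with its acceptance rule:

* **matrix-influence factor** f = 100 * (A_add - A_end) / A_aq, where
  A_add is the analyte peak area after post-extraction addition to plasma,
  A_end the endogenous (blank) area and A_aq the area of the same amount
  in neat solvent.  On this scale a matrix with no effect gives f ~ 100,
  so the acceptance rule ("within 15%") is evaluated on the deviation
  from unity, 100 * ((A_add - A_end) - A_aq) / A_aq; a ``mode`` switch
  lets callers report the deviation form directly.
* **extraction recovery** R = 100 * C_measured / C_added per spike level,
  with per-level means and a grand mean across levels.
* **selectivity**: the largest blank-matrix response must stay under 20%
  of the summed LOD + LLOQ responses (strict <).
* **freeze-thaw stability**: percent loss versus freshly prepared
  standards after stress cycles; a loss of 10% or less is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .calibration import rsd

MATRIX_EFFECT_MAX_PCT = 15.0
STABILITY_MAX_LOSS_PCT = 10.0
SELECTIVITY_MAX_PCT = 20.0

MatrixMode = Literal["ratio", "deviation"]


@dataclass
class MatrixEffectResult:
    f_factor: float  # percent, on the scale selected by `mode`
    deviation_pct: float  # 100*((A_add-A_end)-A_aq)/A_aq, basis of acceptance
    A_add: float
    A_end: float
    A_aq: float
    mode: MatrixMode
    accepted: bool
    rsd_across_replicates: float | None = None


def matrix_factor(
    A_add: float,
    A_end: float,
    A_aq: float,
    mode: MatrixMode = "ratio",
    threshold_pct: float = MATRIX_EFFECT_MAX_PCT,
) -> MatrixEffectResult:
    """Matrix-influence factor for one spiked-matrix measurement.

    ``mode="ratio"`` (default) reports f = 100*(A_add - A_end)/A_aq, the
    recovered-signal ratio in percent; ``mode="deviation"`` reports the
    suppression/enhancement relative to the neat standard,
    100*((A_add - A_end) - A_aq)/A_aq.  Acceptance always tests the
    deviation form against ``threshold_pct``.
    """
    if any(a < 0 for a in (A_add, A_end, A_aq)):
        raise ValueError("areas must be non-negative")
    if A_aq == 0:
        raise ValueError("A_aq must be positive")
    ratio = 100.0 * (A_add - A_end) / A_aq
    deviation = ratio - 100.0
    f = ratio if mode == "ratio" else deviation
    return MatrixEffectResult(
        f_factor=f,
        deviation_pct=deviation,
        A_add=A_add,
        A_end=A_end,
        A_aq=A_aq,
        mode=mode,
        accepted=abs(deviation) <= threshold_pct,
    )


def matrix_factor_batch(
    measurements: Sequence[tuple[float, float, float]],
    mode: MatrixMode = "ratio",
    threshold_pct: float = MATRIX_EFFECT_MAX_PCT,
) -> MatrixEffectResult:
    """Aggregate matrix factor over replicate (A_add, A_end, A_aq) triples.

    Returns the mean factor with the RSD of the per-replicate factors,
    accepted when the mean deviation from unity is within the threshold.
    """
    if not measurements:
        raise ValueError("measurements must be non-empty")
    singles = [matrix_factor(*m, mode=mode, threshold_pct=threshold_pct) for m in measurements]
    fs = [s.f_factor for s in singles]
    deviations = [s.deviation_pct for s in singles]
    mean_dev = float(np.mean(deviations))
    return MatrixEffectResult(
        f_factor=float(np.mean(fs)),
        deviation_pct=mean_dev,
        A_add=float(np.mean([s.A_add for s in singles])),
        A_end=float(np.mean([s.A_end for s in singles])),
        A_aq=float(np.mean([s.A_aq for s in singles])),
        mode=mode,
        accepted=abs(mean_dev) <= threshold_pct,
        rsd_across_replicates=rsd(fs) if len(fs) >= 2 and np.mean(fs) != 0 else None,
    )


@dataclass
class RecoveryResult:
    level: float  # ng/mL added
    measured_conc: float  # ng/mL (mean when replicated)
    added_conc: float  # ng/mL
    recovery_pct: float
    replicates: int = 1


def recovery(measured: float, added: float) -> float:
    """Extraction recovery percent: 100 * measured / added."""
    if added <= 0:
        raise ValueError("added concentration must be positive")
    if measured < 0:
        raise ValueError("measured concentration must be non-negative")
    return 100.0 * measured / added


def recovery_table(
    per_level: dict[float, Sequence[float]],
) -> tuple[list[RecoveryResult], float]:
    """Per-level mean recoveries and the grand mean across levels.

    ``per_level`` maps added concentration (ng/mL) to replicate measured
    concentrations.  The grand mean averages the per-level mean
    recoveries (each level contributes equally regardless of replicate
    count).
    """
    if not per_level:
        raise ValueError("per_level must be non-empty")
    results = []
    for added in sorted(per_level):
        measured = list(per_level[added])
        if not measured:
            raise ValueError(f"level {added}: no measurements")
        mean_measured = float(np.mean(measured))
        results.append(
            RecoveryResult(
                level=added,
                measured_conc=mean_measured,
                added_conc=added,
                recovery_pct=recovery(mean_measured, added),
                replicates=len(measured),
            )
        )
    grand_mean = float(np.mean([r.recovery_pct for r in results]))
    return results, grand_mean


@dataclass
class SelectivityResult:
    blank_response: float  # largest blank area
    reference_response: float  # LOD + LLOQ summed response
    ratio_pct: float
    accepted: bool
    mode: str = "lod+lloq"


def selectivity_check(
    blank_responses: Sequence[float],
    lod_response: float,
    lloq_response: float,
    threshold_pct: float = SELECTIVITY_MAX_PCT,
    mode: Literal["lod+lloq", "lloq"] = "lod+lloq",
) -> SelectivityResult:
    """Interference check on blank matrix.

    Default mode compares the worst blank response with the summed
    LOD + LLOQ responses; ``mode="lloq"`` is the conventional alternative
    (blank under ``threshold_pct`` of the LLOQ response alone).  Both use
    a strict ``<`` comparison.
    """
    if len(blank_responses) == 0:
        raise ValueError("blank_responses must be non-empty")
    if lod_response <= 0 or lloq_response <= 0:
        raise ValueError("reference responses must be positive")
    reference = lod_response + lloq_response if mode == "lod+lloq" else lloq_response
    worst = float(np.max(blank_responses))
    ratio = 100.0 * worst / reference
    return SelectivityResult(
        blank_response=worst,
        reference_response=reference,
        ratio_pct=ratio,
        accepted=ratio < threshold_pct,
        mode=mode,
    )


@dataclass
class StabilityResult:
    level: float  # ng/mL
    fresh_response: float
    stressed_response: float
    loss_pct: float
    accepted: bool

    @property
    def stability_pct(self) -> float:
        return 100.0 - self.loss_pct


def freeze_thaw_stability(
    fresh: float,
    stressed: float,
    level: float = float("nan"),
    max_loss_pct: float = STABILITY_MAX_LOSS_PCT,
) -> StabilityResult:
    """Loss after freeze-thaw stress versus a fresh standard, percent."""
    if fresh <= 0:
        raise ValueError("fresh response must be positive")
    if stressed < 0:
        raise ValueError("stressed response must be non-negative")
    loss = 100.0 * (fresh - stressed) / fresh
    return StabilityResult(
        level=level,
        fresh_response=fresh,
        stressed_response=stressed,
        loss_pct=loss,
        accepted=loss <= max_loss_pct,
    )


def validation_report_frame(
    matrix: MatrixEffectResult | None = None,
    recoveries: Sequence[RecoveryResult] = (),
    recovery_grand_mean: float | None = None,
    selectivity: SelectivityResult | None = None,
    stability: Sequence[StabilityResult] = (),
) -> pd.DataFrame:
    """Assemble the one-row-per-metric-per-level validation report."""
    rows: list[dict] = []
    if matrix is not None:
        rows.append(
            {
                "metric": "matrix_effect",
                "level_ng_ml": 30.0,
                "value": matrix.f_factor,
                "unit": f"% ({matrix.mode})",
                "rsd_pct": matrix.rsd_across_replicates,
                "accepted": matrix.accepted,
            }
        )
    for r in recoveries:
        rows.append(
            {
                "metric": "recovery",
                "level_ng_ml": r.level,
                "value": r.recovery_pct,
                "unit": "%",
                "rsd_pct": None,
                "accepted": True,
            }
        )
    if recovery_grand_mean is not None:
        rows.append(
            {
                "metric": "recovery_grand_mean",
                "level_ng_ml": None,
                "value": recovery_grand_mean,
                "unit": "%",
                "rsd_pct": None,
                "accepted": True,
            }
        )
    if selectivity is not None:
        rows.append(
            {
                "metric": "selectivity",
                "level_ng_ml": None,
                "value": selectivity.ratio_pct,
                "unit": "% of reference",
                "rsd_pct": None,
                "accepted": selectivity.accepted,
            }
        )
    for s in stability:
        rows.append(
            {
                "metric": "freeze_thaw_loss",
                "level_ng_ml": s.level,
                "value": s.loss_pct,
                "unit": "%",
                "rsd_pct": None,
                "accepted": s.accepted,
            }
        )
    return pd.DataFrame(rows)
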
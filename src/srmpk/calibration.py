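"""Weighted linear calibration with LOD/LLOQ decision rules.

The assay response (quantifier peak area) is modelled as a straight line
in concentration, ``area = slope * conc + intercept``, fitted by weighted
least squares.  Because replicate noise is proportional to concentration
over the five-decade calibration range, equal weighting would let the top
calibrators dominate; 1/x weighting (w_i = 1/conc_i) restores balance and
is the default.

A calibration level enters the fit only if it passes the assay acceptance
rules: mean signal-to-noise ratio above ``snr_min`` (default 7.0) and
replicate RSD below ``rsd_max`` (default 15%).  The limit of detection
(LOD) is the lowest level passing the SNR rule alone; the lower limit of
quantitation (LLOQ) additionally requires RSD <= ``rsd_max``.

The fit itself is delegated to statsmodels WLS; this module owns the
acceptance logic, the weighted goodness-of-fit definition and the
back-calculation rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

SNR_MIN_DEFAULT = 7.0
RSD_MAX_DEFAULT = 15.0

Weighting = Literal["none", "1/x", "1/x2"]


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, percent: 100 * sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("rsd requires at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("rsd undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass
class CalibrationLevel:
    """Replicate areas measured at one nominal concentration."""

    nominal_conc: float  # ng/mL
    replicate_areas: list[float]
    mean_snr: float | None = None  # unknown when not measured

    def __post_init__(self) -> None:
        if not self.replicate_areas:
            raise ValueError("replicate_areas must be non-empty")
        if self.nominal_conc <= 0:
            raise ValueError("nominal concentration must be positive")

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.replicate_areas))

    @property
    def rsd(self) -> float | None:
        if len(self.replicate_areas) < 2:
            return None
        return rsd(self.replicate_areas)


def _passes_snr(level: CalibrationLevel, snr_min: float) -> bool:
    # unknown SNR does not veto a level; the rule is applied when measured
    return level.mean_snr is None or level.mean_snr > snr_min


def _passes_rsd(level: CalibrationLevel, rsd_max: float, inclusive: bool) -> bool:
    r = level.rsd
    if r is None:
        return True
    return r <= rsd_max if inclusive else r < rsd_max


def determine_lod_lloq(
    levels: Sequence[CalibrationLevel],
    snr_min: float = SNR_MIN_DEFAULT,
    rsd_max: float = RSD_MAX_DEFAULT,
) -> tuple[float, float | None]:
    """Decide LOD and LLOQ from per-level SNR and RSD summaries.

    LOD: lowest concentration whose mean SNR exceeds ``snr_min`` (strict,
    "more than").  LLOQ: lowest concentration additionally showing
    replicate RSD <= ``rsd_max``.  A level whose SNR was not measured
    does not veto detection (the rule applies where SNR is known), and a
    single-replicate level has no RSD to fail.  Raises when no level
    meets the LOD rule; returns ``(lod, None)`` when detection succeeds
    but no level is precise enough to quantify.
    """
    ordered = sorted(levels, key=lambda lv: lv.nominal_conc)
    lod = next(
        (lv.nominal_conc for lv in ordered if _passes_snr(lv, snr_min)),
        None,
    )
    if lod is None:
        raise ValueError(f"no calibration level reaches SNR > {snr_min}")
    lloq = next(
        (lv.nominal_conc for lv in ordered
         if _passes_snr(lv, snr_min) and _passes_rsd(lv, rsd_max, inclusive=True)),
        None,
    )
    return lod, lloq


@dataclass
class HeteroscedasticityResult:
    variance_ratio: float  # high-level variance / low-level variance
    f_critical: float
    heteroscedastic: bool
    df_high: int
    df_low: int


def assess_heteroscedasticity(
    low_level: CalibrationLevel,
    high_level: CalibrationLevel,
    alpha: float = 0.05,
) -> HeteroscedasticityResult:
    """Compare replicate variances of the lowest and highest calibrators.

    Returns the variance ratio (high/low) and an F-test verdict: the
    response is called heteroscedastic when the ratio exceeds the upper
    critical F value at ``alpha``.
    """
    lo = np.asarray(low_level.replicate_areas, dtype=float)
    hi = np.asarray(high_level.replicate_areas, dtype=float)
    if lo.size < 2 or hi.size < 2:
        raise ValueError("both levels need at least 2 replicates")
    var_lo = lo.var(ddof=1)
    var_hi = hi.var(ddof=1)
    crit = float(scipy.stats.f.ppf(1 - alpha, hi.size - 1, lo.size - 1))
    if var_lo == 0:
        ratio = math.inf if var_hi > 0 else 1.0
    else:
        ratio = float(var_hi / var_lo)
    return HeteroscedasticityResult(
        variance_ratio=ratio,
        f_critical=crit,
        heteroscedastic=ratio > crit,
        df_high=hi.size - 1,
        df_low=lo.size - 1,
    )


@dataclass
class BackCalcResult:
    conc: float  # ng/mL (floored at 0)
    raw_conc: float  # unfloored (area - intercept)/slope
    flags: list[str] = field(default_factory=list)


@dataclass
class CalibrationResult:
    """Fitted calibration curve plus its acceptance bookkeeping."""

    slope: float  # area per (ng/mL)
    intercept: float  # area
    slope_se: float
    intercept_se: float
    weighting: Weighting
    r_squared: float  # weighted Pearson r^2 on the fitted model
    r_squared_back_calc: float  # unweighted r^2, back-calculated vs nominal
    lod: float  # ng/mL
    lloq: float | None  # ng/mL
    levels: list[CalibrationLevel]
    accepted_levels: list[CalibrationLevel]
    excluded_levels: list[tuple[CalibrationLevel, str]]  # (level, reason)
    n_points: int

    def back_calculate(self, area: float) -> BackCalcResult:
        """Convert a measured area to concentration with LOD/LLOQ flags."""
        if self.slope <= 0:
            raise ValueError("back-calculation requires a positive slope")
        raw = (area - self.intercept) / self.slope
        flags: list[str] = []
        conc = raw
        if raw < 0:
            conc = 0.0
            flags.append("negative-raw-reported-0")
        if conc < self.lod:
            flags.append("not-detected")
        elif self.lloq is not None and conc < self.lloq:
            flags.append("below-LLOQ")
        return BackCalcResult(conc=conc, raw_conc=raw, flags=flags)

    def summary(self) -> str:
        lines = [
            "Weighted linear calibration",
            "===========================",
            f"slope      {self.slope:.6g} area/(ng/mL)  (SE {self.slope_se:.3g})",
            f"intercept  {self.intercept:.6g} area        (SE {self.intercept_se:.3g})",
            f"weighting  {self.weighting}",
            f"r^2        {self.r_squared:.6f} (weighted)  "
            f"{self.r_squared_back_calc:.6f} (back-calculated)",
            f"LOD        {self.lod:g} ng/mL",
            f"LLOQ       {'none' if self.lloq is None else f'{self.lloq:g} ng/mL'}",
            f"levels     {len(self.accepted_levels)} accepted, "
            f"{len(self.excluded_levels)} excluded, {self.n_points} points fitted",
        ]
        for lv, reason in self.excluded_levels:
            lines.append(f"  excluded {lv.nominal_conc:g} ng/mL: {reason}")
        return "\n".join(lines)

    def report_frame(self) -> pd.DataFrame:
        """Per-level calibration report (mean area, RSD, SNR, acceptance)."""
        rows = []
        excluded = {id(lv): reason for lv, reason in self.excluded_levels}
        for lv in sorted(self.levels, key=lambda l: l.nominal_conc):
            rows.append(
                {
                    "nominal_conc_ng_ml": lv.nominal_conc,
                    "n_replicates": len(lv.replicate_areas),
                    "mean_area": lv.mean_area,
                    "rsd_pct": lv.rsd,
                    "mean_snr": lv.mean_snr,
                    "accepted": id(lv) not in excluded,
                    "exclusion_reason": excluded.get(id(lv), ""),
                }
            )
        return pd.DataFrame(rows)


class CalibrationModel:
    """Weighted linear calibration model over replicate calibrant areas.

    Parameters
    ----------
    levels:
        Per-concentration replicate areas (with mean SNR when available).
    weighting:
        "none", "1/x" (default) or "1/x2"; weights are 1, 1/conc, 1/conc^2.
    snr_min, rsd_max:
        Acceptance rules applied before fitting (levels failing them are
        excluded and recorded) and reused for the LOD/LLOQ decision.
    fit_on:
        "replicates" fits every replicate point (default); "means" fits
        the per-level mean areas.
    """

    def __init__(
        self,
        levels: Sequence[CalibrationLevel],
        weighting: Weighting = "1/x",
        snr_min: float = SNR_MIN_DEFAULT,
        rsd_max: float = RSD_MAX_DEFAULT,
        fit_on: Literal["replicates", "means"] = "replicates",
    ) -> None:
        if weighting not in ("none", "1/x", "1/x2"):
            raise ValueError(f"unknown weighting {weighting!r}")
        if fit_on not in ("replicates", "means"):
            raise ValueError(f"unknown fit_on {fit_on!r}")
        self.levels = list(levels)
        self.weighting = weighting
        self.snr_min = snr_min
        self.rsd_max = rsd_max
        self.fit_on = fit_on

    def _split_levels(self) -> tuple[list[CalibrationLevel], list[tuple[CalibrationLevel, str]]]:
        accepted, excluded = [], []
        for lv in self.levels:
            if not _passes_snr(lv, self.snr_min):
                excluded.append((lv, f"SNR {lv.mean_snr:g} <= {self.snr_min:g}"))
            elif not _passes_rsd(lv, self.rsd_max, inclusive=False):
                excluded.append((lv, f"RSD {lv.rsd:.2f}% >= {self.rsd_max:g}%"))
            else:
                accepted.append(lv)
        return accepted, excluded

    def fit(self) -> CalibrationResult:
        accepted, excluded = self._split_levels()
        if len(accepted) < 3:
            raise ValueError(
                f"only {len(accepted)} calibration levels pass acceptance; "
                "at least 3 required"
            )
        xs, ys = [], []
        for lv in accepted:
            if self.fit_on == "means":
                xs.append(lv.nominal_conc)
                ys.append(lv.mean_area)
            else:
                xs.extend([lv.nominal_conc] * len(lv.replicate_areas))
                ys.extend(lv.replicate_areas)
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        if np.unique(x).size < 2:
            raise ValueError("all accepted levels share one concentration")

        if self.weighting == "none":
            w = np.ones_like(x)
        elif self.weighting == "1/x":
            w = 1.0 / x
        else:
            w = 1.0 / x**2

        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        intercept, slope = res.params
        intercept_se, slope_se = res.bse

        # LOD/LLOQ consider every measured level: a level too imprecise to
        # enter the fit can still set the detection limit.
        lod, lloq = determine_lod_lloq(self.levels, self.snr_min, self.rsd_max)
        r2w = _weighted_pearson_r2(x, y, w)
        back = (y - intercept) / slope if slope != 0 else np.zeros_like(y)
        r2b = _weighted_pearson_r2(x, back, np.ones_like(x))
        return CalibrationResult(
            slope=float(slope),
            intercept=float(intercept),
            slope_se=float(slope_se),
            intercept_se=float(intercept_se),
            weighting=self.weighting,
            r_squared=r2w,
            r_squared_back_calc=r2b,
            lod=lod,
            lloq=lloq,
            levels=self.levels,
            accepted_levels=accepted,
            excluded_levels=excluded,
            n_points=int(x.size),
        )


def _weighted_pearson_r2(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx = float(np.sum(w * x))
    my = float(np.sum(w * y))
    cov = float(np.sum(w * (x - mx) * (y - my)))
    vx = float(np.sum(w * (x - mx) ** 2))
    vy = float(np.sum(w * (y - my) ** 2))
    if vx == 0 or vy == 0:
        return float("nan")
    return cov * cov / (vx * vy)


def fit_weighted_linear(
    levels: Sequence[CalibrationLevel],
    weighting: Weighting = "1/x",
    snr_min: float = SNR_MIN_DEFAULT,
    rsd_max: float = RSD_MAX_DEFAULT,
    fit_on: Literal["replicates", "means"] = "replicates",
) -> CalibrationResult:
    """Functional convenience wrapper around :class:`CalibrationModel`."""
    return CalibrationModel(levels, weighting, snr_min, rsd_max, fit_on).fit()


def back_calculate(curve: CalibrationResult, area: float) -> BackCalcResult:
    """Convert a measured area to concentration using a fitted curve."""
    return curve.back_calculate(area)
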
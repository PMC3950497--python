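"""Non-compartmental and model-based pharmacokinetics.

Quantities computed per animal from a plasma concentration-time profile:

* observed C_max and T_max (ties broken toward the earlier time);
* terminal elimination constant K_el as the negative slope of the
  log-linear regression over the terminal points (strictly after T_max,
  positive concentration, at least ``min_points``), with the
  extrapolated intercept C_0 = exp(intercept);
* half-life T_1/2 = ln(2)/K_el;
* AUC by the trapezoidal rule over the observed points, extrapolated to
  infinity from the last point as C_last/K_el;
* the closed-form AUC of the piecewise first-order
  absorption/elimination model from t_start (default 15 min, the first
  sampling time) to infinity:

      AUC = C0 * [ (Tmax - t_start)
                   + (exp(-K1*Tmax) - exp(-K1*t_start)) / K1
                   + exp(-Kel*Tmax) / Kel ]

* total body clearance CL = dose / AUC (mg converted to ng inside).

:class:`PKModel` wraps the whole per-animal analysis statsmodels-style:
construct from a profile, call :meth:`PKModel.fit`, read estimates,
diagnostics and ``summary()`` off the returned :class:`PKResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .io import ConcentrationTimeProfile
from .simulate import piecewise_concentration

T_START_DEFAULT = 15.0  # minutes; the first post-dose sampling time
FLAG_INSUFFICIENT_TERMINAL = "insufficient-terminal-points"
FLAG_INSUFFICIENT_RISING = "insufficient-rising-points"


def observed_cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Observed maximum concentration and its time (earliest on ties)."""
    concs = profile.concentrations
    if concs.size == 0 or np.all(concs == 0):
        raise ValueError(f"profile {profile.animal_id}: no nonzero concentrations")
    idx = int(np.argmax(concs))  # argmax returns the first maximum
    return float(concs[idx]), float(profile.times[idx])


@dataclass
class TerminalFit:
    """Log-linear terminal-phase regression result."""

    kel: float | None  # 1/min
    c0_extrapolated: float | None  # ng/mL, exp(intercept)
    r_squared: float | None
    n_points: int
    flags: list[str] = field(default_factory=list)


def terminal_elimination_fit(
    profile: ConcentrationTimeProfile,
    min_points: int = 3,
    after_time: float | None = None,
) -> TerminalFit:
    """Fit ln(conc) against time over the terminal phase.

    Terminal points are those strictly after ``after_time`` (observed
    T_max by default) with positive concentration; zero concentrations
    are excluded (log undefined).  With fewer than ``min_points`` the
    result carries the insufficient-terminal-points flag and no K_el.
    """
    if after_time is None:
        _, after_time = observed_cmax_tmax(profile)
    t = profile.times
    c = profile.concentrations
    mask = (t > after_time) & (c > 0)
    if int(mask.sum()) < min_points:
        return TerminalFit(
            kel=None,
            c0_extrapolated=None,
            r_squared=None,
            n_points=int(mask.sum()),
            flags=[FLAG_INSUFFICIENT_TERMINAL],
        )
    res = scipy.stats.linregress(t[mask], np.log(c[mask]))
    return TerminalFit(
        kel=float(-res.slope),
        c0_extrapolated=float(math.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        n_points=int(mask.sum()),
    )


def half_life(kel: float) -> float:
    """Terminal half-life ln(2)/K_el, minutes."""
    if kel <= 0:
        raise ValueError("Kel must be positive")
    return math.log(2) / kel


def auc_trapezoidal(points: Sequence[tuple[float, float]]) -> float:
    """Linear trapezoidal AUC over the observed points, ng*min/mL."""
    if len(points) < 2:
        raise ValueError("at least 2 points required")
    t = np.asarray([p[0] for p in points], dtype=float)
    c = np.asarray([p[1] for p in points], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(c, t))


def auc_extrapolate_to_infinity(last_time: float, last_conc: float, kel: float) -> float:
    """Tail AUC from the last observed point to infinity: C_last/K_el."""
    if kel <= 0:
        raise ValueError("Kel must be positive")
    if last_conc < 0:
        raise ValueError("last concentration must be non-negative")
    return last_conc / kel


def auc_model_closed_form(
    C0: float,
    K1: float,
    Kel: float,
    Tmax: float,
    t_start: float = T_START_DEFAULT,
) -> float:
    """Closed-form AUC of the piecewise model from t_start to infinity.

    Integrates C0*(1 - exp(-K1*t)) from t_start to Tmax plus
    C0*exp(-Kel*t) from Tmax to infinity.
    """
    if K1 <= 0 or Kel <= 0:
        raise ValueError("rate constants must be positive")
    if Tmax <= t_start:
        raise ValueError("Tmax must exceed t_start")
    return C0 * (
        (Tmax - t_start)
        + (math.exp(-K1 * Tmax) - math.exp(-K1 * t_start)) / K1
        + math.exp(-Kel * Tmax) / Kel
    )


def clearance(dose_mg: float, auc: float) -> float:
    """Total body clearance, mL/min: dose (mg -> ng) over AUC (ng*min/mL)."""
    if auc <= 0:
        raise ValueError("AUC must be positive")
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    return dose_mg * 1e6 / auc


@dataclass
class AbsorptionFit:
    """Rising-phase absorption fit: K1 with the profiled plateau C0."""

    k1: float | None  # 1/min
    c0_rising: float | None  # ng/mL plateau of the absorption branch
    sse: float | None  # ng^2/mL^2, concentration-space residual
    n_points: int
    flags: list[str] = field(default_factory=list)


def _k1_given_plateau(t: np.ndarray, c: np.ndarray, c0: float) -> tuple[float, float]:
    """Closed-form through-origin fit of ln(1 - c/c0) = -K1*t; returns
    (K1, SSE in concentration space)."""
    y = np.log(1.0 - c / c0)
    k1 = float(-(t @ y) / (t @ t))
    pred = c0 * (1.0 - np.exp(-k1 * t))
    return k1, float(np.sum((pred - c) ** 2))


def fit_absorption_model(
    profile: ConcentrationTimeProfile,
    min_rising: int = 2,
    min_terminal: int = 3,
    refine: bool = False,
) -> tuple[AbsorptionFit, TerminalFit, float]:
    """Fit the piecewise absorption/elimination model to one profile.

    T_max is fixed at the observed value.  K_el and the extrapolated C_0
    come from the terminal log-linear fit.  K_1 is estimated on the
    rising phase (0 < t <= T_max, conc > 0) by profiling the plateau
    concentration: for each candidate plateau the through-origin
    regression of ln(1 - conc/plateau) on time gives K_1 in closed form,
    and the plateau minimising the concentration-space SSE is selected
    with a bounded scalar search.  ``refine=True`` runs an additional
    full nonlinear least-squares polish of (plateau, K_1) and is an
    explicitly labelled option, not the default.

    Returns ``(absorption_fit, terminal_fit, tmax)``.
    """
    cmax, tmax = observed_cmax_tmax(profile)
    terminal = terminal_elimination_fit(profile, min_points=min_terminal)

    t_all = profile.times
    c_all = profile.concentrations
    rising = (t_all > 0) & (t_all <= tmax) & (c_all > 0)
    t = t_all[rising]
    c = c_all[rising]
    if t.size < min_rising:
        return (
            AbsorptionFit(
                k1=None, c0_rising=None, sse=None, n_points=int(t.size),
                flags=[FLAG_INSUFFICIENT_RISING],
            ),
            terminal,
            tmax,
        )

    cmax_rise = float(c.max())
    lo = cmax_rise * (1.0 + 1e-6)
    hi = cmax_rise * 50.0

    def objective(c0: float) -> float:
        return _k1_given_plateau(t, c, c0)[1]

    res = scipy.optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": cmax_rise * 1e-9},
    )
    c0_best = float(res.x)
    k1, sse = _k1_given_plateau(t, c, c0_best)

    if refine:
        def model(tt, c0, kk1):
            return c0 * (1.0 - np.exp(-kk1 * tt))

        try:
            popt, _ = scipy.optimize.curve_fit(
                model, t, c, p0=[c0_best, k1],
                bounds=([cmax_rise, 1e-6], [np.inf, 10.0]),
            )
            c0_best, k1 = float(popt[0]), float(popt[1])
            sse = float(np.sum((model(t, *popt) - c) ** 2))
        except RuntimeError:
            pass  # keep the profiled solution

    return (
        AbsorptionFit(k1=k1, c0_rising=c0_best, sse=sse, n_points=int(t.size)),
        terminal,
        tmax,
    )


@dataclass
class PKParameters:
    """One animal's pharmacokinetic parameter set."""

    animal_id: str
    dose: float  # mg
    cmax: float  # ng/mL
    tmax: float  # minutes
    k1: float | None  # 1/min
    kel: float | None  # 1/min
    t_half: float | None  # minutes
    c0: float | None  # ng/mL (terminal extrapolated intercept by default)
    auc15: float | None  # ng*min/mL, closed-form model AUC from t_start
    auc_trapz: float  # ng*min/mL, trapezoid over observed points
    auc_inf: float | None  # ng*min/mL, trapezoid + C_last/Kel tail
    cl: float | None  # mL/min, dose/auc15
    flags: list[str] = field(default_factory=list)


@dataclass
class PKResult:
    """Fit result carrying the parameter estimates and diagnostics."""

    params: PKParameters
    terminal: TerminalFit
    absorption: AbsorptionFit
    residuals: np.ndarray | None  # model minus observed, ng/mL

    def summary(self) -> str:
        p = self.params
        def fmt(v, spec=".4g", unit=""):
            return "n/a" if v is None else f"{v:{spec}}{unit}"

        lines = [
            f"Pharmacokinetic analysis: animal {p.animal_id} (dose {p.dose:g} mg)",
            "=" * 58,
            f"Cmax       {p.cmax:.4g} ng/mL      Tmax  {p.tmax:g} min",
            f"K1         {fmt(p.k1, '.3g', ' 1/min')}",
            f"Kel        {fmt(p.kel, '.3g', ' 1/min')}   "
            f"(terminal n={self.terminal.n_points}, "
            f"r^2={fmt(self.terminal.r_squared, '.4f')})",
            f"T1/2       {fmt(p.t_half, '.4g', ' min')}",
            f"C0         {fmt(p.c0, '.4g', ' ng/mL')}",
            f"AUC15-inf  {fmt(p.auc15, '.5g', ' ng*min/mL')} (model closed form)",
            f"AUC trapz  {p.auc_trapz:.5g} ng*min/mL"
            + (f"   AUC0-inf {fmt(p.auc_inf, '.5g')}" if p.auc_inf is not None else ""),
            f"CL         {fmt(p.cl, '.4g', ' mL/min')}",
        ]
        if p.flags:
            lines.append(f"flags      {', '.join(p.flags)}")
        return "\n".join(lines)


class PKModel:
    """Per-animal pharmacokinetic model over a concentration-time profile.

    Parameters
    ----------
    profile:
        The animal's plasma measurements.
    t_start:
        Lower limit of the model AUC integral, minutes.
    min_terminal, min_rising:
        Minimum point counts for the two regression phases.
    c0_override, k1_override, kel_override:
        Externally supplied model parameters (e.g. from an independent
        software fit); when given they replace the corresponding
        regression estimate in the closed-form AUC and clearance.
    """

    def __init__(
        self,
        profile: ConcentrationTimeProfile,
        t_start: float = T_START_DEFAULT,
        min_terminal: int = 3,
        min_rising: int = 2,
        c0_override: float | None = None,
        k1_override: float | None = None,
        kel_override: float | None = None,
    ) -> None:
        self.profile = profile
        self.t_start = t_start
        self.min_terminal = min_terminal
        self.min_rising = min_rising
        self.c0_override = c0_override
        self.k1_override = k1_override
        self.kel_override = kel_override

    def fit(self) -> PKResult:
        profile = self.profile
        cmax, tmax = observed_cmax_tmax(profile)
        absorption, terminal, _ = fit_absorption_model(
            profile, min_rising=self.min_rising, min_terminal=self.min_terminal
        )
        flags = list(dict.fromkeys(absorption.flags + terminal.flags))

        kel = self.kel_override if self.kel_override is not None else terminal.kel
        c0 = self.c0_override if self.c0_override is not None else terminal.c0_extrapolated
        k1 = self.k1_override if self.k1_override is not None else absorption.k1

        t_half = half_life(kel) if kel is not None else None
        auc_trapz = auc_trapezoidal(profile.points)
        auc_inf = None
        if kel is not None:
            last_t, last_c = profile.points[-1]
            auc_inf = auc_trapz + auc_extrapolate_to_infinity(last_t, last_c, kel)
        auc15 = None
        cl = None
        if kel is not None and k1 is not None and c0 is not None:
            auc15 = auc_model_closed_form(c0, k1, kel, tmax, self.t_start)
            cl = clearance(profile.dose, auc15)

        residuals = None
        if kel is not None and k1 is not None and c0 is not None:
            pred = piecewise_concentration(profile.times, c0, k1, kel, tmax)
            residuals = pred - profile.concentrations

        params = PKParameters(
            animal_id=profile.animal_id,
            dose=profile.dose,
            cmax=cmax,
            tmax=tmax,
            k1=k1,
            kel=kel,
            t_half=t_half,
            c0=c0,
            auc15=auc15,
            auc_trapz=auc_trapz,
            auc_inf=auc_inf,
            cl=cl,
            flags=flags,
        )
        return PKResult(
            params=params, terminal=terminal, absorption=absorption, residuals=residuals
        )


def pk_report_frame(results: Sequence[PKResult]) -> pd.DataFrame:
    """Tabulate per-animal PK parameters, one row per animal.

    Values are stored at full precision; round for display only.
    """
    rows = []
    for r in results:
        p = r.params
        rows.append(
            {
                "animal_id": p.animal_id,
                "dose_mg": p.dose,
                "cmax_ng_ml": p.cmax,
                "tmax_min": p.tmax,
                "k1_per_min": p.k1,
                "kel_per_min": p.kel,
                "t_half_min": p.t_half,
                "c0_ng_ml": p.c0,
                "auc15_ng_min_ml": p.auc15,
                "auc_trapz_ng_min_ml": p.auc_trapz,
                "cl_ml_min": p.cl,
                "flags": ";".join(p.flags),
            }
        )
    return pd.DataFrame(rows)
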
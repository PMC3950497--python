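"""Readers and writers for chromatogram and tabular data.

The package exchanges data through three plain CSV schemas:

* chromatogram CSV: ``sample_id, transition_id, time_min, intensity``,
  one row per acquired point, where ``transition_id`` encodes the SRM
  transition as ``<precursor>><product>|<role>`` (e.g. ``298.4>161.2|quantifier``);
* sample sheet CSV: ``sample_id, role, nominal_conc_ng_ml, animal_id,
  time_min, dose_mg`` describing what each acquired sample is;
* concentration table CSV: ``animal_id, time_min, conc_ng_ml, dose_mg``
  (the literal token ``n/a`` or an empty cell marks a missing measurement).

Canonical units everywhere: minutes, ng/mL, mg.  Any unit conversion
(e.g. mzML retention times in seconds) happens at this boundary.

SRM chromatograms exported to the mzML standard can additionally be read
(read-only) through :func:`read_mzml_chromatograms`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

QUANTIFIER = "quantifier"
QUALIFIER = "qualifier"

#: Stepharine [M+H]+ SRM transitions: the m/z 161.2 fragment is the
#: quantifier, m/z 192.1 and 238.2 confirm identity as qualifiers.
STEPHARINE_TRANSITIONS: tuple["Transition", ...]


@dataclass(frozen=True, order=True)
class Transition:
    """A precursor -> product ion pair monitored in SRM mode."""

    precursor_mz: float
    product_mz: float
    role: str = QUALIFIER

    def __post_init__(self) -> None:
        if self.role not in (QUANTIFIER, QUALIFIER):
            raise ValueError(f"unknown transition role {self.role!r}")
        if not self.product_mz < self.precursor_mz:
            raise ValueError(
                f"product m/z {self.product_mz} must be below precursor "
                f"m/z {self.precursor_mz}"
            )

    @property
    def transition_id(self) -> str:
        return f"{self.precursor_mz:g}>{self.product_mz:g}|{self.role}"

    @classmethod
    def from_transition_id(cls, transition_id: str) -> "Transition":
        m = re.fullmatch(r"([\d.]+)>([\d.]+)\|(\w+)", transition_id)
        if m is None:
            raise DataError(f"unparseable transition_id {transition_id!r}")
        return cls(float(m.group(1)), float(m.group(2)), m.group(3))


STEPHARINE_TRANSITIONS = (
    Transition(298.4, 161.2, QUANTIFIER),
    Transition(298.4, 192.1, QUALIFIER),
    Transition(298.4, 238.2, QUALIFIER),
)


@dataclass
class ChromatogramTrace:
    """Time/intensity series of one SRM transition for one sample."""

    sample_id: str
    transition: Transition
    times: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray  # detector units

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise DataError(
                f"trace {self.sample_id}/{self.transition.transition_id}: "
                "times and intensities must be 1-D arrays of equal length"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise DataError(
                f"trace {self.sample_id}/{self.transition.transition_id}: "
                "times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise DataError(
                f"trace {self.sample_id}/{self.transition.transition_id}: "
                "intensities must be finite"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChromatogramTrace):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.transition == other.transition
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass
class SampleRecord:
    """One acquired sample and its role in the batch."""

    sample_id: str
    role: str  # blank | calibrant | qc | study
    nominal_conc: float | None = None  # ng/mL
    animal_id: str | None = None
    time_point: float | None = None  # minutes
    dose: float | None = None  # mg

    def __post_init__(self) -> None:
        if self.role not in ("blank", "calibrant", "qc", "study"):
            raise DataError(f"sample {self.sample_id}: unknown role {self.role!r}")
        if self.role == "calibrant" and self.nominal_conc is None:
            raise DataError(f"calibrant {self.sample_id} lacks nominal_conc")
        if self.role == "study" and (
            self.animal_id is None or self.time_point is None or self.dose is None
        ):
            raise DataError(
                f"study sample {self.sample_id} must carry animal_id, "
                "time_point and dose"
            )


@dataclass
class ConcentrationTimeProfile:
    """Plasma concentration-time measurements for one animal."""

    animal_id: str
    dose: float  # mg
    points: list[tuple[float, float]]  # (minutes, ng/mL), times increasing
    missing_points: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DataError(f"profile {self.animal_id}: times must be increasing")
        if any(t < 0 for t in times) or any(c < 0 for _, c in self.points):
            raise DataError(f"profile {self.animal_id}: negative time or concentration")
        if not self.dose > 0:
            raise DataError(f"profile {self.animal_id}: dose must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.points], dtype=float)


# ---------------------------------------------------------------------------
# chromatogram CSV

_CHROM_COLUMNS = ["sample_id", "transition_id", "time_min", "intensity"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column {col!r}")


def write_chromatograms(traces: Iterable[ChromatogramTrace], path) -> None:
    """Write traces to the chromatogram CSV schema (full float precision)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": tr.sample_id,
                    "transition_id": tr.transition.transition_id,
                    "time_min": tr.times,
                    "intensity": tr.intensities,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=_CHROM_COLUMNS)
    # 17 significant digits guarantee a bit-exact float64 round trip
    df.to_csv(path, index=False, float_format="%.17g")


def read_chromatograms(path) -> list[ChromatogramTrace]:
    """Read a chromatogram CSV, grouping rows into per-transition traces."""
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    _require_columns(df, _CHROM_COLUMNS, "chromatogram CSV")
    traces: list[ChromatogramTrace] = []
    if df.empty:
        return traces
    for (sample_id, tid), grp in df.groupby(["sample_id", "transition_id"], sort=False):
        grp = grp.sort_values("time_min", kind="stable")
        times = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) == 0):
            raise DataError(
                f"trace {sample_id}/{tid}: duplicated time points in chromatogram"
            )
        traces.append(
            ChromatogramTrace(
                sample_id=str(sample_id),
                transition=Transition.from_transition_id(str(tid)),
                times=times,
                intensities=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# sample sheet CSV

_SHEET_COLUMNS = [
    "sample_id",
    "role",
    "nominal_conc_ng_ml",
    "animal_id",
    "time_min",
    "dose_mg",
]


def write_sample_sheet(samples: Iterable[SampleRecord], path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "role": s.role,
                "nominal_conc_ng_ml": "n/a" if s.nominal_conc is None else s.nominal_conc,
                "animal_id": "n/a" if s.animal_id is None else s.animal_id,
                "time_min": "n/a" if s.time_point is None else s.time_point,
                "dose_mg": "n/a" if s.dose is None else s.dose,
            }
        )
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, index=False)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip().lower() in ("", "n/a", "na"):
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s.lower() in ("", "n/a", "na") else s


def read_sample_sheet(path) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _SHEET_COLUMNS, "sample sheet CSV")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                role=str(row["role"]),
                nominal_conc=_opt_float(row["nominal_conc_ng_ml"]),
                animal_id=_opt_str(row["animal_id"]),
                time_point=_opt_float(row["time_min"]),
                dose=_opt_float(row["dose_mg"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# concentration table CSV

_CONC_COLUMNS = ["animal_id", "time_min", "conc_ng_ml", "dose_mg"]


def write_concentration_table(profiles: Iterable[ConcentrationTimeProfile], path) -> None:
    rows = []
    for p in profiles:
        for t, c in p.points:
            rows.append(
                {"animal_id": p.animal_id, "time_min": t, "conc_ng_ml": c, "dose_mg": p.dose}
            )
        for t in p.missing_points:
            rows.append(
                {"animal_id": p.animal_id, "time_min": t, "conc_ng_ml": "n/a", "dose_mg": p.dose}
            )
    df = pd.DataFrame(rows, columns=_CONC_COLUMNS)
    df = df.sort_values(["animal_id", "time_min"], kind="stable")
    df.to_csv(path, index=False)


def read_concentration_table(path) -> list[ConcentrationTimeProfile]:
    """Read per-animal concentration-time profiles.

    The token ``n/a`` (or an empty cell) marks a concentration that could
    not be measured; such time points are excluded from the profile and
    recorded in ``missing_points``.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "conc_ng_ml": str})
    _require_columns(df, _CONC_COLUMNS, "concentration table CSV")
    profiles: list[ConcentrationTimeProfile] = []
    if df.empty:
        return profiles
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("time_min", kind="stable")
        points: list[tuple[float, float]] = []
        missing: list[float] = []
        doses = set()
        for _, row in grp.iterrows():
            t = float(row["time_min"])
            if t < 0:
                raise DataError(f"animal {animal_id}: negative time {t}")
            doses.add(float(row["dose_mg"]))
            conc = _opt_float(row["conc_ng_ml"])
            if conc is None:
                missing.append(t)
                continue
            if conc < 0:
                raise DataError(f"animal {animal_id}: negative concentration {conc}")
            points.append((t, conc))
        if len(doses) != 1:
            raise DataError(f"animal {animal_id}: inconsistent dose values {sorted(doses)}")
        profiles.append(
            ConcentrationTimeProfile(
                animal_id=str(animal_id),
                dose=doses.pop(),
                points=points,
                missing_points=missing,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# packaged study data


def _data_path(name: str):
    return resources.files("srmpk.data").joinpath(name)


def load_study_concentrations() -> list[ConcentrationTimeProfile]:
    """Plasma stepharine concentration-time profiles of the six rabbits
    dosed intramuscularly with stephaglabrine sulfate (0.1 mg/kg)."""
    with resources.as_file(_data_path("rabbit_plasma_concentrations.csv")) as p:
        return read_concentration_table(p)


def load_study_pk_parameters() -> pd.DataFrame:
    """Published per-animal model parameters (dose, Cmax, Tmax, K1, Kel, C0).

    Animals for which the terminal phase could not be characterised carry
    missing (NaN) Kel and C0.
    """
    with resources.as_file(_data_path("rabbit_pk_parameters.csv")) as p:
        df = pd.read_csv(p, na_values=["n/a"])
    return df


# ---------------------------------------------------------------------------
# mzML (read-only, optional path)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(element) -> list:
    return element.findall(f"{_MZML_NS}cvParam") + element.findall("cvParam")


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray, str | None]:
    """Decode one <binaryDataArray>: (array kind, values, unit name)."""
    import base64
    import zlib

    dtype = "<f8"
    compressed = False
    kind = None
    unit = None
    for cv in _cv_params(bda):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000595":
            kind = "time"
            unit = cv.get("unitName")
        elif acc == "MS:1000515":
            kind = "intensity"
    binary = bda.find(f"{_MZML_NS}binary")
    if binary is None:
        binary = bda.find("binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float), unit


def _isolation_target(chrom, tag: str) -> float | None:
    block = chrom.find(f"{_MZML_NS}{tag}")
    if block is None:
        block = chrom.find(tag)
    if block is None:
        return None
    iso = block.find(f"{_MZML_NS}isolationWindow")
    if iso is None:
        iso = block.find("isolationWindow")
    if iso is None:
        return None
    for cv in _cv_params(iso):
        if cv.get("accession") == "MS:1000827":
            return float(cv.get("value"))
    return None


def read_mzml_chromatograms(path, quantifier_product_mz: float | None = None) -> list[ChromatogramTrace]:
    """Read SRM chromatogram entries from an mzML file.

    Each chromatogram with precursor/product isolation metadata becomes one
    :class:`ChromatogramTrace`; retention times in seconds are converted to
    minutes.  The quantifier transition is the one whose product m/z matches
    ``quantifier_product_mz`` (within 0.01); if not given, the chromatogram
    with the largest total intensity is taken as the quantifier.
    Chromatograms without parseable transition metadata are skipped with a
    logged warning.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    chroms = tree.findall(f".//{_MZML_NS}chromatogram") + tree.findall(".//chromatogram")
    parsed = []
    for ch in chroms:
        times = intensities = None
        unit = None
        for bda in ch.iter(f"{_MZML_NS}binaryDataArray"):
            kind, values, u = _decode_binary_array(bda)
            if kind == "time":
                times, unit = values, u
            elif kind == "intensity":
                intensities = values
        if times is None or intensities is None:
            continue
        q1 = _isolation_target(ch, "precursor")
        q3 = _isolation_target(ch, "product")
        if q1 is None or q3 is None:
            m = re.search(r"Q1=([\d.]+)\s+Q3=([\d.]+)", str(ch.get("id", "")))
            if m:
                q1, q3 = float(m.group(1)), float(m.group(2))
        if q1 is None or q3 is None:
            logger.warning("skipping chromatogram %r: no transition metadata", ch.get("id"))
            continue
        if unit in ("second", "seconds", "s"):
            times = times / 60.0
        parsed.append(((q1, q3), times, intensities))
    if not parsed:
        raise DataError(f"{path}: mzML file contains no SRM chromatogram entries")

    if quantifier_product_mz is None:
        totals = [float(np.sum(i)) for _, _, i in parsed]
        quant_idx = int(np.argmax(totals))
    else:
        quant_idx = next(
            (k for k, (mzs, _, _) in enumerate(parsed)
             if abs(mzs[1] - quantifier_product_mz) <= 0.01),
            None,
        )
        if quant_idx is None:
            raise DataError(
                f"{path}: no chromatogram with product m/z {quantifier_product_mz}"
            )
    stem = getattr(path, "stem", None) or str(path)
    traces = []
    for k, ((q1, q3), times, inten) in enumerate(parsed):
        role = QUANTIFIER if k == quant_idx else QUALIFIER
        traces.append(
            ChromatogramTrace(
                sample_id=str(stem),
                transition=Transition(q1, q3, role),
                times=times,
                intensities=inten,
            )
        )
    return traces
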
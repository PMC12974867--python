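"""CSV and curve-file readers/writers.

All tabular interchange is comma-separated UTF-8 with a header row and
"." decimals.  Calibration curves use the IntCal-style columnar text
convention: ``cal BP, 14C age (or F14C), 1-sigma`` with ``#`` comments,
extra columns ignored.  Every reader validates domain invariants and
names the offending row in its diagnostic; ``write(read(f))`` round-trips
to an identical object (modulo float formatting).

Interpolated ages are serialized with one decimal place; all other floats
keep full precision via :func:`repr`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import yaml

from .agemodel import TiePoint, ValidationReport
from .calibration import CalibratedDate
from .composite import CompositeRecord
from .types import (
    AnnualRecord,
    CalibrationCurve,
    DatedSeries,
    IsotopeSeries,
    RadiocarbonDate,
    ValidationError,
)

__all__ = [
    "read_isotope_series", "write_isotope_series",
    "read_radiocarbon_dates", "write_radiocarbon_dates",
    "read_calibration_curve", "write_calibration_curve",
    "read_annual_record", "write_annual_record",
    "read_tie_points", "write_tie_points",
    "read_dated_series", "write_dated_series",
    "read_composite", "write_composite",
    "write_calibrated_intervals", "read_calibrated_intervals",
    "write_validation_report",
    "read_config",
]


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
            f"{col!r} at data row {row + 1}"
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0])
        raise ValidationError(
            f"{path}: missing value in column {col!r} at data row {row + 1}"
        )
    return vals.to_numpy()


# -- isotope series ---------------------------------------------------------

def read_isotope_series(path, tree_id: str = None,
                        plausible_range=(-40.0, 0.0)) -> IsotopeSeries:
    """Read a per-core δ13C series from CSV (sample_number, delta13C).

    ``tree_id`` defaults to the file stem.  A YAML sidecar ``<path>.meta.yaml``
    is loaded into ``metadata`` when present.
    """
    path = Path(path)
    df = _read_csv(path, ["sample_number", "delta13C"])
    sn = _numeric(df, "sample_number", path)
    vals = _numeric(df, "delta13C", path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return IsotopeSeries(
        tree_id=tree_id or path.stem,
        sample_numbers=sn.astype(int) if np.all(sn == sn.astype(int))
        else sn,  # IsotopeSeries rejects non-integers with a diagnostic
        delta13c=vals,
        metadata=meta,
        plausible_range=plausible_range,
    )


def write_isotope_series(series: IsotopeSeries, path) -> None:
    df = pd.DataFrame({"sample_number": series.sample_numbers,
                       "delta13C": series.delta13c})
    df.to_csv(path, index=False, float_format="%.17g")
    if series.metadata:
        sidecar = Path(path).with_suffix(Path(path).suffix + ".meta.yaml")
        sidecar.write_text(yaml.safe_dump(series.metadata))


# -- radiocarbon dates ------------------------------------------------------

_DATE_COLS = ["tree_id", "sample_number", "measurement_type", "value",
              "sigma", "flagged_outlier"]


def read_radiocarbon_dates(path) -> List[RadiocarbonDate]:
    """Read AMS dates from CSV; ``flagged_outlier`` column optional."""
    path = Path(path)
    df = _read_csv(path, _DATE_COLS[:-1])
    if "flagged_outlier" not in df.columns:
        df["flagged_outlier"] = False
    dates = []
    for i, row in df.iterrows():
        try:
            dates.append(RadiocarbonDate(
                tree_id=str(row["tree_id"]),
                sample_number=int(row["sample_number"]),
                measurement_type=str(row["measurement_type"]),
                value=float(row["value"]),
                sigma=float(row["sigma"]),
                flagged_outlier=bool(row["flagged_outlier"]),
            ))
        except (ValueError, ValidationError) as e:
            raise ValidationError(f"{path}: data row {i + 1}: {e}") from None
    return dates


def write_radiocarbon_dates(dates: Sequence[RadiocarbonDate], path) -> None:
    pd.DataFrame([{
        "tree_id": d.tree_id, "sample_number": d.sample_number,
        "measurement_type": d.measurement_type, "value": d.value,
        "sigma": d.sigma, "flagged_outlier": d.flagged_outlier,
    } for d in dates]).to_csv(path, index=False, float_format="%.17g")


# -- calibration curves -----------------------------------------------------

def read_calibration_curve(path, era: str = "pre_bomb",
                           name: str = None) -> CalibrationCurve:
    """Read an IntCal-style columnar curve file.

    Whitespace- or comma-separated; first three columns are cal BP,
    14C age (or F14C), 1-sigma; further columns and ``#`` comments are
    ignored.
    """
    path = Path(path)
    rows = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise ValidationError(
                f"{path}: line {ln}: need >= 3 columns, got {len(parts)}"
            )
        try:
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
        except ValueError:
            raise ValidationError(
                f"{path}: line {ln}: non-numeric entry in {parts[:3]}"
            ) from None
    if len(rows) < 2:
        raise ValidationError(f"{path}: fewer than 2 curve points")
    arr = np.asarray(rows)
    return CalibrationCurve(cal_bp=arr[:, 0], c14_value=arr[:, 1],
                            curve_sigma=arr[:, 2], era=era,
                            name=name or path.stem)


def write_calibration_curve(curve: CalibrationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {curve.name} (cal BP, value, sigma); era={curve.era}\n")
        for bp, v, s in zip(curve.cal_bp, curve.c14_value, curve.curve_sigma):
            fh.write(f"{float(bp)!r},{float(v)!r},{float(s)!r}\n")


# -- annual records ---------------------------------------------------------

def read_annual_record(path, kind: str = "forcing_index",
                       max_gap: int = None) -> AnnualRecord:
    """Read an annual (year, value) CSV."""
    path = Path(path)
    df = _read_csv(path, ["year", "value"])
    years = _numeric(df, "year", path)
    if not np.all(years == years.astype(int)):
        row = int(np.flatnonzero(years != years.astype(int))[0])
        raise ValidationError(
            f"{path}: non-integer year {years[row]} at data row {row + 1}"
        )
    return AnnualRecord(years=years.astype(int),
                        values=_numeric(df, "value", path),
                        kind=kind, max_gap=max_gap)


def write_annual_record(record: AnnualRecord, path) -> None:
    pd.DataFrame({"year": record.years,
                  "value": record.values}).to_csv(path, index=False,
                                                  float_format="%.17g")


# -- tie points -------------------------------------------------------------

def read_tie_points(path) -> Dict[str, List[TiePoint]]:
    """Read tie points CSV (tree_id, sample_number, year_CE) grouped by tree."""
    path = Path(path)
    df = _read_csv(path, ["tree_id", "sample_number", "year_CE"])
    sn = _numeric(df, "sample_number", path).astype(int)
    yr = _numeric(df, "year_CE", path)
    out: Dict[str, List[TiePoint]] = {}
    for tid, s, y in zip(df["tree_id"].astype(str), sn, yr):
        out.setdefault(tid, []).append(TiePoint(tid, int(s), float(y)))
    return out


def write_tie_points(tie_points: Dict[str, List[TiePoint]], path) -> None:
    rows = [{"tree_id": p.tree_id, "sample_number": p.sample_number,
             "year_CE": p.year_ce}
            for pts in tie_points.values() for p in pts]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# -- dated series -----------------------------------------------------------

def read_dated_series(path, tree_id: str = None) -> DatedSeries:
    path = Path(path)
    df = _read_csv(path, ["year_CE", "delta13C"])
    return DatedSeries(tree_id=tree_id or path.stem,
                       years=_numeric(df, "year_CE", path),
                       values=_numeric(df, "delta13C", path))


def write_dated_series(series: DatedSeries, path) -> None:
    # interpolated ages carry one decimal place by convention
    pd.DataFrame({"year_CE": [f"{y:.1f}" for y in series.years],
                  "delta13C": series.values}).to_csv(path, index=False)


# -- composite --------------------------------------------------------------

def read_composite(path) -> CompositeRecord:
    path = Path(path)
    df = _read_csv(path, ["year", "value", "se", "n_trees"])
    se = pd.to_numeric(df["se"], errors="coerce").to_numpy()
    return CompositeRecord(years=_numeric(df, "year", path).astype(int),
                           values=_numeric(df, "value", path),
                           se=se,
                           n_trees=_numeric(df, "n_trees", path).astype(int))


def write_composite(record: CompositeRecord, path) -> None:
    pd.DataFrame({"year": record.years, "value": record.values,
                  "se": record.se,
                  "n_trees": record.n_trees}).to_csv(path, index=False,
                                                     float_format="%.17g")


# -- calibration products ---------------------------------------------------

def write_calibrated_intervals(cals: Sequence[CalibratedDate], path) -> None:
    """HPD intervals CSV: one row per (date, interval)."""
    rows = []
    for c in cals:
        for a, b in c.hpd_intervals:
            sel = (c.year_ce >= a) & (c.year_ce <= b)
            rows.append({"tree_id": c.tree_id,
                         "sample_number": c.sample_number,
                         "start_CE": a, "end_CE": b,
                         "mass": float(c.density[sel].sum()),
                         "coverage": c.coverage,
                         "flagged_outlier": c.flagged_outlier})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calibrated_intervals(path) -> List[CalibratedDate]:
    """Rebuild interval-only CalibratedDate stubs (no density) from CSV."""
    path = Path(path)
    df = _read_csv(path, ["tree_id", "sample_number", "start_CE", "end_CE"])
    out: Dict[tuple, CalibratedDate] = {}
    for _, row in df.iterrows():
        key = (str(row["tree_id"]), int(row["sample_number"]))
        cd = out.get(key)
        if cd is None:
            cd = CalibratedDate(
                tree_id=key[0], sample_number=key[1],
                year_ce=np.array([]), density=np.array([]),
                coverage=float(row.get("coverage", 0.683)),
                flagged_outlier=bool(row.get("flagged_outlier", False)),
            )
            out[key] = cd
        cd.hpd_intervals.append((float(row["start_CE"]), float(row["end_CE"])))
    for cd in out.values():
        cd.hpd_intervals.sort()
    return list(out.values())


def write_validation_report(report: ValidationReport, path) -> None:
    pd.DataFrame(report.records).to_csv(path, index=False)


def read_config(path) -> dict:
    """Load a nested key/value YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
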
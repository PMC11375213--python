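"""Readers, writers and the decimal-year convention.

All modules work in decimal calendar years; this module owns the single
conversion routine (365.2425-day years) and the titleholder CSV schema:

    date_death, age_death_years, successor_age_years

``date_death`` is either a decimal year (dialect ``decimal_year``) or an
ISO date (dialect ``iso_dates``).  A converter from the day-resolved
dialect used by public supercentenarian tables (death date plus days
lived) is included.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import TitleholderRecord, validate_records

DAYS_PER_YEAR = 365.2425

REQUIRED_COLUMNS = ("date_death", "age_death_years", "successor_age_years")


def decimal_year(date) -> float:
    """Calendar date -> decimal year (365.2425-day convention)."""
    ts = pd.Timestamp(date)
    start = pd.Timestamp(year=ts.year, month=1, day=1)
    return float(ts.year + (ts - start) / pd.Timedelta(days=1) / DAYS_PER_YEAR)


def years_from_days(days) -> float:
    """Day counts (e.g. age in days) -> decimal years."""
    return np.asarray(days, dtype=float) / DAYS_PER_YEAR


def read_titleholders(path, dialect: str = "decimal_year", consistency_tol: float = 0.01):
    """Parse a titleholder CSV into validated records.

    Parameters
    ----------
    path : file path
    dialect : {"decimal_year", "iso_dates"}
        How ``date_death`` is encoded.

    Returns
    -------
    list of TitleholderRecord, sorted by transition time.
    """
    if dialect not in ("decimal_year", "iso_dates"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty titleholder file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no titleholder rows")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            if dialect == "iso_dates":
                t = decimal_year(row.date_death)
            else:
                t = float(row.date_death)
            records.append(
                TitleholderRecord(
                    t=t,
                    y=float(row.age_death_years),
                    z=float(row.successor_age_years),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {line}: {exc}") from exc
    records.sort(key=lambda r: r.t)
    return validate_records(records, tol=consistency_tol)


def convert_days_dialect(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a (death date, days lived) table to the standard schema.

    Expects columns ``date_death`` (ISO date), ``days_lived`` and
    ``successor_days_lived``.
    """
    need = {"date_death", "days_lived", "successor_days_lived"}
    if not need <= set(df.columns):
        raise ValueError(f"days dialect needs columns {sorted(need)}")
    return pd.DataFrame(
        {
            "date_death": [decimal_year(d) for d in df["date_death"]],
            "age_death_years": years_from_days(df["days_lived"]),
            "successor_age_years": years_from_days(df["successor_days_lived"]),
        }
    )


def write_titleholders(records, path) -> None:
    df = pd.DataFrame(
        {
            "date_death": [r.t for r in records],
            "age_death_years": [r.y for r in records],
            "successor_age_years": [r.z for r in records],
        }
    )
    Path(path).write_text(df.to_csv(index=False, float_format="%.8f"))


def read_counts_csv(path) -> pd.DataFrame:
    """Two-column (year, count) CSV for the exponential-intensity fit."""
    df = pd.read_csv(path)
    cols = {c.lower() for c in df.columns}
    if not {"year", "count"} <= cols:
        raise ValueError(f"{path}: counts CSV must have header columns year,count")
    df.columns = [c.lower() for c in df.columns]
    return df[["year", "count"]]
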
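"""Reading, validation and writing of the three survey tables.

A multi-stage bottom-trawl survey is represented by three delimited-text
tables, held in memory as :class:`pandas.DataFrame` objects:

haul table
    one row per haul (= one visit to a sampling site in one year):
    ``haul_id, date, year, longitude, latitude, depth, bottom_temperature,
    catch_count, catch_weight``.
length table
    stage-2 length-frequency records: ``haul_id, length_bin, sex, count``
    with ``length_bin`` the lower edge of a 1-cm bin and ``sex`` one of
    ``male / female / undetermined``.
otolith table
    stage-3 aged fish: ``haul_id, length, sex, age`` (sex must be known).

Validation is strict: schema problems raise :class:`SchemaError`, rows that
violate invariants raise :class:`RowError` carrying the offending row indices
so a user can locate them in the source file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

HAUL_COLUMNS = [
    "haul_id",
    "date",
    "year",
    "longitude",
    "latitude",
    "depth",
    "bottom_temperature",
    "catch_count",
    "catch_weight",
]
LENGTH_COLUMNS = ["haul_id", "length_bin", "sex", "count"]
OTOLITH_COLUMNS = ["haul_id", "length", "sex", "age"]

SEXES = ("male", "female")
SEXES_WITH_UNDETERMINED = SEXES + ("undetermined",)

#: plausible range (cm) for 1-cm length bins; configurable per call
DEFAULT_LENGTH_RANGE = (5, 120)


class SurveyTableError(ValueError):
    """Base class for survey-table validation failures."""


class SchemaError(SurveyTableError):
    """A required column is missing or has an unusable dtype."""


class RowError(SurveyTableError):
    """One or more rows violate a table invariant."""

    def __init__(self, message: str, rows: Iterable[int]):
        self.rows = sorted(int(r) for r in rows)
        super().__init__(f"{message} (rows {self.rows})")


def _require_columns(df: pd.DataFrame, columns: list[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required columns: {missing}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], table: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise RowError(f"{table} table column '{col}' has unparsable values", df.index[bad])
        if coerced.isna().any():
            raise RowError(f"{table} table column '{col}' has missing values", df.index[coerced.isna()])
        df[col] = coerced
    return df


def validate_hauls(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a haul table, returning a clean copy with numeric dtypes."""
    _require_columns(df, HAUL_COLUMNS, "haul")
    df = _coerce_numeric(
        df,
        ["year", "longitude", "latitude", "depth", "bottom_temperature", "catch_count", "catch_weight"],
        "haul",
    )
    dup = df["haul_id"].duplicated(keep=False)
    if dup.any():
        raise RowError("haul table has duplicate haul_id", df.index[dup])
    bad_depth = df["depth"] <= 0
    if bad_depth.any():
        raise RowError("haul table has non-positive depth", df.index[bad_depth])
    bad_catch = (df["catch_count"] < 0) | (df["catch_weight"] < 0)
    if bad_catch.any():
        raise RowError("haul table has negative catch", df.index[bad_catch])
    df["year"] = df["year"].astype(int)
    df["catch_count"] = df["catch_count"].astype(int)
    return df[HAUL_COLUMNS]


def validate_lengths(
    df: pd.DataFrame,
    hauls: pd.DataFrame | None = None,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> pd.DataFrame:
    """Validate a stage-2 length-frequency table.

    When ``hauls`` is given, every ``haul_id`` must resolve against it.
    """
    _require_columns(df, LENGTH_COLUMNS, "length")
    df = _coerce_numeric(df, ["length_bin", "count"], "length")
    bad_sex = ~df["sex"].isin(SEXES_WITH_UNDETERMINED)
    if bad_sex.any():
        raise RowError("length table has invalid sex codes", df.index[bad_sex])
    bad_count = df["count"] < 1
    if bad_count.any():
        raise RowError("length table has counts < 1", df.index[bad_count])
    lo, hi = length_range
    bad_bin = (df["length_bin"] < lo) | (df["length_bin"] > hi)
    if bad_bin.any():
        raise RowError(f"length table has bins outside [{lo}, {hi}] cm", df.index[bad_bin])
    if hauls is not None:
        orphan = ~df["haul_id"].isin(hauls["haul_id"])
        if orphan.any():
            raise RowError("length table references unknown haul_id", df.index[orphan])
    df["length_bin"] = df["length_bin"].astype(int)
    df["count"] = df["count"].astype(int)
    return df[LENGTH_COLUMNS]


def validate_otoliths(df: pd.DataFrame, hauls: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a stage-3 otolith (aged-fish) table."""
    _require_columns(df, OTOLITH_COLUMNS, "otolith")
    df = _coerce_numeric(df, ["length", "age"], "otolith")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise RowError("otolith table requires known sex (male/female)", df.index[bad_sex])
    bad_age = df["age"] < 0
    if bad_age.any():
        raise RowError("otolith table has negative ages", df.index[bad_age])
    if hauls is not None:
        orphan = ~df["haul_id"].isin(hauls["haul_id"])
        if orphan.any():
            raise RowError("otolith table references unknown haul_id", df.index[orphan])
    df["age"] = df["age"].astype(int)
    return df[OTOLITH_COLUMNS]


def read_haul_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a haul table from a delimited text file."""
    return validate_hauls(pd.read_csv(path, sep=delimiter))


def read_length_table(
    path: str | Path,
    hauls: pd.DataFrame | None = None,
    delimiter: str = ",",
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> pd.DataFrame:
    """Read and validate a length-frequency table."""
    return validate_lengths(pd.read_csv(path, sep=delimiter), hauls, length_range)


def read_otolith_table(
    path: str | Path,
    hauls: pd.DataFrame | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read and validate an otolith table."""
    return validate_otoliths(pd.read_csv(path, sep=delimiter), hauls)


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write any survey table back to delimited text (lossless round-trip)."""
    df.to_csv(path, sep=delimiter, index=False)


def expand_length_records(lengths: pd.DataFrame) -> pd.DataFrame:
    """Expand a length-frequency table to one row per measured fish.

    Counts collapse to repeated rows; the result keeps ``haul_id``,
    ``length_bin`` and ``sex``.
    """
    reps = np.repeat(lengths.index.to_numpy(), lengths["count"].to_numpy())
    out = lengths.loc[reps, ["haul_id", "length_bin", "sex"]].reset_index(drop=True)
    return out
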
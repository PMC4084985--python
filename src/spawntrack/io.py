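"""Typed readers/writers for the tabular inputs and packaged reference tables.

All tables travel as pandas DataFrames with validated schemas. Timestamps are
local civil time in fixed-offset Eastern Standard Time (UTC-5, no daylight
saving), stored as naive datetimes; hour binning is therefore reproducible
across platforms. Coordinates are planar meters (UTM-like); no geodesy.
"""

from __future__ import annotations

import importlib.resources
from typing import Mapping

import numpy as np
import pandas as pd

SPAWNING_SITE_ZONES = frozenset({2, 3})
SPAWNING_SEASON_MONTHS = frozenset({4, 5, 6, 7, 8, 9})  # April-September

#: default column mappings for VR2-export-style CSVs
DETECTION_COLUMNS = {"timestamp": "timestamp", "receiver_id": "receiver_id", "tag_id": "tag_id"}


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns: {missing}")


def parse_timestamps(values: pd.Series) -> pd.Series:
    """Parse timestamps to naive EST datetimes, reporting bad rows by line.

    Accepts ISO-8601 and M/D/YYYY HH:MM[:SS] forms.
    """
    parsed = pd.to_datetime(values, errors="coerce", format="mixed")
    bad = parsed.isna() & values.notna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"malformed timestamp(s) at line(s) {lines[:10]}: "
                          f"{values[bad].head(3).tolist()}")
    return parsed


def read_deployments(path) -> pd.DataFrame:
    """Read the receiver deployment table (receiver_id, easting, northing, zone, core_array)."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["receiver_id", "easting", "northing", "zone"], "deployment")
    if df["receiver_id"].duplicated().any():
        raise SchemaError("duplicate receiver_id in deployment table")
    if "core_array" not in df.columns:
        # receivers 3-19 monitor the spawning site (zones 2-3) by convention
        df["core_array"] = df["receiver_id"].between(3, 19)
    df["core_array"] = df["core_array"].astype(bool)
    return df


def read_detections(path, deployments: pd.DataFrame,
                    columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a detection CSV, fix timezones, sort by (tag_id, timestamp).

    Unknown receiver ids are a hard error (they indicate a deployment-table
    mismatch, not noise).
    """
    colmap = dict(DETECTION_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, comment="#", dtype={colmap["tag_id"]: str})
    _require_columns(raw, colmap.values(), "detection")
    df = pd.DataFrame({
        "tag_id": raw[colmap["tag_id"]].astype(str),
        "receiver_id": raw[colmap["receiver_id"]].astype(int),
        "timestamp": parse_timestamps(raw[colmap["timestamp"]]),
    })
    known = set(deployments["receiver_id"].astype(int))
    unknown = sorted(set(df["receiver_id"]) - known)
    if unknown:
        raise SchemaError(f"unknown receiver_id(s) {unknown} not in deployment table")
    return df.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def read_tags(path) -> pd.DataFrame:
    """Read tag metadata (sex, length, model, implant time, duty cycle, censor date)."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["tag_id", "sex", "total_length_mm", "tag_model", "implant_time"],
                     "tag metadata")
    df = df.copy()
    df["tag_id"] = df["tag_id"].astype(str)
    df["implant_time"] = parse_timestamps(df["implant_time"])
    if df["sex"].isna().any() or df["tag_model"].isna().any():
        raise SchemaError("sex and tag_model must be non-missing for every tag")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise SchemaError(f"sex must be M or F, got {bad_sex}")
    if "censor_date" in df.columns:
        df["censor_date"] = pd.to_datetime(df["censor_date"], errors="coerce")
        early = df["censor_date"].notna() & (df["censor_date"] < df["implant_time"])
        if early.any():
            raise SchemaError(f"censor_date precedes implant_time for tags "
                              f"{df.loc[early, 'tag_id'].tolist()}")
    else:
        df["censor_date"] = pd.NaT
    return df


def read_hauls(path) -> pd.DataFrame:
    """Read the haul-seine survey table and derive year/month/season columns."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["haul_id", "date", "x", "y", "adult_count"], "haul")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    if (df["adult_count"] < 0).any():
        raise SchemaError("adult_count must be non-negative")
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    df["season"] = np.where(df["month"].isin(sorted(SPAWNING_SEASON_MONTHS)),
                            "spawning", "non-spawning")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline table as RFC-4180 CSV (round-trips with the readers)."""
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged reference tables (per-fish-year residence summary; year x zone
# hourly-relocation counts) used by the exact arithmetic tests.
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("spawntrack.data").joinpath(name)


def load_table1_fixture() -> pd.DataFrame:
    """Per-fish-year residence summary: DD, first/last dates, TP, RI for the
    whole array (``_a``) and the spawning site (``_ss``); ``censored`` flags
    the two 2009 mortalities whose printed summaries are incomplete.
    """
    with _data_path("table1_residence.csv").open() as fh:
        df = pd.read_csv(
            fh,
            dtype={"dd_a": "Int64", "tp_a": "Int64", "dd_ss": "Int64", "tp_ss": "Int64"},
            parse_dates=["first_a", "last_a", "first_ss", "last_ss"],
        )
    df["multiyear"] = df["multiyear"].astype(bool)
    df["censored"] = df["censored"].astype(bool)
    return df


def load_table2_fixture() -> pd.DataFrame:
    """Year x zone counts of hourly-bin relocations (wide, one zone per column)."""
    with _data_path("table2_relocations.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("year")


def table1_to_residence(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reshape the packaged residence table to the long per-scope layout
    produced by :func:`spawntrack.residence.residence_summary`.

    Censored rows and scopes without data are dropped (their printed
    summaries are incomplete).
    """
    df = load_table1_fixture() if fixture is None else fixture
    frames = []
    for scope, suf in (("array", "a"), ("spawning_site", "ss")):
        sub = df[df[f"dd_{suf}"].notna() & ~df["censored"]]
        frames.append(pd.DataFrame({
            "tag_id": sub["tag_id"].astype(str), "year": sub["year"],
            "scope": scope, "first_date": sub[f"first_{suf}"],
            "last_date": sub[f"last_{suf}"],
            "DD": sub[f"dd_{suf}"].astype(int), "TP": sub[f"tp_{suf}"].astype(int),
            "RI": sub[f"ri_{suf}"].astype(float),
        }))
    out = pd.concat(frames, ignore_index=True)
    out["eligible"] = out["DD"] >= 5
    return out
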
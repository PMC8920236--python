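"""Per-survey ingest and standardization.

Each monitoring program publishes its catch in its own dialect: wide or
long layout, agency species codes, its own column names and units.  This
module reformats every survey to one long-format standard (one row per
sample x taxon/life-stage), applies the zero-vs-missing correction driven
by the per-survey taxa lists, and splits the combined table into a
sample-level environment table and a catch table keyed by SampleID.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .errors import InputError, KeyCollisionError, MappingError, RowError
from .taxonomy import TaxaList

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyConfig",
    "load_survey_config",
    "read_survey",
    "zeros_to_na",
    "make_sample_id",
    "bind_and_split",
    "sampling_effort",
    "qc_flowmeter",
    "ENVIRONMENT_COLUMNS",
    "CATCH_COLUMNS",
    "write_table",
    "read_table",
]

#: Sample-level variables of the standard schema, in output order.
ENVIRONMENT_COLUMNS = [
    "SampleID", "Source", "Station", "Latitude", "Longitude",
    "Year", "Date", "Datetime", "SizeClass", "Volume", "Tide",
    "BottomDepth", "Secchi", "Temperature", "Turbidity", "Microcystis",
    "pH", "DO", "Chl", "SalSurf", "SalBott",
]

#: Catch-level variables of the standard schema.
CATCH_COLUMNS = ["SampleID", "Taxname", "Lifestage", "Taxlifestage", "CPUE", "Undersampled"]

# columns that are sample-level when present in the standardized long table
_SAMPLE_LEVEL = [c for c in ENVIRONMENT_COLUMNS if c != "SampleID"]


class TaxonCode(BaseModel):
    """Scientific name + life stage behind one agency species code."""

    taxname: str
    lifestage: str


class SurveyConfig(BaseModel):
    """Descriptor of one survey's published dialect.

    ``columns`` renames source columns to the standard schema.  For wide
    tables, every column not mapped and not in ``ignore_columns`` is
    treated as a taxon column whose header is a species code resolved via
    ``species_codes``.  ``unit_factors`` multiplies standard columns into
    standard units (e.g. CPUE reported per liter -> ``{"CPUE": 1000}``).
    """

    name: str
    size_class: str
    fmt: Literal["long", "wide"] = "long"
    columns: dict[str, str] = Field(default_factory=dict)
    species_codes: dict[str, TaxonCode] = Field(default_factory=dict)
    taxname_column: Optional[str] = None
    lifestage_column: Optional[str] = None
    code_column: Optional[str] = None
    cpue_column: Optional[str] = None
    ignore_columns: list[str] = Field(default_factory=list)
    unit_factors: dict[str, float] = Field(default_factory=dict)
    datetime_format: Optional[str] = None


def load_survey_config(path) -> SurveyConfig:
    """Read a survey descriptor from a JSON or YAML file."""
    text = open(path).read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return SurveyConfig.model_validate(data)


def read_survey(path, config: SurveyConfig) -> pd.DataFrame:
    """Ingest one survey table into the standard long format.

    Renames columns, resolves species codes to scientific names, converts
    units, and pivots wide tables so each row carries one CPUE for one
    (sample, taxon/life-stage).
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    df = df.rename(columns=config.columns)

    if config.fmt == "wide":
        mapped = set(config.columns.values())
        id_cols = [c for c in df.columns if c in mapped or c in config.ignore_columns]
        taxon_cols = [c for c in df.columns if c not in id_cols]
        offenders = [c for c in taxon_cols if c not in config.species_codes]
        if offenders:
            raise MappingError(offenders)
        df = df.melt(id_vars=id_cols, value_vars=taxon_cols,
                     var_name="_code", value_name="CPUE")
        code_col = "_code"
    else:
        code_col = config.code_column
        if code_col is not None:
            offenders = df.loc[~df[code_col].isin(config.species_codes), code_col]
            if len(offenders):
                raise MappingError(offenders.astype(str).tolist())
        if config.cpue_column and config.cpue_column in df.columns:
            df = df.rename(columns={config.cpue_column: "CPUE"})

    if code_col is not None:
        codes = df[code_col].astype(str)
        df["Taxname"] = codes.map({k: v.taxname for k, v in config.species_codes.items()})
        df["Lifestage"] = codes.map({k: v.lifestage for k, v in config.species_codes.items()})
        df = df.drop(columns=[code_col])
    else:
        if config.taxname_column:
            df = df.rename(columns={config.taxname_column: "Taxname"})
        if config.lifestage_column:
            df = df.rename(columns={config.lifestage_column: "Lifestage"})

    for col in ("Taxname", "Lifestage", "CPUE"):
        if col not in df.columns:
            raise InputError(f"{config.name}: standardized table lacks {col}")

    df["CPUE"] = pd.to_numeric(df["CPUE"], errors="coerce")
    bad = df.index[df["CPUE"] < 0]
    if len(bad):
        # +2: header line and 1-based numbering of the source file
        raise RowError(f"{path}: negative CPUE at line {int(bad[0]) + 2}")

    for col, factor in config.unit_factors.items():
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce") * factor

    df["Source"] = config.name
    df["SizeClass"] = config.size_class
    df["Datetime"] = pd.to_datetime(df["Datetime"], format=config.datetime_format)
    df["Date"] = df["Datetime"].dt.normalize()
    df["Year"] = df["Datetime"].dt.year
    df["Taxlifestage"] = df["Taxname"].str.cat(df["Lifestage"], sep=" ")
    logger.info("read_survey %s: %d records", config.name, len(df))
    return df


def zeros_to_na(records: pd.DataFrame, lists: TaxaList) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace false zeros with missing values.

    A CPUE of 0 recorded in a year the survey did not count that
    taxon/life stage means "unknown", not "absent", and becomes NA — except
    for non-native taxa before their introduction year, which were truly
    absent and keep 0.  Nonzero values are never altered.

    Returns the corrected table and a report of records whose category was
    not found in the taxa lists (kept, flagged in the report).
    """
    out = records.copy()
    missing_rows = []
    cache: dict[tuple, tuple] = {}
    for idx in out.index[out["CPUE"] == 0]:
        row = out.loc[idx]
        key = (row["Source"], row["SizeClass"], row["Taxname"], row["Lifestage"])
        if key not in cache:
            entries = lists.entries_for(*key)
            intro = next((e.intro_year for e in entries if e.intro_year is not None), None)
            cache[key] = (entries, intro)
        entries, intro = cache[key]
        year = int(row["Year"])
        if not entries:
            missing_rows.append(dict(row[["Source", "SizeClass", "Taxname", "Lifestage", "Year"]]))
            continue
        counted = any(e.counted_in(year) for e in entries)
        if counted:
            continue
        if intro is not None and year < intro:
            continue  # non-native before introduction: a true zero
        out.loc[idx, "CPUE"] = np.nan
    report = pd.DataFrame(missing_rows, columns=["Source", "SizeClass", "Taxname", "Lifestage", "Year"])
    if len(report):
        logger.warning("zeros_to_na: %d records not resolvable in taxa lists", len(report))
    return out, report


def make_sample_id(source, station, datetime, size_class) -> str:
    """Human-auditable unique key: source, station, ISO datetime, size class."""
    ts = pd.Timestamp(datetime)
    return f"{source} {station} {ts.isoformat()} {size_class}"


def bind_and_split(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the bound long table into environment and catch tables.

    Environment rows are unique per SampleID and carry every sample-level
    variable of the standard schema (unmeasured ones as NA); the catch
    table carries one row per (SampleID, taxon/life-stage).  The join of
    the two on SampleID reconstructs the input.
    """
    df = records.copy()
    if df.empty:
        env = pd.DataFrame(columns=ENVIRONMENT_COLUMNS)
        catch = pd.DataFrame(columns=CATCH_COLUMNS)
        return env, catch
    df["SampleID"] = [
        make_sample_id(s, st, dt, sc)
        for s, st, dt, sc in zip(df["Source"], df["Station"], df["Datetime"], df["SizeClass"])
    ]
    env_cols = [c for c in ENVIRONMENT_COLUMNS if c in df.columns]
    env = df[env_cols].drop_duplicates()
    if env["SampleID"].duplicated().any():
        dupes = env.loc[env["SampleID"].duplicated(), "SampleID"].unique()
        raise KeyCollisionError(f"conflicting sample-level data for SampleID(s): {dupes[:3]}")
    env = env.reindex(columns=ENVIRONMENT_COLUMNS)

    if "Undersampled" not in df.columns:
        df["Undersampled"] = False
    catch = df[CATCH_COLUMNS].reset_index(drop=True)
    if catch.duplicated(subset=["SampleID", "Taxlifestage"]).any():
        raise KeyCollisionError("duplicate (SampleID, Taxlifestage) in catch records")
    return env.reset_index(drop=True), catch


def sampling_effort(env: pd.DataFrame, timestep: Literal["year", "month"] = "year") -> pd.DataFrame:
    """Mean samples per station per month, averaged to a timestep.

    For each survey, counts samples per station-month-year, averages over
    the stations sampled that month (stations with no samples do not
    dilute the mean), then averages those monthly values per year
    (``timestep="year"``) or per calendar month across years
    (``timestep="month"``).
    """
    if timestep not in ("year", "month"):
        raise InputError(f"unknown timestep: {timestep!r}")
    df = env.copy()
    dates = pd.to_datetime(df["Date"])
    df["Year"] = dates.dt.year
    df["Month"] = dates.dt.month
    per_station = (
        df.groupby(["Source", "Station", "Year", "Month"]).size().rename("n").reset_index()
    )
    monthly = per_station.groupby(["Source", "Year", "Month"])["n"].mean().rename("Effort").reset_index()
    key = "Year" if timestep == "year" else "Month"
    return monthly.groupby(["Source", key])["Effort"].mean().reset_index()


def qc_flowmeter(
    env: pd.DataFrame,
    grouping: Literal["station", "date"] = "station",
    *,
    mad_factor: float = 3.0,
    volume_bounds: Optional[tuple[float, float]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag unreliable volumes and impute them from similar samples.

    A volume is deemed unreliable when its log deviates from the group
    median log-volume by more than ``mad_factor`` scaled MADs (groups are
    same station or same date, within survey and size class), or when it
    falls outside ``volume_bounds``.  Flagged volumes are replaced by the
    mean of the unflagged volumes in the group; groups with no valid donor
    leave the volume missing and log it as un-imputable.
    """
    if grouping not in ("station", "date"):
        raise InputError(f"unknown grouping: {grouping!r}")
    group_col = "Station" if grouping == "station" else "Date"
    out = env.copy()
    log_rows = []
    for key, idx in out.groupby(["Source", "SizeClass", group_col]).groups.items():
        vols = out.loc[idx, "Volume"].astype(float)
        valid = vols.dropna()
        flagged = pd.Series(False, index=vols.index)
        if volume_bounds is not None:
            lo, hi = volume_bounds
            flagged |= (vols < lo) | (vols > hi)
        if len(valid) >= 3:
            logs = np.log(valid[valid > 0])
            med = logs.median()
            mad = 1.4826 * (logs - med).abs().median()
            if mad > 0:
                outliers = (logs - med).abs() > mad_factor * mad
                flagged.loc[outliers.index[outliers]] = True
        flagged &= vols.notna()
        if not flagged.any():
            continue
        donors = vols[~flagged].dropna()
        donor_mean = float(donors.mean()) if len(donors) else np.nan
        for i in flagged.index[flagged]:
            old = float(vols.loc[i])
            if len(donors):
                out.loc[i, "Volume"] = donor_mean
                status = "imputed"
            else:
                out.loc[i, "Volume"] = np.nan
                status = "unimputable"
            log_rows.append(
                {
                    "SampleID": out.loc[i, "SampleID"] if "SampleID" in out.columns else i,
                    "Group": f"{key[0]}/{key[1]}/{key[2]}",
                    "OldVolume": old,
                    "NewVolume": out.loc[i, "Volume"],
                    "Status": status,
                    "Donors": len(donors),
                }
            )
    log = pd.DataFrame(log_rows, columns=["SampleID", "Group", "OldVolume", "NewVolume", "Status", "Donors"])
    logger.info("qc_flowmeter: %d volumes flagged", len(log))
    return out, log


def write_table(df: pd.DataFrame, path) -> None:
    """Write a standard table as RFC-4180 CSV with NA for missing values."""
    out = df.copy()
    for col in ("Date", "Datetime"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime(
                "%Y-%m-%d" if col == "Date" else "%Y-%m-%d %H:%M:%S"
            )
    out.to_csv(path, index=False, na_rep="NA")


def read_table(path, parse_dates: Iterable[str] = ("Date", "Datetime")) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    for col in parse_dates:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    if "Undersampled" in df.columns:
        df["Undersampled"] = df["Undersampled"].astype("boolean").fillna(False).astype(bool)
    return df
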
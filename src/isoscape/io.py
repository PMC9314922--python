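"""Readers and writers for the pipeline's file formats.

Tables travel as UTF-8 CSV with a header row, gridded fields as NetCDF
(written through xarray's scipy backend, i.e. classic NetCDF-3), habitat
regions as GeoJSON, and reports as JSON.  Readers validate the declared
schemas and name offending columns/variables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .sections import SectionSeries

__all__ = [
    "SchemaError",
    "DependencyError",
    "MEASUREMENT_COLUMNS",
    "TELEMETRY_COLUMNS",
    "read_measurements",
    "read_telemetry",
    "write_records",
    "read_records",
    "write_section",
    "read_section",
    "write_report",
    "write_geojson",
]


class SchemaError(ValueError):
    """Input file does not conform to its declared schema (CLI exit code 2)."""


class DependencyError(RuntimeError):
    """A required upstream artifact is missing (CLI exit code 3)."""


MEASUREMENT_COLUMNS = [
    "seal_id", "amino_acid", "replicate_index", "d15n_measured",
    "standard_measured", "standard_known", "catch_year", "age_years",
]

TELEMETRY_COLUMNS = ["animal_id", "timestamp", "lon", "lat"]

SECTION_VARIABLES = ["uo", "thetao", "so", "no3", "d15n_no3", "cell_area"]


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, MEASUREMENT_COLUMNS, f"measurement table {path}")
    numeric = ["d15n_measured", "standard_measured", "standard_known"]
    for col in numeric:
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise SchemaError(f"non-finite values in column {col!r} of {path}")
    return df


def read_telemetry(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TELEMETRY_COLUMNS, f"telemetry table {path}")
    lat = df["lat"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise SchemaError(f"latitude outside [-90, 90] in {path}")
    return df


def write_records(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(
        df, ["seal_id", "midpoint_year", "d15n_phe", "qc_flag"], f"record table {path}"
    )
    return df


def write_section(section: SectionSeries, path) -> None:
    section.to_dataset().to_netcdf(path, engine="scipy")


def read_section(path) -> SectionSeries:
    with xr.open_dataset(path) as ds:
        ds = ds.load()
    missing = [v for v in SECTION_VARIABLES if v not in ds]
    if missing:
        raise SchemaError(f"section file {path} is missing variables: {missing}")
    return SectionSeries.from_dataset(ds)


def write_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")


def write_geojson(region, path) -> None:
    Path(path).write_text(json.dumps(region.to_geojson(), indent=2) + "\n")
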
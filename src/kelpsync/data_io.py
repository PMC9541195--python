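"""Reading, validation, aggregation, filtering and regionalisation of
quarterly spatiotemporal data, plus tabular output.

The canonical in-memory container is :class:`QuarterlySeriesMatrix`: a
locations x quarters real matrix (NaN = missing) with an explicit
(year, quarter) time axis and per-location metadata.  Input files are
long-format CSV with one row per (location, year, quarter) observation;
outputs are plain CSV.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocationInfo",
    "QuarterlySeriesMatrix",
    "IndexSeries",
    "read_quarterly_dataset",
    "read_index_series",
    "aggregate_to_quarters",
    "filter_persistent_locations",
    "assign_regions",
    "write_attribution_table",
    "atomic_write_csv",
]

#: month -> quarter, winter = Jan-Mar, spring = Apr-Jun, summer = Jul-Sep,
#: autumn = Oct-Dec.
MONTH_TO_QUARTER = {m: (m - 1) // 3 + 1 for m in range(1, 13)}

#: Default boundary latitude separating the "central" from the "southern"
#: coastal region (Point Conception area); configurable everywhere it is used.
DEFAULT_BOUNDARY_LATITUDE = 34.45


@dataclass(frozen=True)
class LocationInfo:
    """Metadata for one 500-m-scale coastal location."""

    location_id: str
    latitude: float
    longitude: float
    region: str | None = None


@dataclass
class QuarterlySeriesMatrix:
    """Locations x quarters real-valued field.

    ``values[i, j]`` is the value of ``variable_name`` at location ``i`` in
    quarter ``time_axis[j]``; NaN encodes missing.  The time axis is a list
    of (year, quarter) pairs, strictly increasing and gap-free.
    """

    values: np.ndarray
    time_axis: list[tuple[int, int]]
    variable_name: str
    units: str
    locations: list[LocationInfo]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (locations x quarters) array")
        n, T = self.values.shape
        if n < 1 or T < 8:
            raise ValueError(f"need n >= 1 locations and T >= 8 quarters, got {n} x {T}")
        if len(self.time_axis) != T:
            raise ValueError("time_axis length does not match number of columns")
        if len(self.locations) != n:
            raise ValueError("locations length does not match number of rows")
        ids = [loc.location_id for loc in self.locations]
        if len(set(ids)) != len(ids):
            raise ValueError("location_id values must be unique")
        for (y0, q0), (y1, q1) in zip(self.time_axis, self.time_axis[1:]):
            if (y1, q1) != _next_quarter(y0, q0):
                raise ValueError(
                    f"time axis must be gap-free and increasing; "
                    f"({y0},{q0}) is followed by ({y1},{q1})"
                )
        for y, q in self.time_axis:
            if q not in (1, 2, 3, 4):
                raise ValueError(f"quarter must be in 1..4, got {q}")

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_quarters(self) -> int:
        return self.values.shape[1]

    def location_ids(self) -> list[str]:
        return [loc.location_id for loc in self.locations]

    def subset_locations(self, keep: Sequence[int]) -> "QuarterlySeriesMatrix":
        keep = list(keep)
        return QuarterlySeriesMatrix(
            values=self.values[keep].copy(),
            time_axis=list(self.time_axis),
            variable_name=self.variable_name,
            units=self.units,
            locations=[self.locations[i] for i in keep],
        )


@dataclass
class IndexSeries:
    """A single (non-spatial) series on the same quarterly axis, e.g. a
    basin-scale climate index."""

    values: np.ndarray
    time_axis: list[tuple[int, int]]
    name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.time_axis):
            raise ValueError("values must be 1-D and match time_axis length")


def _next_quarter(year: int, quarter: int) -> tuple[int, int]:
    return (year, quarter + 1) if quarter < 4 else (year + 1, 1)


def quarter_range(first: tuple[int, int], last: tuple[int, int]) -> list[tuple[int, int]]:
    """All (year, quarter) pairs from ``first`` to ``last`` inclusive."""
    if first > last:
        raise ValueError(f"empty quarter range: {first} .. {last}")
    out = [first]
    while out[-1] != last:
        out.append(_next_quarter(*out[-1]))
    return out


DEFAULT_SCHEMA = {
    "location_id": "location_id",
    "latitude": "lat",
    "longitude": "lon",
    "year": "year",
    "quarter": "quarter",
    "value": "value",
}


def read_quarterly_dataset(
    path: str | os.PathLike,
    schema: Mapping[str, str] | None = None,
    variable_name: str = "value",
    units: str = "",
) -> QuarterlySeriesMatrix:
    """Read a long-format CSV into a :class:`QuarterlySeriesMatrix`.

    ``schema`` maps the logical column roles (location_id, latitude,
    longitude, year, quarter, value) to the file's column names.  One row
    per unique (location, year, quarter); duplicates are an error; absent
    combinations become missing cells.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    missing_cols = [c for c in colmap.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    bad_q = df[~df["quarter"].isin([1, 2, 3, 4])]
    if len(bad_q):
        raise ValueError(
            f"{path}: quarter outside 1..4 at file line(s) "
            f"{[int(i) + 2 for i in bad_q.index[:5]]}"
        )
    for col in ("year", "value", "latitude", "longitude"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: malformed {col!r} at file line {int(bad.index[0]) + 2}"
            )
        df[col] = converted

    dup = df.duplicated(subset=["location_id", "year", "quarter"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for location {r['location_id']!r} "
            f"year {int(r['year'])} quarter {int(r['quarter'])}"
        )

    time_axis = quarter_range(
        (int(df["year"].min()), int(df.loc[df["year"] == df["year"].min(), "quarter"].min())),
        (int(df["year"].max()), int(df.loc[df["year"] == df["year"].max(), "quarter"].max())),
    )
    col_index = {tq: j for j, tq in enumerate(time_axis)}

    loc_ids = sorted(df["location_id"].astype(str).unique())
    locations = []
    for lid in loc_ids:
        sub = df[df["location_id"].astype(str) == lid]
        locations.append(
            LocationInfo(
                location_id=lid,
                latitude=float(sub["latitude"].iloc[0]),
                longitude=float(sub["longitude"].iloc[0]),
            )
        )
    row_index = {lid: i for i, lid in enumerate(loc_ids)}

    values = np.full((len(loc_ids), len(time_axis)), np.nan)
    for _, r in df.iterrows():
        i = row_index[str(r["location_id"])]
        j = col_index[(int(r["year"]), int(r["quarter"]))]
        values[i, j] = float(r["value"])

    return QuarterlySeriesMatrix(values, time_axis, variable_name, units, locations)


def read_index_series(path: str | os.PathLike, name: str = "index") -> IndexSeries:
    """Read a CSV with columns year, quarter, value into an IndexSeries."""
    df = pd.read_csv(path)
    for c in ("year", "quarter", "value"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    df = df.sort_values(["year", "quarter"]).reset_index(drop=True)
    time_axis = [(int(y), int(q)) for y, q in zip(df["year"], df["quarter"])]
    expected = quarter_range(time_axis[0], time_axis[-1])
    if time_axis != expected:
        raise ValueError(f"{path}: index time axis has gaps or duplicates")
    return IndexSeries(df["value"].to_numpy(float), time_axis, name)


def aggregate_to_quarters(
    records: pd.DataFrame,
    statistic: str,
    variable_name: str = "value",
    units: str = "",
) -> QuarterlySeriesMatrix:
    """Aggregate timestamped per-location records to a quarterly matrix.

    ``records`` needs columns location_id, lat, lon, date (parseable), value.
    ``statistic`` is "mean" (biomass, nitrate) or "max" (wave height).
    Quarters with no records are missing.
    """
    if statistic not in ("mean", "max"):
        raise ValueError(f"unknown statistic {statistic!r}; use 'mean' or 'max'")
    df = records.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    df["quarter"] = dates.dt.month.map(MONTH_TO_QUARTER)
    grouped = (
        df.groupby(["location_id", "year", "quarter"])["value"]
        .agg(statistic)
        .reset_index()
    )

    time_axis = quarter_range(
        (int(grouped["year"].min()), int(grouped.loc[grouped["year"] == grouped["year"].min(), "quarter"].min())),
        (int(grouped["year"].max()), int(grouped.loc[grouped["year"] == grouped["year"].max(), "quarter"].max())),
    )
    col_index = {tq: j for j, tq in enumerate(time_axis)}
    loc_ids = sorted(df["location_id"].astype(str).unique())
    row_index = {lid: i for i, lid in enumerate(loc_ids)}
    locations = []
    for lid in loc_ids:
        sub = df[df["location_id"].astype(str) == lid]
        locations.append(LocationInfo(lid, float(sub["lat"].iloc[0]), float(sub["lon"].iloc[0])))

    values = np.full((len(loc_ids), len(time_axis)), np.nan)
    for _, r in grouped.iterrows():
        values[row_index[str(r["location_id"])], col_index[(int(r["year"]), int(r["quarter"]))]] = r["value"]
    return QuarterlySeriesMatrix(values, time_axis, variable_name, units, locations)


def absent_year_counts(m: QuarterlySeriesMatrix) -> dict[str, int]:
    """Count, per location, calendar years in which every quarter is zero or
    missing ("absent" years).  Years only partially covered by the time axis
    are judged on the quarters present."""
    years = sorted({y for y, _ in m.time_axis})
    counts: dict[str, int] = {}
    for i, loc in enumerate(m.locations):
        n_absent = 0
        for y in years:
            cols = [j for j, (yy, _) in enumerate(m.time_axis) if yy == y]
            vals = m.values[i, cols]
            if np.all(np.isnan(vals) | (vals == 0.0)):
                n_absent += 1
        counts[loc.location_id] = n_absent
    return counts


def filter_persistent_locations(
    m: QuarterlySeriesMatrix, max_absent_years: int = 3
) -> tuple[QuarterlySeriesMatrix | None, pd.DataFrame]:
    """Keep locations whose cumulative count of fully-absent calendar years
    (all quarters zero or missing) is at most ``max_absent_years``.

    Returns the filtered matrix (None when nothing survives) and a report
    frame listing every location with its absent-year count and whether it
    was retained.
    """
    counts = absent_year_counts(m)
    keep = [i for i, loc in enumerate(m.locations) if counts[loc.location_id] <= max_absent_years]
    report = pd.DataFrame(
        {
            "location_id": [loc.location_id for loc in m.locations],
            "absent_years": [counts[loc.location_id] for loc in m.locations],
            "retained": [counts[loc.location_id] <= max_absent_years for loc in m.locations],
        }
    )
    if not keep:
        return None, report
    return m.subset_locations(keep), report


def assign_regions(
    locations: Iterable[LocationInfo],
    boundary_latitude: float = DEFAULT_BOUNDARY_LATITUDE,
) -> list[LocationInfo]:
    """Label each location "central" (latitude strictly above the boundary)
    or "southern" (at or below it)."""
    out = []
    for loc in locations:
        if loc.latitude is None or (isinstance(loc.latitude, float) and math.isnan(loc.latitude)):
            raise ValueError(f"location {loc.location_id!r} has no latitude")
        region = "central" if loc.latitude > boundary_latitude else "southern"
        out.append(replace(loc, region=region))
    return out


def atomic_write_csv(df: pd.DataFrame, path: str | os.PathLike, **to_csv_kwargs) -> None:
    """Write a CSV via a temp file + rename so a failed write leaves nothing
    behind."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, index=False, **to_csv_kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_attribution_table(table, path: str | os.PathLike) -> None:
    """Write an attribution table as CSV: q values in percent with one
    decimal, phases in fractions of pi with two decimals.  A full-precision
    companion file is written next to it with suffix ``.full.csv``.

    ``table`` is any object with a ``to_frame()`` method returning one row
    per (region, band) with q_* columns (fractions) and phi_* columns.
    """
    df = table.to_frame()
    if df.empty and len(df.columns) == 0:
        df = pd.DataFrame(columns=["region", "band", "q_all", "q_int"])
    path = os.fspath(path)
    full_path = path[:-4] + ".full.csv" if path.endswith(".csv") else path + ".full.csv"
    atomic_write_csv(df, full_path)

    rounded = df.copy()
    for col in rounded.columns:
        if col.startswith("q_"):
            rounded[col] = (100.0 * df[col]).map(lambda v: f"{v:.1f}")
        elif col.startswith("phi_"):
            rounded[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    atomic_write_csv(rounded, path)
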
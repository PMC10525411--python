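"""Occurrence records, spatial thinning, and invasion-timeline reconstruction.

Occurrence tables are thin wrappers over a pandas DataFrame with
``longitude`` / ``latitude`` columns plus optional ``year`` / ``country`` /
``source``.  Cleaning drops rows without finite in-bounds coordinates and
collapses exact duplicate coordinates, keeping the first.

The invasion timeline follows the country-level first-record convention: the
earliest documented year in a country is taken as its invasion year.  The
timeline has one open-ended pre-interval plus fixed-width intervals, and is
segmented into lag / spread / equilibrium phases by a spread-rate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceTable",
    "CountryFirstRecord",
    "InvasionTimeline",
    "PhaseSegmentation",
    "EmptyTableError",
    "load_occurrences",
    "clean_occurrences",
    "thin_occurrences",
    "build_timeline",
    "classify_phases",
    "first_records_from_table",
]

#: km per degree of latitude used to convert thinning cell sizes to angles
KM_PER_DEGREE = 111.32

#: sentinel start year for the open-ended pre-interval
PRE_INTERVAL_START = -9999


class EmptyTableError(ValueError):
    """A cleaning or loading step produced zero valid records."""


@dataclass
class OccurrenceTable:
    """Cleaned occurrence records on the WGS84 lon/lat datum."""

    df: pd.DataFrame
    crs: str = "WGS84"

    def __post_init__(self) -> None:
        for col in ("longitude", "latitude"):
            if col not in self.df.columns:
                raise ValueError(f"occurrence table lacks a {col!r} column")
        lon = self.df["longitude"].to_numpy(float)
        lat = self.df["latitude"].to_numpy(float)
        if not np.all(np.isfinite(lon)) or not np.all(np.isfinite(lat)):
            raise ValueError("occurrence table contains non-finite coordinates")
        if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
            raise ValueError("occurrence coordinates out of bounds")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def longitude(self) -> np.ndarray:
        return self.df["longitude"].to_numpy(float)

    @property
    def latitude(self) -> np.ndarray:
        return self.df["latitude"].to_numpy(float)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class CountryFirstRecord:
    country: str
    first_year: int


@dataclass
class InvasionTimeline:
    """Newly invaded countries per interval plus running totals.

    ``interval_edges`` holds the finite edges: the first interval is the
    open-ended ``(-inf, edges[0])`` pre-category, interval ``i >= 1`` is
    ``[edges[i-1], edges[i])`` with the final edge clamped at the timeline
    end (closed there).
    """

    interval_edges: list[int]
    new_counts: list[int]
    cumulative: list[int]

    def intervals(self) -> list[tuple[int | None, int]]:
        """(start, end) pairs; the pre-interval start is None."""
        out: list[tuple[int | None, int]] = [(None, self.interval_edges[0])]
        for i in range(1, len(self.interval_edges)):
            out.append((self.interval_edges[i - 1], self.interval_edges[i]))
        return out

    def to_frame(self) -> pd.DataFrame:
        starts = [PRE_INTERVAL_START] + self.interval_edges[:-1]
        return pd.DataFrame(
            {
                "interval_start": starts,
                "interval_end": self.interval_edges,
                "new": self.new_counts,
                "cumulative": self.cumulative,
            }
        )


@dataclass
class PhaseSegmentation:
    """Ordered lag / spread / equilibrium segmentation of a timeline."""

    phases: list[tuple[str, int | None, int]]

    def to_json_obj(self) -> list[dict]:
        return [
            {"phase": label, "start_year": start, "end_year": end}
            for label, start, end in self.phases
        ]


# ---------------------------------------------------------------------------
# loading and cleaning


def clean_occurrences(
    raw: pd.DataFrame,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
    year_col: str | None = "year",
    country_col: str | None = "country",
    source: str = "",
) -> tuple[OccurrenceTable, dict]:
    """Validate and deduplicate a raw occurrence frame.

    Rows with missing or unparseable coordinates, or coordinates outside
    WGS84 bounds, are dropped; exact duplicate (lon, lat) pairs are
    collapsed to the first.  Returns the table and a cleaning report.
    """
    n_read = len(raw)
    lon = pd.to_numeric(raw[lon_col], errors="coerce")
    lat = pd.to_numeric(raw[lat_col], errors="coerce")
    ok = (
        np.isfinite(lon.to_numpy(float))
        & np.isfinite(lat.to_numpy(float))
        & (lon.abs() <= 180)
        & (lat.abs() <= 90)
    )
    df = pd.DataFrame({"longitude": lon[ok], "latitude": lat[ok]})
    if year_col and year_col in raw.columns:
        df["year"] = pd.to_numeric(raw.loc[ok, year_col], errors="coerce")
    if country_col and country_col in raw.columns:
        df["country"] = raw.loc[ok, country_col].astype(str)
    df["source"] = source
    n_valid = len(df)
    df = df.drop_duplicates(subset=["longitude", "latitude"], keep="first").reset_index(
        drop=True
    )
    report = {
        "rows_read": int(n_read),
        "rows_dropped": int(n_read - n_valid),
        "duplicates_collapsed": int(n_valid - len(df)),
        "rows_kept": int(len(df)),
    }
    if len(df) == 0:
        raise EmptyTableError("no valid occurrence records after cleaning")
    return OccurrenceTable(df), report


def load_occurrences(
    path: str | Path,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
    year_col: str | None = "year",
    country_col: str | None = "country",
    sep: str = ",",
) -> tuple[OccurrenceTable, dict]:
    """Read delimited occurrence records from disk and clean them."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep)
    for col in (lon_col, lat_col):
        if col not in raw.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    return clean_occurrences(
        raw, lon_col, lat_col, year_col, country_col, source=str(path)
    )


# ---------------------------------------------------------------------------
# spatial thinning


def thin_occurrences(table: OccurrenceTable, cell_km: float = 5.0) -> OccurrenceTable:
    """Keep at most one record per square thinning cell.

    The kilometre cell size is converted to a fixed angular cell
    (``cell_km / 111.32`` degrees) anchored at (-180, -90); within a cell the
    first record in input order is retained, which makes the operation
    deterministic and idempotent.
    """
    if cell_km <= 0:
        raise ValueError("cell size must be positive")
    if len(table) == 0:
        raise EmptyTableError("cannot thin an empty table")
    cell_deg = cell_km / KM_PER_DEGREE
    ix = np.floor((table.longitude + 180.0) / cell_deg).astype(np.int64)
    iy = np.floor((table.latitude + 90.0) / cell_deg).astype(np.int64)
    key = pd.MultiIndex.from_arrays([ix, iy])
    keep = ~key.duplicated(keep="first")
    return OccurrenceTable(table.df.loc[keep].reset_index(drop=True), table.crs)


# ---------------------------------------------------------------------------
# invasion timeline


def first_records_from_table(table: OccurrenceTable) -> list[CountryFirstRecord]:
    """Earliest recorded year per country from an occurrence table."""
    df = table.df
    if "country" not in df.columns or "year" not in df.columns:
        raise ValueError("table needs country and year columns for first records")
    sub = df.dropna(subset=["country", "year"])
    firsts = sub.groupby("country")["year"].min()
    return [CountryFirstRecord(c, int(y)) for c, y in firsts.sort_index().items()]


def build_timeline(
    first_records: list[CountryFirstRecord],
    pre_edge: int = 1970,
    width: int = 10,
    end: int = 2023,
) -> InvasionTimeline:
    """Bin country first-record years into an open pre-interval plus fixed-width intervals.

    Interval 0 is ``(-inf, pre_edge)``; later intervals are half-open
    ``[edge, edge + width)``.  A trailing partial period shorter than
    ``width`` is merged into the last full-width interval, so e.g.
    1970..2023 with width 10 gives five finite intervals, the last spanning
    2010..2023 (inclusive of the end year).
    """
    if end < pre_edge:
        raise ValueError("timeline end precedes the pre-interval edge")
    seen: dict[str, int] = {}
    for rec in first_records:
        if rec.first_year > end:
            raise ValueError(
                f"country {rec.country!r} has first record {rec.first_year} after timeline end {end}"
            )
        if rec.country not in seen or rec.first_year < seen[rec.country]:
            seen[rec.country] = rec.first_year
    span = end - pre_edge
    n_finite = max(1, span // width)
    edges = [pre_edge + k * width for k in range(1, n_finite)] + [end]
    edges = [pre_edge] + edges
    n_int = len(edges)  # total intervals including the pre-category
    new_counts = [0] * n_int
    for year in seen.values():
        if year < pre_edge:
            new_counts[0] += 1
            continue
        idx = min((year - pre_edge) // width + 1, n_int - 1)
        new_counts[idx] += 1
    cumulative = list(np.cumsum(new_counts).astype(int))
    return InvasionTimeline(edges, new_counts, cumulative)


def classify_phases(
    timeline: InvasionTimeline, spread_rate: int = 6
) -> PhaseSegmentation:
    """Segment a timeline into lag -> spread -> equilibrium phases.

    The lag phase is the maximal prefix of intervals with fewer than
    ``spread_rate`` newly invaded countries per interval (the open-ended
    pre-interval is always part of the lag and excluded from the rate
    comparison); the spread phase is the maximal following run at or above
    the rate; everything after is equilibrium.  Any phase may be empty.
    """
    counts = timeline.new_counts
    if len(counts) < 2:
        raise ValueError("timeline needs at least 2 intervals to segment")
    intervals = timeline.intervals()
    # index of first finite interval at/above the spread rate
    i = 1
    while i < len(counts) and counts[i] < spread_rate:
        i += 1
    spread_start = i
    while i < len(counts) and counts[i] >= spread_rate:
        i += 1
    spread_end = i
    phases: list[tuple[str, int | None, int]] = []
    if spread_start > 0:
        phases.append(("lag", None, intervals[spread_start - 1][1]))
    if spread_end > spread_start:
        phases.append(
            ("spread", intervals[spread_start][0], intervals[spread_end - 1][1])
        )
    if spread_end < len(counts):
        phases.append(("equilibrium", intervals[spread_end][0], intervals[-1][1]))
    return PhaseSegmentation(phases)
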
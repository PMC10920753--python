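"""Domain types and I/O for salmon mass-mortality event (MME) records.

An event record says *who* (country, reporting unit — a production site or a
county), *when* (period start date at a declared temporal resolution) and
*how many* fish were lost.  Countries report at different grains: some per
site per month or finer, some per county per month, some only as yearly
totals per facility.  Everything downstream (trend tests, extreme-value
fits) consumes either the raw event magnitudes or regular time series
aggregated from them.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mmerisk")

RESOLUTIONS = ("submonthly", "monthly", "yearly")

#: ordering used to decide whether a requested aggregation grain is coarser
#: than the native reporting grain
_RESOLUTION_RANK = {"submonthly": 0, "monthly": 1, "yearly": 2}

STATISTICS = ("count", "max", "sum", "mean")


class DataError(Exception):
    """Base class for event-data problems."""


class SchemaError(DataError):
    """Input file does not provide the required columns."""


class ValidationError(DataError):
    """A record violates an invariant (negative count, bad date, ...)."""


class ResolutionError(DataError):
    """Requested aggregation finer than the native reporting resolution."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalityEvent:
    """One reported loss record.

    Parameters
    ----------
    country : str
        Country label (e.g. ``"Norway"``).
    unit_id : str
        Reporting unit: production site or county identifier.
    period_start : datetime.date
        Start of the reporting period.  Yearly records carry January 1 of
        the year; monthly records the first of the month.
    resolution : str
        One of ``submonthly``, ``monthly``, ``yearly``.
    fish_lost : int
        Non-negative count of fish lost in the period.
    latitude, longitude : float or None
        Optional position in decimal degrees.
    """

    country: str
    unit_id: str
    period_start: _dt.date
    resolution: str
    fish_lost: int
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTIONS:
            raise ValidationError(
                f"unknown resolution {self.resolution!r}; expected one of {RESOLUTIONS}"
            )
        if not float(self.fish_lost).is_integer() or self.fish_lost < 0:
            raise ValidationError(
                f"fish_lost must be a non-negative integer, got {self.fish_lost!r}"
            )
        object.__setattr__(self, "fish_lost", int(self.fish_lost))

    @property
    def key(self) -> tuple:
        """Duplicate-detection key (country, unit, period, magnitude)."""
        return (self.country, self.unit_id, self.period_start, self.fish_lost)


@dataclass
class EventTable:
    """Ordered collection of :class:`MortalityEvent` with provenance."""

    events: list[MortalityEvent]
    source: str = "<memory>"
    n_source_rows: int = -1
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_source_rows < 0:
            self.n_source_rows = len(self.events)
        self._warn_on_mixed_resolution()

    def _warn_on_mixed_resolution(self) -> None:
        per_country: dict[str, set[str]] = {}
        for ev in self.events:
            per_country.setdefault(ev.country, set()).add(ev.resolution)
        for country, res in per_country.items():
            if len(res) > 1:
                warnings.warn(
                    f"country {country!r} mixes reporting resolutions {sorted(res)}",
                    stacklevel=3,
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[MortalityEvent]:
        return iter(self.events)

    def countries(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.country)
        return list(seen)

    def for_country(self, country: str) -> "EventTable":
        return EventTable(
            [ev for ev in self.events if ev.country == country],
            source=f"{self.source}[{country}]",
        )

    def restrict_years(self, first: int, last: int) -> "EventTable":
        """Keep events whose period starts in ``first..last`` inclusive."""
        return EventTable(
            [ev for ev in self.events if first <= ev.period_start.year <= last],
            source=f"{self.source}[{first}-{last}]",
        )

    def magnitudes(self) -> np.ndarray:
        return np.array([ev.fish_lost for ev in self.events], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": [e.country for e in self.events],
                "unit_id": [e.unit_id for e in self.events],
                "period_start": [e.period_start.isoformat() for e in self.events],
                "resolution": [e.resolution for e in self.events],
                "fish_lost": [e.fish_lost for e in self.events],
                "latitude": [e.latitude for e in self.events],
                "longitude": [e.longitude for e in self.events],
            }
        )


@dataclass
class EventSeries:
    """Regular, contiguous time-indexed series derived from events.

    ``values`` holds one number per period; NaN marks periods that are
    undefined for the statistic (e.g. the maximum of an empty month).
    """

    country: str
    periods: pd.PeriodIndex
    values: np.ndarray
    statistic: str
    resolution: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.statistic not in STATISTICS:
            raise ValidationError(f"unknown statistic {self.statistic!r}")
        if len(self.periods) != len(self.values):
            raise ValidationError("periods and values must be equal length")
        if len(self.periods) < 1:
            raise ValidationError("series must have length >= 1")
        if len(self.periods) > 1:
            deltas = np.diff(self.periods.asi8)
            if not np.all(deltas == 1):
                raise ValidationError("period index must be strictly increasing and contiguous")

    def __len__(self) -> int:
        return len(self.values)

    def dropna(self) -> np.ndarray:
        """Values with undefined periods removed (for trend tests on maxima)."""
        return self.values[~np.isnan(self.values)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": self.country,
                "period": self.periods.astype(str),
                "value": self.values,
                "statistic": self.statistic,
                "resolution": self.resolution,
            }
        )


@dataclass
class ThresholdSet:
    """Company/county MME threshold values for one country.

    A threshold is the loss level at which a reporting unit considers an
    event a mass mortality; the aggregate mean is what risk estimates are
    compared against.
    """

    country: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for unit, v in self.values.items():
            if not v > 0:
                raise ValidationError(f"threshold for {unit!r} must be > 0, got {v}")


def mean_threshold(thresholds: ThresholdSet) -> float:
    """Arithmetic mean of the per-unit threshold values."""
    if not thresholds.values:
        raise ValidationError("threshold set is empty")
    return float(np.mean(list(thresholds.values.values())))


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

#: logical fields every schema must map to a CSV column
REQUIRED_FIELDS = ("country", "unit_id", "period_start", "fish_lost")

DEFAULT_SCHEMA: dict = {
    "columns": {
        "country": "country",
        "unit_id": "unit_id",
        "period_start": "period_start",
        "resolution": "resolution",
        "fish_lost": "fish_lost",
        "latitude": "latitude",
        "longitude": "longitude",
    },
    "date_format": "%Y-%m-%d",
    "resolution": None,       # fixed resolution if the file has no column
    "allow_duplicates": False,
}


def _anchor_date(date: _dt.date, resolution: str) -> _dt.date:
    """Snap a parsed date to the convention for its resolution.

    Yearly records are anchored to Jan 1, monthly (and sub-monthly, which
    are binned into their containing month downstream) to the first of the
    month; sub-monthly records keep their day.
    """
    if resolution == "yearly":
        return _dt.date(date.year, 1, 1)
    if resolution == "monthly":
        return _dt.date(date.year, date.month, 1)
    return date


def read_events(path, schema: Mapping | None = None) -> EventTable:
    """Read an event CSV using a logical-field → column mapping.

    Rows failing validation are collected (with their 1-based data row
    number) in ``EventTable.rejected``, never silently dropped.  A missing
    required column raises :class:`SchemaError`.
    """
    cfg = dict(DEFAULT_SCHEMA)
    if schema:
        cfg.update(schema)
        if "columns" in schema:
            cols = dict(DEFAULT_SCHEMA["columns"])
            cols.update(schema["columns"])
            cfg["columns"] = cols
    colmap = cfg["columns"]

    frame = pd.read_csv(path, dtype=str)
    for logical in REQUIRED_FIELDS:
        col = colmap.get(logical)
        if col is None or col not in frame.columns:
            raise SchemaError(
                f"required field {logical!r} maps to column {col!r} which is "
                f"absent from {path} (columns: {list(frame.columns)})"
            )
    has_res_col = colmap.get("resolution") in frame.columns
    if not has_res_col and cfg.get("resolution") is None:
        raise SchemaError(
            "no resolution column present and no fixed 'resolution' given in schema"
        )

    events: list[MortalityEvent] = []
    rejected: list[tuple[int, str]] = []
    seen_keys: set[tuple] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        rowd = dict(zip(frame.columns, row))
        try:
            resolution = (
                str(rowd[colmap["resolution"]]).strip().lower()
                if has_res_col
                else cfg["resolution"]
            )
            raw_date = str(rowd[colmap["period_start"]]).strip()
            try:
                date = _dt.datetime.strptime(raw_date, cfg["date_format"]).date()
            except ValueError as exc:
                raise ValidationError(f"unparseable date {raw_date!r}: {exc}") from exc
            raw_count = str(rowd[colmap["fish_lost"]]).strip()
            try:
                count = float(raw_count.replace(",", ""))
            except ValueError as exc:
                raise ValidationError(f"unparseable count {raw_count!r}") from exc
            ev = MortalityEvent(
                country=str(rowd[colmap["country"]]).strip(),
                unit_id=str(rowd[colmap["unit_id"]]).strip(),
                period_start=_anchor_date(date, resolution),
                resolution=resolution,
                fish_lost=count,
                latitude=_opt_float(rowd.get(colmap.get("latitude"))),
                longitude=_opt_float(rowd.get(colmap.get("longitude"))),
            )
            if not cfg.get("allow_duplicates") and ev.key in seen_keys:
                raise ValidationError(f"duplicate record {ev.key}")
            seen_keys.add(ev.key)
            events.append(ev)
        except ValidationError as exc:
            rejected.append((i, str(exc)))

    logger.info(
        "read %s: %d rows accepted, %d rejected", path, len(events), len(rejected)
    )
    for rownum, msg in rejected:
        logger.warning("row %d rejected: %s", rownum, msg)
    table = EventTable(events, source=str(path), n_source_rows=len(frame))
    table.rejected = rejected
    return table


def _opt_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    return float(s)


def read_thresholds(path) -> dict[str, ThresholdSet]:
    """Read a threshold CSV (columns country, unit_id, threshold_fish)."""
    frame = pd.read_csv(path)
    for col in ("country", "unit_id", "threshold_fish"):
        if col not in frame.columns:
            raise SchemaError(f"threshold file {path} lacks column {col!r}")
    out: dict[str, ThresholdSet] = {}
    for country, group in frame.groupby("country"):
        out[str(country)] = ThresholdSet(
            str(country),
            {str(u): float(v) for u, v in zip(group["unit_id"], group["threshold_fish"])},
        )
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(
    events: EventTable,
    resolution: str,
    statistic: str,
    span: tuple[str, str] | None = None,
) -> EventSeries:
    """Aggregate one country's events to a regular series.

    ``count`` fills event-free periods with 0 (no extreme event that month
    is genuine information); ``max``/``sum``/``mean`` leave them as NaN —
    the maximum of an empty month is undefined, and inventing a zero would
    fabricate data.

    Raises :class:`ResolutionError` when monthly aggregation is requested
    for yearly-native records.
    """
    if resolution not in ("monthly", "yearly"):
        raise ValidationError(f"aggregation resolution must be monthly or yearly, got {resolution!r}")
    if statistic not in ("count", "max", "sum", "mean"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    if len(events) == 0 and span is None:
        raise ValidationError("cannot aggregate an empty table without an explicit span")

    countries = events.countries()
    if len(countries) > 1:
        raise ValidationError(f"aggregate expects a single country, got {countries}")
    country = countries[0] if countries else ""

    freq = "M" if resolution == "monthly" else "Y"
    for ev in events:
        if _RESOLUTION_RANK[ev.resolution] > _RESOLUTION_RANK[resolution]:
            raise ResolutionError(
                f"{ev.resolution}-native event at {ev.period_start} cannot be "
                f"aggregated to {resolution} resolution"
            )

    periods = pd.PeriodIndex(
        [pd.Period(ev.period_start, freq=freq) for ev in events], freq=freq
    )
    values = pd.Series([float(ev.fish_lost) for ev in events], index=periods)

    if span is not None:
        full = pd.period_range(pd.Period(span[0], freq=freq), pd.Period(span[1], freq=freq), freq=freq)
    elif len(values) > 0:
        full = pd.period_range(periods.min(), periods.max(), freq=freq)
    else:
        raise ValidationError("empty table and empty span")

    grouped = values.groupby(level=0)
    if statistic == "count":
        out = grouped.count().reindex(full, fill_value=0).astype(float)
    else:
        agg = {"max": "max", "sum": "sum", "mean": "mean"}[statistic]
        out = grouped.agg(agg).reindex(full)

    return EventSeries(
        country=country,
        periods=full,
        values=out.to_numpy(dtype=float),
        statistic=statistic,
        resolution=resolution,
    )


def total_mortality(events: EventTable) -> int:
    """Total fish lost across all records."""
    return int(sum(ev.fish_lost for ev in events))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_events(events: EventTable, path) -> None:
    events.to_frame().to_csv(path, index=False)


def write_series(series: EventSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def write_geojson(events: EventTable, path) -> int:
    """Export located events as a GeoJSON FeatureCollection.

    Events without coordinates are skipped; returns the number of features
    written.
    """
    features = []
    for ev in events:
        if ev.latitude is None or ev.longitude is None:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [ev.longitude, ev.latitude]},
                "properties": {
                    "country": ev.country,
                    "fish_lost": ev.fish_lost,
                    "period_start": ev.period_start.isoformat(),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return len(features)
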
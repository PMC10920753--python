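"""Configuration-driven end-to-end pipeline.

One flat config drives ingestion (or synthesis), per-country trend tests
on event frequency and per-period maxima, extreme-value risk estimation,
and report emission (CSV tables, lowess-annotated plots, optional GeoJSON,
and a machine-readable run manifest).  Identical config + inputs produce
identical numeric outputs; per-country failures are isolated and reported
rather than aborting the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import (
    DataError,
    EventTable,
    ThresholdSet,
    aggregate,
    read_events,
    read_thresholds,
    total_mortality,
    write_events,
    write_geojson,
    write_series,
)
from .evt import FitError, RiskDomainError, RiskEstimate, country_risk_summary
from .synthetic import (
    GeneratorConfig,
    GpdTailMagnitude,
    LognormalMagnitude,
    ParameterError,
    generate_events,
)
from .trends import InsufficientDataError, TrendResult, lowess_smooth, select_top_fraction, trend_test_pipeline

logger = logging.getLogger("mmerisk")


class ConfigError(ValueError):
    """The run configuration is malformed or incomplete."""


#: study-default per-country settings: reporting resolution, analysis
#: basis, top-fraction rule and the year window the collation is trusted in
DEFAULT_COUNTRY_SETTINGS: dict[str, dict] = {
    "Norway": {"resolution": "monthly", "basis": "per_event", "top_fraction": 0.10, "years": (2012, 2021)},
    "Canada": {"resolution": "monthly", "basis": "per_event", "top_fraction": 0.10, "years": (2013, 2020)},
    "UK": {"resolution": "monthly", "basis": "per_event", "top_fraction": 0.10, "years": (2015, 2021)},
    "Chile": {"resolution": "yearly", "basis": "per_year", "top_fraction": 0.50, "years": (2013, 2021)},
    "Australia": {"resolution": "yearly", "basis": "per_year", "top_fraction": 0.50, "years": (2013, 2021)},
    "New Zealand": {"resolution": "yearly", "basis": "per_year", "top_fraction": 0.50, "years": (2013, 2021)},
}


@dataclass
class CountrySettings:
    resolution: str = "monthly"
    basis: str = "per_event"
    top_fraction: float = 0.10
    years: tuple[int, int] | None = None


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    output_dir: str = "mmerisk_out"
    events_path: str | None = None
    thresholds_path: str | None = None
    schema: dict | None = None
    synthetic: list[GeneratorConfig] = field(default_factory=list)
    countries: dict[str, CountrySettings] = field(default_factory=dict)
    run_trend: bool = True
    run_evt: bool = True
    map_export: bool = False
    make_plots: bool = False
    q: float = 0.999
    q_upper: float = 0.9999
    log_level: str = "INFO"

    def settings_for(self, country: str) -> CountrySettings:
        if country in self.countries:
            return self.countries[country]
        if country in DEFAULT_COUNTRY_SETTINGS:
            d = DEFAULT_COUNTRY_SETTINGS[country]
            return CountrySettings(
                resolution=d["resolution"], basis=d["basis"],
                top_fraction=d["top_fraction"], years=d["years"],
            )
        return CountrySettings()


def _magnitude_from_dict(d: dict):
    kind = d.get("kind", "lognormal")
    if kind == "lognormal":
        return LognormalMagnitude(mu=float(d["mu"]), sigma=float(d["sigma"]))
    if kind == "gpd_tail":
        return GpdTailMagnitude(
            body_scale=float(d["body_scale"]),
            tail_shape=float(d["tail_shape"]),
            tail_scale=float(d["tail_scale"]),
            tail_fraction=float(d["tail_fraction"]),
        )
    raise ConfigError(f"unknown magnitude kind {kind!r}")


def load_config(path, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; an explicit seed overrides the file's."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "mmerisk_out")),
            events_path=raw.get("events"),
            thresholds_path=raw.get("thresholds"),
            schema=raw.get("schema"),
            run_trend=bool(raw.get("analyses", {}).get("trend", True)),
            run_evt=bool(raw.get("analyses", {}).get("evt", True)),
            map_export=bool(raw.get("analyses", {}).get("map_export", False)),
            make_plots=bool(raw.get("analyses", {}).get("plots", False)),
            q=float(raw.get("q", 0.999)),
            q_upper=float(raw.get("q_upper", 0.9999)),
            log_level=str(raw.get("log_level", "INFO")),
        )
        for name, d in (raw.get("countries") or {}).items():
            years = d.get("years")
            cfg.countries[name] = CountrySettings(
                resolution=d.get("resolution", "monthly"),
                basis=d.get("basis", "per_event"),
                top_fraction=float(d.get("top_fraction", 0.10)),
                years=tuple(years) if years else None,
            )
        for d in raw.get("synthetic") or []:
            d = dict(d)
            mag = d.pop("magnitude", None)
            if mag is not None:
                d["magnitude"] = _magnitude_from_dict(mag)
            cfg.synthetic.append(GeneratorConfig(**d))
    except (KeyError, TypeError, ValueError, ParameterError) as exc:
        raise ConfigError(f"bad configuration {path}: {exc}") from exc
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


@dataclass
class ReportBundle:
    """Outcome of one pipeline run."""

    output_dir: Path
    trend_rows: list[dict] = field(default_factory=list)
    risk_rows: list[dict] = field(default_factory=list)
    total_fish_lost: int = 0
    failures: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _collect_events(config: RunConfig) -> EventTable:
    if config.events_path:
        return read_events(config.events_path, config.schema)
    if config.synthetic:
        events = []
        for i, gen in enumerate(config.synthetic):
            gen = dataclasses.replace(gen, seed=(config.seed * 1_000 + gen.seed + i) % (2**31))
            events.extend(generate_events(gen).events)
        return EventTable(events, source=f"synthetic(seed={config.seed})")
    raise ConfigError("config provides neither an events CSV nor synthetic generators")


def _frequency_series(events: EventTable, settings: CountrySettings):
    """Counts per period of the country's top-fraction events (zeros kept)."""
    top = select_top_fraction(events, settings.top_fraction)
    span = None
    if settings.years:
        if settings.resolution == "monthly":
            span = (f"{settings.years[0]}-01", f"{settings.years[1]}-12")
        else:
            span = (str(settings.years[0]), str(settings.years[1]))
    return aggregate(top, settings.resolution, "count", span=span)


def _maxima_series(events: EventTable, settings: CountrySettings):
    """Per-period maximum loss over all events (empty periods stay missing)."""
    return aggregate(events, settings.resolution, "max")


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> ReportBundle:
    """Execute ingestion → trends → extreme-value analysis → reports."""
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out)

    events = _collect_events(config)
    bundle.total_fish_lost = total_mortality(events)
    write_events(events, out / "events.csv")

    thresholds: dict[str, ThresholdSet] = {}
    if config.thresholds_path:
        thresholds = read_thresholds(config.thresholds_path)

    for country in events.countries():
        settings = config.settings_for(country)
        table = events.for_country(country)
        if settings.years:
            table = table.restrict_years(*settings.years)
        try:
            if config.run_trend:
                for series_type, series in (
                    ("frequency", _frequency_series(table, settings)),
                    ("maxima", _maxima_series(table, settings)),
                ):
                    write_series(series, out / f"series_{country}_{series_type}.csv".replace(" ", "_"))
                    result = trend_test_pipeline(series)
                    row = {"country": country, "series": series_type,
                           "resolution": settings.resolution,
                           "top_fraction": settings.top_fraction if series_type == "frequency" else None}
                    row.update(result.to_row())
                    bundle.trend_rows.append(row)
                    if config.make_plots:
                        _plot_series(series, result, out, country, series_type)
            if config.run_evt:
                est = country_risk_summary(
                    table,
                    thresholds.get(country),
                    basis=settings.basis,
                    top_fraction=settings.top_fraction,
                    q=config.q,
                    q_upper=config.q_upper,
                )
                bundle.risk_rows.append(est.to_row())
        except (DataError, FitError, RiskDomainError, InsufficientDataError, ParameterError, ValueError) as exc:
            logger.error("country %s failed: %s", country, exc)
            bundle.failures[country] = str(exc)

    if config.map_export:
        n = write_geojson(events, out / "events.geojson")
        logger.info("wrote %d located events to events.geojson", n)

    if bundle.trend_rows:
        pd.DataFrame(bundle.trend_rows).to_csv(out / "trend_results.csv", index=False)
    if bundle.risk_rows:
        pd.DataFrame(bundle.risk_rows).to_csv(out / "risk_estimates.csv", index=False)
        if config.make_plots:
            _plot_risk(bundle.risk_rows, out)

    bundle.manifest = _manifest(config, bundle)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
    return bundle


def _manifest(config: RunConfig, bundle: ReportBundle) -> dict:
    cfg_dict = dataclasses.asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    return {
        "package": "mmerisk",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "total_fish_lost": bundle.total_fish_lost,
        "n_trend_rows": len(bundle.trend_rows),
        "n_risk_rows": len(bundle.risk_rows),
        "failures": bundle.failures,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


# ---------------------------------------------------------------------------
# Plotting (secondary artifacts; all checks read the CSV/JSON reports)
# ---------------------------------------------------------------------------

def _plot_series(series, result: TrendResult, out: Path, country: str, series_type: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = ~np.isnan(series.values)
    x = np.arange(len(series.values), dtype=float)[mask]
    y = series.values[mask]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(x, y, "o", ms=3, color="0.4", label=series_type)
    if len(x) >= 3:
        ax.plot(x, lowess_smooth(x, y), "-", color="black", label="lowess")
    ax.set_title(f"{country} {series_type} (tau={result.tau:.3f}, p={result.p:.3g})")
    ax.set_xlabel(f"{series.resolution} period index")
    ax.set_ylabel("events" if series_type == "frequency" else "max fish lost")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / f"trend_{country}_{series_type}.png".replace(" ", "_"), dpi=100)
    plt.close(fig)


def _plot_risk(rows: list[dict], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    names = [r["country"] for r in rows]
    es = [r["es_point"] for r in rows]
    lo = [max(r["es_point"] - r["var_lower"], 0.0) for r in rows]
    hi = [max(r["var_upper"] - r["es_point"], 0.0) for r in rows]
    ax.bar(names, es, color="steelblue")
    ax.errorbar(names, es, yerr=[lo, hi], fmt="none", ecolor="black", capsize=4)
    for r in rows:
        if np.isfinite(r.get("threshold_mean", float("nan"))):
            ax.axhline(r["threshold_mean"], color="firebrick", ls="--", lw=0.8)
    ax.set_ylabel("fish")
    ax.set_title("Expected shortfall with 1/1,000 – 1/10,000 event bounds")
    fig.tight_layout()
    fig.savefig(out / "risk_estimates.png", dpi=100)
    plt.close(fig)
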
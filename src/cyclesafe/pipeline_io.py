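"""Formats, configuration, orchestration and run manifests.

CSV dialect is UTF-8, comma-separated, "." decimal, ISO-8601 datetimes.
GeoJSON carries planar metric coordinates (a local projected CRS declared
in the config); nothing here transforms coordinates.  A pipeline run is
reproducible: every stochastic stage derives its seed from the single
config seed, and the manifest records content hashes of the config and of
every stage output so a re-run can prove byte-identity or refuse to resume
from corrupted intermediates.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml
from shapely.geometry import mapping, shape

from .errors import InvalidArgumentError, SchemaError
from .synthetic_city import (GrowthTrend, RoadNetwork, Zone, ZoneMap,
                             default_risk, generate_city, generate_collisions,
                             generate_surveys, place_hotspot_centers,
                             true_vkmt_panel)

REQUIRED_COLLISION_COLUMNS = ("event_id", "x", "y", "zone_id", "datetime",
                              "fatal", "sex", "age", "vehicle_type")


# ---------------------------------------------------------------------------
# Collision ingest
# ---------------------------------------------------------------------------

@dataclass
class IngestReport:
    n_read: int
    n_kept: int
    n_under5: int
    quarantined: pd.DataFrame  # original rows + 'reason'


def read_collisions(path, schema=REQUIRED_COLLISION_COLUMNS
                    ) -> tuple[pd.DataFrame, IngestReport]:
    """Read and type a collision table, applying the ingest rules.

    Rows with individuals under five years old are removed and counted;
    rows with unparseable datetimes or non-finite coordinates are
    quarantined with a reason and the run continues.  A missing required
    column is a schema error naming the column.
    """
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    n_read = len(df)
    reasons = pd.Series("", index=df.index, dtype=object)

    dt = pd.to_datetime(df["datetime"], errors="coerce", format="ISO8601")
    reasons[dt.isna()] = "malformed datetime"
    xy_bad = (~np.isfinite(pd.to_numeric(df["x"], errors="coerce"))
              | ~np.isfinite(pd.to_numeric(df["y"], errors="coerce")))
    reasons[xy_bad & (reasons == "")] = "invalid coordinates"
    quarantined = df[reasons != ""].copy()
    quarantined["reason"] = reasons[reasons != ""]
    keep = df[reasons == ""].copy()
    keep["datetime"] = dt[reasons == ""]
    keep["x"] = keep["x"].astype(float)
    keep["y"] = keep["y"].astype(float)
    keep["fatal"] = keep["fatal"].astype(int)

    under5 = keep["age"].astype(float) < 5
    n_under5 = int(under5.sum())
    keep = keep[~under5].reset_index(drop=True)
    return keep, IngestReport(n_read=n_read, n_kept=len(keep),
                              n_under5=n_under5, quarantined=quarantined)


# ---------------------------------------------------------------------------
# GeoJSON round-trip
# ---------------------------------------------------------------------------

def write_zones_geojson(zones: ZoneMap, path) -> None:
    feats = [{"type": "Feature",
              "properties": {"zone_id": z.zone_id,
                             "income_stratum": z.income_stratum},
              "geometry": mapping(z.polygon)} for z in zones.zones]
    minx, miny, maxx, maxy = zones.window.bounds
    obj = {"type": "FeatureCollection",
           "bbox": [minx, miny, maxx, maxy],
           "features": feats}
    Path(path).write_text(json.dumps(obj))


def read_zones_geojson(path) -> ZoneMap:
    obj = json.loads(Path(path).read_text())
    zones = [Zone(f["properties"]["zone_id"], shape(f["geometry"]),
                  f["properties"]["income_stratum"])
             for f in obj["features"]]
    from shapely.geometry import box
    window = box(*obj["bbox"])
    return ZoneMap(zones=zones, window=window)


def write_network_geojson(network: RoadNetwork, path) -> None:
    g = network.graph
    feats = []
    for n, attrs in g.nodes(data=True):
        feats.append({"type": "Feature",
                      "properties": {"kind": "node", "node_id": n},
                      "geometry": {"type": "Point",
                                   "coordinates": [attrs["x"], attrs["y"]]}})
    for a, b, attrs in g.edges(data=True):
        props = {"kind": "edge", "node_a": a, "node_b": b, **attrs}
        coords = [[g.nodes[a]["x"], g.nodes[a]["y"]],
                  [g.nodes[b]["x"], g.nodes[b]["y"]]]
        feats.append({"type": "Feature", "properties": props,
                      "geometry": {"type": "LineString",
                                   "coordinates": coords}})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_network_geojson(path) -> RoadNetwork:
    obj = json.loads(Path(path).read_text())
    g = nx.Graph()
    for f in obj["features"]:
        props = f["properties"]
        if props["kind"] == "node":
            x, y = f["geometry"]["coordinates"]
            g.add_node(props["node_id"], x=x, y=y)
    for f in obj["features"]:
        props = dict(f["properties"])
        if props.pop("kind") == "edge":
            a = props.pop("node_a")
            b = props.pop("node_b")
            g.add_edge(a, b, **props)
    return RoadNetwork(graph=g)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "seed", "n_zones", "window", "survey_years", "trend", "period",
    "n_events", "hotspot", "severity", "epsg", "n_sample_persons",
    "n_sample_trips",
}
_TREND_KEYS = {"kind", "base_year", "base_total", "factor", "end_year"}
_HOTSPOT_KEYS = {"mass", "top_fraction", "sigma", "side"}
_SEVERITY_KEYS = {"balance", "stratify", "screen"}


@dataclass
class RunConfig:
    seed: int
    n_zones: int = 16
    window: tuple[float, float] = (8000.0, 8000.0)
    survey_years: tuple[int, ...] = (2005, 2011, 2014, 2015, 2017)
    period: tuple[int, int] = (2011, 2017)
    n_events: int = 1500
    trend: dict = field(default_factory=dict)
    hotspot: dict = field(default_factory=lambda: {"mass": 0.95,
                                                   "top_fraction": 0.05})
    severity: dict = field(default_factory=lambda: {"balance": 0.30,
                                                    "stratify": None,
                                                    "screen": True})
    epsg: str = "local-transverse-mercator"
    n_sample_persons: int = 3000
    n_sample_trips: int = 3000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise SchemaError("config must set a seed")
        for key, allowed in (("trend", _TREND_KEYS),
                             ("hotspot", _HOTSPOT_KEYS),
                             ("severity", _SEVERITY_KEYS)):
            bad = set(raw.get(key, {})) - allowed
            if bad:
                raise SchemaError(f"unknown {key} key(s): {sorted(bad)}")
        kwargs = dict(raw)
        if "window" in kwargs:
            kwargs["window"] = tuple(float(v) for v in kwargs["window"])
        if "survey_years" in kwargs:
            kwargs["survey_years"] = tuple(int(v)
                                           for v in kwargs["survey_years"])
        if "period" in kwargs:
            kwargs["period"] = tuple(int(v) for v in kwargs["period"])
        base = cls(seed=int(kwargs.pop("seed")))
        for k, v in kwargs.items():
            default = getattr(base, k)
            if isinstance(default, dict) and isinstance(v, dict):
                default.update(v)
            else:
                setattr(base, k, v)
        return base

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


# ---------------------------------------------------------------------------
# Manifest and orchestration
# ---------------------------------------------------------------------------

def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)
    # stage -> {"outputs": {relpath: sha256}, "completed_at": iso, "ok": bool}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "stages": self.stages},
            indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunManifest":
        obj = json.loads(Path(path).read_text())
        return cls(config_hash=obj["config_hash"], stages=obj["stages"])

    @property
    def completed_stages(self) -> list[str]:
        return [s for s, rec in self.stages.items() if rec.get("ok")]


STAGES = ("simulate", "exposure", "trends", "hotspots", "severity")


def run_pipeline(config: RunConfig, out_dir, resume: bool = True
                 ) -> RunManifest:
    """Execute simulate -> exposure -> trends -> hotspots -> severity.

    Each stage writes its outputs under ``out_dir`` and appends a record
    (output paths + content hashes, timestamp) to ``manifest.json`` as a
    resumable checkpoint.  With ``resume``, completed stages whose recorded
    output hashes still match on disk are skipped; a hash mismatch raises
    instead of silently rebuilding on corrupted intermediates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = RunManifest(config_hash=config.hash())
    if resume and manifest_path.exists():
        prev = RunManifest.load(manifest_path)
        if prev.config_hash == config.hash():
            for stage, rec in prev.stages.items():
                if not rec.get("ok"):
                    continue
                for rel, digest in rec["outputs"].items():
                    f = out / rel
                    if not f.exists() or _file_hash(f) != digest:
                        raise InvalidArgumentError(
                            f"stage {stage!r} output {rel} is missing or "
                            "corrupted; refusing to resume — run fresh")
                manifest.stages[stage] = rec

    seeds = {s: int(np.random.SeedSequence(config.seed).generate_state(
        len(STAGES))[i] % (2**31 - 1)) for i, s in enumerate(STAGES)}
    state: dict = {}

    def record(stage: str, outputs: list[Path]) -> None:
        manifest.stages[stage] = {
            "outputs": {str(p.relative_to(out)): _file_hash(p)
                        for p in outputs},
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "ok": True,
        }
        manifest.save(manifest_path)

    # --- simulate -----------------------------------------------------
    zones_p = out / "zones.geojson"
    network_p = out / "network.geojson"
    surveys_p = out / "surveys.csv"
    collisions_p = out / "collisions.csv"
    truth_p = out / "ground_truth.json"
    if "simulate" not in manifest.completed_stages:
        zones, network = generate_city(config.n_zones, config.window,
                                       seed=seeds["simulate"])
        trend = GrowthTrend(**config.trend) if config.trend else \
            GrowthTrend()
        surveys, truth = generate_surveys(
            zones, config.survey_years, trend, seed=seeds["simulate"],
            n_sample_persons=config.n_sample_persons,
            n_sample_trips=config.n_sample_trips)
        cache: dict = {}
        centers = place_hotspot_centers(zones, network, truth.true_trips,
                                        seed=seeds["simulate"],
                                        path_cache=cache)
        risk = default_risk(zones.window, hotspot_centers=centers)
        collisions = generate_collisions(
            zones, network, truth.true_trips, risk, config.period,
            seed=seeds["simulate"], n_events=config.n_events,
            population_truth=truth.true_population, path_cache=cache)
        write_zones_geojson(zones, zones_p)
        write_network_geojson(network, network_p)
        pd.concat(surveys, ignore_index=True).to_csv(surveys_p, index=False)
        coll_out = collisions.copy()
        coll_out["datetime"] = coll_out["datetime"].dt.strftime(
            "%Y-%m-%dT%H:%M:%S")
        coll_out.to_csv(collisions_p, index=False)
        truth_p.write_text(json.dumps({
            "seed": int(truth.seed),
            "hotspot_centers": [list(c) for c in risk.hotspot_centers],
            "intercept": risk.intercept,
            "linear_log_odds": risk.linear,
            "true_population_total": {
                str(y): float(truth.true_population.query("year == @y")
                              ["population"].sum())
                for y in config.survey_years},
        }, indent=2))
        state["truth_trips"] = truth.true_trips
        record("simulate", [zones_p, network_p, surveys_p, collisions_p,
                            truth_p])

    zones = read_zones_geojson(zones_p)
    network = read_network_geojson(network_p)
    collisions, _ = read_collisions(collisions_p)
    surveys_all = pd.read_csv(surveys_p, keep_default_na=False)

    # --- exposure -----------------------------------------------------
    exposure_p = out / "exposure.csv"
    if "exposure" not in manifest.completed_stages:
        from . import exposure as expo

        surveys = [g for _, g in surveys_all.groupby("year")]
        pop = expo.estimate_population(surveys, zone_ids=zones.zone_ids)
        years = list(range(config.period[0], config.period[1] + 1))
        pop_full = expo.interpolate_panel(pop, years)
        trips = surveys_all[surveys_all["kind"] == "trip"]
        vkmt = expo.estimate_vkmt(trips, network, zones)
        vkmt_full = expo.interpolate_panel(vkmt, years)
        # split zone-year VKmT across strata by population share
        zy = (pop_full.groupby(["zone_id", "year"])["population"]
              .transform("sum"))
        share = np.where(zy > 0, pop_full["population"] / zy, 0.0)
        panel = pop_full.merge(
            vkmt_full.rename(columns={"provenance": "vkmt_provenance"}),
            on=["zone_id", "year"], how="left")
        panel["daily_vkmt"] = panel["daily_vkmt"].fillna(0.0) * share
        panel = panel.drop(columns=["vkmt_provenance"])
        panel.to_csv(exposure_p, index=False)
        record("exposure", [exposure_p])
    panel = pd.read_csv(exposure_p)

    # --- trends -------------------------------------------------------
    rates_p = out / "trends_rates.csv"
    summary_p = out / "trends_summary.csv"
    smr_p = out / "smr.csv"
    if "trends" not in manifest.completed_stages:
        from . import trends as tr

        frames = [tr.monthly_rates(collisions, panel, kind,
                                   period=config.period)
                  for kind in ("population", "vkmt")]
        rates = pd.concat(frames, ignore_index=True)
        rates.to_csv(rates_p, index=False)
        tr.yearly_summary(rates).to_csv(summary_p, index=False)
        tr.smr(collisions, panel, period=config.period).to_csv(
            smr_p, index=False)
        record("trends", [rates_p, summary_p, smr_p])

    # --- hotspots -----------------------------------------------------
    quad_p = out / "hotspot_quadrats.csv"
    flag_p = out / "hotspot_flagged.csv"
    kfun_p = out / "kfunction.csv"
    surf_p = out / "kde_surface.csv"
    if "hotspots" not in manifest.completed_stages:
        from . import hotspots as hs

        fatal = collisions[collisions["fatal"] == 1]
        minx, miny, maxx, maxy = zones.window.bounds
        window = (minx, miny, maxx, maxy)
        result = hs.detect_hotspots(
            fatal[["x", "y"]].to_numpy(), window,
            mass=config.hotspot.get("mass", 0.95),
            top_fraction=config.hotspot.get("top_fraction", 0.05),
            sigma=config.hotspot.get("sigma"),
            side=config.hotspot.get("side"))
        radii = np.linspace(0, min(maxx - minx, maxy - miny) / 4, 25)[1:]
        hs.ripleys_k(result.pattern, radii).to_csv(kfun_p, index=False)
        surf = pd.DataFrame(result.surface.values)
        surf.to_csv(surf_p, index=False)
        result.grid.quadrats.to_csv(quad_p, index=False)
        result.flagged.to_csv(flag_p, index=False)
        record("hotspots", [quad_p, flag_p, kfun_p, surf_p])

    # --- severity -----------------------------------------------------
    coef_p = out / "severity_coefficients.csv"
    smooth_p = out / "severity_smooths.csv"
    resd_p = out / "severity_random_sd.csv"
    if "severity" not in manifest.completed_stages:
        from . import severity as sev

        data = collisions.copy()
        data["year"] = pd.to_datetime(data["datetime"]).dt.year
        spec = sev.ModelSpec(
            linear_terms={"vehicle_type": "automobile", "sex": "F",
                          "weekday": "Sunday"},
            smooth_terms=[sev.SmoothSpec("slope_pct", k=8),
                          sev.SmoothSpec("time_of_day", k=8, cyclic=True)],
            spatial_smooth=None,
            random_intercepts=["zone_id"])
        balance = config.severity.get("balance")
        if balance:
            frac = data["fatal"].mean()
            if frac < balance:
                data = sev.oversample(data, balance,
                                      seed=seeds["severity"])
        fit = sev.fit_gamm(data, spec)
        fit.coefficients.to_csv(coef_p, index=False)
        pd.concat([df.assign(term=name)
                   for name, df in fit.smooths.items()],
                  ignore_index=True).to_csv(smooth_p, index=False)
        pd.DataFrame(list(fit.random_sd.items()),
                     columns=["group", "sd"]).to_csv(resd_p, index=False)
        record("severity", [coef_p, smooth_p, resd_p])

    return manifest
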
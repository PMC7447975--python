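"""Exposure-denominator estimation from weighted travel surveys.

Two denominators are produced per zone, year and stratum: the bicyclist
population (Horvitz-Thompson expansion of weighted person records) and the
daily bicycle kilometres travelled (VKmT: weighted origin-destination trips
routed over the road network by shortest path, with each path split at zone
boundaries so that every kilometre is attributed to the zone containing it).
Years between surveys are filled by stratified linear interpolation, years
after the last survey by linear extrapolation from the last two surveys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

from .errors import (CoverageError, InsufficientDataError,
                     InvalidArgumentError, NoPathError, SchemaError)
from .synthetic_city import RoadNetwork, ZoneMap

STRATA_DEFAULT = ("sex", "age_group")


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def estimate_population(surveys: list[pd.DataFrame],
                        strata: tuple[str, ...] = STRATA_DEFAULT,
                        zone_ids: list[str] | None = None) -> pd.DataFrame:
    """Weighted bicyclist counts per zone-year-stratum (observed years only).

    Every (zone, observed year, stratum) cell is present, zero where no
    bicyclist record fell in it.  Returns columns zone_id, year, *strata,
    population, provenance='observed'.
    """
    if not surveys:
        raise InvalidArgumentError("surveys must be non-empty")
    frames = []
    for s in surveys:
        if "weight" not in s.columns:
            raise SchemaError("survey table lacks a 'weight' column")
        persons = s[(s["kind"] == "person")].copy()
        if persons["weight"].isna().any():
            raise SchemaError("person records with missing weights")
        if (persons["weight"] < 0).any() or \
                not np.isfinite(persons["weight"]).all():
            raise SchemaError("weights must be finite and non-negative")
        frames.append(persons)
    persons = pd.concat(frames, ignore_index=True)
    bik = persons[persons["is_bicyclist"] == 1]
    keys = ["home_zone", "year", *strata]
    agg = (bik.groupby(keys, observed=True)["weight"].sum()
           .rename("population").reset_index()
           .rename(columns={"home_zone": "zone_id"}))

    years = sorted(persons["year"].unique())
    zones = zone_ids if zone_ids is not None \
        else sorted(persons["home_zone"].unique())
    levels = [zones, years] + [sorted(persons[c].dropna().unique())
                               for c in strata]
    full = pd.MultiIndex.from_product(
        levels, names=["zone_id", "year", *strata]).to_frame(index=False)
    out = full.merge(agg, how="left").fillna({"population": 0.0})
    out["provenance"] = "observed"
    return out


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

@dataclass
class Path:
    """A shortest path: ordered node ids, coordinates, and length in km."""

    nodes: list
    coords: np.ndarray          # (k, 2) metres
    length_km: float

    @property
    def geometry(self) -> LineString | Point:
        if len(self.nodes) == 1:
            return Point(self.coords[0])
        return LineString(self.coords)

    def point_at(self, dist_km: float):
        """Coordinates at arc length ``dist_km`` plus the bounding edge's
        node pair (for edge-attribute lookup)."""
        if len(self.nodes) == 1:
            x, y = self.coords[0]
            return float(x), float(y), self.nodes[0], self.nodes[0]
        seg = np.diff(self.coords, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1]) / 1000.0
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        d = min(max(dist_km, 0.0), cum[-1])
        i = int(np.searchsorted(cum, d, side="right") - 1)
        i = min(i, len(seg_len) - 1)
        t = 0.0 if seg_len[i] == 0 else (d - cum[i]) / seg_len[i]
        x, y = self.coords[i] + t * seg[i]
        return float(x), float(y), self.nodes[i], self.nodes[i + 1]


def _lex_shortest(graph: nx.Graph, src, dst) -> list:
    """Lexicographically smallest node sequence among shortest paths."""
    try:
        d_src = nx.single_source_dijkstra_path_length(graph, src,
                                                      weight="length")
        d_dst = nx.single_source_dijkstra_path_length(graph, dst,
                                                      weight="length")
    except nx.NetworkXNoPath:  # pragma: no cover
        raise NoPathError(f"no path between {src} and {dst}")
    if dst not in d_src:
        raise NoPathError(f"no path between {src} and {dst}")
    total = d_src[dst]
    tol = 1e-9 * max(1.0, total)
    path = [src]
    u = src
    while u != dst:
        candidates = []
        for v in graph.neighbors(u):
            if v not in d_dst:
                continue
            length = graph.edges[u, v]["length"]
            if abs(d_src[u] + length + d_dst[v] - total) <= tol:
                candidates.append(v)
        if not candidates:  # pragma: no cover - numerical safety
            raise NoPathError(f"path reconstruction failed at {u}")
        u = min(candidates)
        path.append(u)
    return path


def shortest_path(network: RoadNetwork, zones: ZoneMap,
                  origin_zone: str, dest_zone: str) -> Path:
    """Shortest path by edge length between zone centroids snapped to their
    nearest network nodes.  Ties break to the lexicographically smallest node
    sequence; origin == destination gives a zero-length single-node path."""
    g = network.graph
    oc = zones.centroid(origin_zone)
    dc = zones.centroid(dest_zone)
    src = network.nearest_node(oc.x, oc.y)
    dst = network.nearest_node(dc.x, dc.y)
    if src == dst:
        xy = np.array([[g.nodes[src]["x"], g.nodes[src]["y"]]])
        return Path(nodes=[src], coords=xy, length_km=0.0)
    nodes = _lex_shortest(g, src, dst)
    coords = np.array([[g.nodes[n]["x"], g.nodes[n]["y"]] for n in nodes])
    length = sum(g.edges[a, b]["length"] for a, b in zip(nodes, nodes[1:]))
    return Path(nodes=nodes, coords=coords, length_km=length / 1000.0)


# ---------------------------------------------------------------------------
# VKmT allocation
# ---------------------------------------------------------------------------

@dataclass
class PathAllocation:
    origin_zone: str
    dest_zone: str
    n_trips: float
    total_length_km: float
    segments: list[tuple[str, float]]  # (zone_id, in-zone length km)

    @property
    def vkmt(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for zid, km in self.segments:
            out[zid] = out.get(zid, 0.0) + km * self.n_trips
        return out


def allocate_vkmt(path: Path, n_trips: float, zones: ZoneMap,
                  origin_zone: str = "", dest_zone: str = "",
                  coverage_tol: float = 1e-6) -> PathAllocation:
    """Split a path at zone boundaries and allocate VKmT per zone.

    Zones are visited in lexicographic zone_id order and each claims the part
    of the line not already claimed, so shared-boundary overlaps go to the
    smaller zone_id and the in-zone lengths partition the path exactly.
    Raises :class:`CoverageError` (with the orphan length) if part of the
    path lies outside every zone.
    """
    if path.length_km == 0.0:
        zid = origin_zone
        if not zid:
            pt = Point(path.coords[0])
            for z in sorted(zones.zones, key=lambda z: z.zone_id):
                if z.polygon.intersects(pt):
                    zid = z.zone_id
                    break
        return PathAllocation(origin_zone, dest_zone, n_trips, 0.0,
                              [(zid, 0.0)] if zid else [])
    line = path.geometry
    tree = STRtree([z.polygon for z in zones.zones])
    cand = sorted(int(i) for i in tree.query(line))
    segments: list[tuple[str, float]] = []
    remaining = line
    for i in cand:
        z = zones.zones[i]
        if remaining.is_empty:
            break
        part = remaining.intersection(z.polygon)
        if part.length > 0:
            segments.append((z.zone_id, part.length / 1000.0))
            remaining = remaining.difference(z.polygon)
    orphan = 0.0 if remaining.is_empty else remaining.length / 1000.0
    if orphan > coverage_tol * max(path.length_km, 1.0):
        raise CoverageError(
            f"path leaves the zone cover; orphan length {orphan:.6f} km",
            orphan_km=orphan)
    total = sum(km for _, km in segments)
    if total > 0:  # absorb float slack so the partition is exact
        scale = path.length_km / total
        segments = [(zid, km * scale) for zid, km in segments]
    segments.sort(key=lambda t: t[0])
    return PathAllocation(origin_zone, dest_zone, float(n_trips),
                          path.length_km, segments)


def estimate_vkmt(trip_records: pd.DataFrame, network: RoadNetwork,
                  zones: ZoneMap) -> pd.DataFrame:
    """Weighted daily VKmT per zone and year from trip records.

    ``trip_records`` needs columns origin_zone, dest_zone, year, weight; the
    weight expands to trips/day.  OD pairs are routed once and reused across
    years.  Returns columns zone_id, year, daily_vkmt (all zones present).
    """
    req = {"origin_zone", "dest_zone", "year", "weight"}
    if not req.issubset(trip_records.columns):
        raise SchemaError(f"trip records need columns {sorted(req)}")
    od = (trip_records.groupby(["origin_zone", "dest_zone", "year"],
                               observed=True)["weight"].sum().reset_index())
    cache: dict[tuple[str, str], PathAllocation] = {}
    rows: dict[tuple[str, int], float] = {}
    for o, d, year, w in od.itertuples(index=False):
        key = (o, d)
        if key not in cache:
            p = shortest_path(network, zones, o, d)
            cache[key] = allocate_vkmt(p, 1.0, zones, o, d)
        for zid, km in cache[key].segments:
            rows[(zid, int(year))] = rows.get((zid, int(year)), 0.0) + km * w
    years = sorted(od["year"].astype(int).unique())
    out = pd.DataFrame(
        [(z, y, rows.get((z, y), 0.0))
         for z in zones.zone_ids for y in years],
        columns=["zone_id", "year", "daily_vkmt"])
    return out


# ---------------------------------------------------------------------------
# Interpolation and validation
# ---------------------------------------------------------------------------

def interpolate_panel(panel: pd.DataFrame, target_years: list[int],
                      value_cols: tuple[str, ...] | None = None
                      ) -> pd.DataFrame:
    """Fill a panel at ``target_years`` by stratified linear interpolation.

    Within each stratum series (all key columns except ``year`` and the value
    columns), values at years between two observed years are linear in year;
    years beyond the observed range are extrapolated linearly from the two
    nearest observed years and clipped at 0.  Observed cells pass through
    unchanged; ``provenance`` records observed/interpolated/extrapolated.
    """
    if value_cols is None:
        value_cols = tuple(c for c in ("population", "daily_vkmt")
                           if c in panel.columns)
    if not value_cols:
        raise SchemaError("panel has no value columns to interpolate")
    keys = [c for c in panel.columns
            if c not in (*value_cols, "year", "provenance")]
    target_years = sorted(int(y) for y in target_years)
    out_frames = []
    for key_vals, grp in panel.groupby(keys, observed=True, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        grp = grp.sort_values("year")
        obs_years = grp["year"].to_numpy(dtype=float)
        if len(obs_years) < 2:
            raise InsufficientDataError(
                f"stratum {key_vals} has {len(obs_years)} observed year(s); "
                "need >= 2")
        rows = {"year": target_years}
        prov = []
        for y in target_years:
            if y in obs_years:
                prov.append("observed")
            elif obs_years[0] < y < obs_years[-1]:
                prov.append("interpolated")
            else:
                prov.append("extrapolated")
        for col in value_cols:
            vals = grp[col].to_numpy(dtype=float)
            est = np.empty(len(target_years))
            for i, y in enumerate(target_years):
                if obs_years[0] <= y <= obs_years[-1]:
                    est[i] = np.interp(y, obs_years, vals)
                elif y > obs_years[-1]:
                    x0, x1 = obs_years[-2], obs_years[-1]
                    v0, v1 = vals[-2], vals[-1]
                    est[i] = v1 + (v1 - v0) * (y - x1) / (x1 - x0)
                else:
                    x0, x1 = obs_years[0], obs_years[1]
                    v0, v1 = vals[0], vals[1]
                    est[i] = v0 + (v1 - v0) * (y - x0) / (x1 - x0)
            rows[col] = np.maximum(est, 0.0)
        df = pd.DataFrame(rows)
        for k, v in zip(keys, key_vals):
            df[k] = v
        df["provenance"] = prov
        out_frames.append(df)
    out = pd.concat(out_frames, ignore_index=True)
    return out[[*keys, "year", *value_cols, "provenance"]]


@dataclass
class ValidationResult:
    total_pct_error: float
    mean_stratified_pct_error: float
    n_groups: int
    n_excluded: int  # groups with zero actual value, excluded from the mean


def validation_error(actual: pd.DataFrame, estimated: pd.DataFrame,
                     value_col: str | None = None) -> ValidationResult:
    """Percent errors of an estimated panel against an actual panel.

    Total error is ``100 * |sum(actual) - sum(estimated)| / sum(actual)``;
    the stratified error is the unweighted mean of per-group absolute percent
    errors, with zero-actual groups excluded (and counted).
    """
    if value_col is None:
        common = [c for c in ("daily_vkmt", "population")
                  if c in actual.columns and c in estimated.columns]
        if not common:
            raise SchemaError("no common value column between panels")
        value_col = common[0]
    keys = [c for c in actual.columns
            if c != value_col and c in estimated.columns
            and c != "provenance"]
    merged = actual.merge(estimated, on=keys, how="outer",
                          suffixes=("_act", "_est")).fillna(0.0)
    a = merged[f"{value_col}_act"].to_numpy(dtype=float)
    e = merged[f"{value_col}_est"].to_numpy(dtype=float)
    if a.sum() == 0:
        raise InvalidArgumentError("actual total is zero: error undefined")
    total = 100.0 * abs(a.sum() - e.sum()) / a.sum()
    nz = a != 0
    per_group = 100.0 * np.abs(a[nz] - e[nz]) / a[nz]
    return ValidationResult(
        total_pct_error=float(total),
        mean_stratified_pct_error=float(per_group.mean()) if nz.any()
        else float("nan"),
        n_groups=int(nz.sum()),
        n_excluded=int((~nz).sum()),
    )
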
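"""Synthetic city generator with stored ground truth.

Builds a planar city — a tessellation of planning zones, a jittered lattice
road network, weighted household travel surveys at irregular years, and a
collision point process with a low fatality fraction — so that every
downstream stage (exposure estimation, rate trends, hotspot detection,
severity modelling) can be validated against known truth.

All randomness flows from the integer ``seed`` passed to each generator;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy.special import expit, logit
from shapely.geometry import LineString, MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from .errors import InvalidArgumentError

#: Quinquennial age groups for commuting bicyclists (the under-5 group is
#: excluded from analysis by the ingest rules, so it is never generated).
AGE_GROUPS: tuple[str, ...] = tuple(
    f"{lo:02d}-{lo + 4:02d}" for lo in range(5, 80, 5)
)

#: Relative frequency of each age group among bicyclists — a unimodal
#: commuter profile peaking at 25-34.
_AGE_PROFILE = np.array(
    [0.02, 0.04, 0.08, 0.11, 0.13, 0.13, 0.12, 0.10, 0.08, 0.07,
     0.05, 0.03, 0.02, 0.01, 0.01]
)
_AGE_PROFILE = _AGE_PROFILE / _AGE_PROFILE.sum()

#: Male share of the bicyclist population (cycling in the emulated setting
#: is strongly male-dominated).
MALE_SHARE = 0.78

SURVEY_YEARS_DEFAULT = (2005, 2011, 2014, 2015, 2017)

VEHICLE_TYPES = ("automobile", "motorcycle", "bus", "cargo", "brt", "other")
_VEHICLE_PROBS = np.array([0.38, 0.28, 0.14, 0.08, 0.02, 0.10])

WEEKDAYS = ("Sunday", "Monday", "Tuesday", "Wednesday", "Thursday",
            "Friday", "Saturday")


def age_to_group(age) -> str | np.ndarray:
    """Map age in years to its quinquennial group label (clamped to 5-79)."""
    a = np.clip(np.asarray(age, dtype=float), 5, 79)
    lo = (np.floor(a / 5).astype(int)) * 5
    labels = np.array(AGE_GROUPS)
    out = labels[(lo - 5) // 5]
    return out if out.ndim else out.item()


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Zone:
    zone_id: str
    polygon: Polygon
    income_stratum: str  # {"low", "middle", "high"}


@dataclass
class ZoneMap:
    """Tessellation of planning zones covering a rectangular study window."""

    zones: list[Zone]
    window: Polygon

    @property
    def zone_ids(self) -> list[str]:
        return [z.zone_id for z in self.zones]

    def polygon(self, zone_id: str) -> Polygon:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z.polygon
        raise KeyError(zone_id)

    def centroid(self, zone_id: str) -> Point:
        return self.polygon(zone_id).centroid

    def validate(self, tol: float = 1e-6) -> None:
        ids = self.zone_ids
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("zone_ids are not unique")
        area = sum(z.polygon.area for z in self.zones)
        if abs(area - self.window.area) > tol * self.window.area:
            raise InvalidArgumentError(
                f"zones do not tile the window: {area} vs {self.window.area}"
            )
        for z in self.zones:
            if not z.polygon.is_valid:
                raise InvalidArgumentError(f"invalid polygon for {z.zone_id}")


@dataclass
class RoadNetwork:
    """Undirected planar road graph; node attrs x/y (m), edge attr length (m)
    plus geometry inputs for traffic-stress rating."""

    graph: nx.Graph

    def node_xy(self) -> tuple[np.ndarray, np.ndarray, list]:
        nodes = list(self.graph.nodes)
        xs = np.array([self.graph.nodes[n]["x"] for n in nodes])
        ys = np.array([self.graph.nodes[n]["y"] for n in nodes])
        return xs, ys, nodes

    def nearest_node(self, x: float, y: float):
        xs, ys, nodes = self.node_xy()
        i = int(np.argmin((xs - x) ** 2 + (ys - y) ** 2))
        return nodes[i]


@dataclass
class GrowthTrend:
    """Bicyclist-population trajectory over the survey horizon.

    ``kind='factor'`` grows log-linearly from ``base_total`` at ``base_year``
    by ``factor`` over [base_year, end_year]; ``kind='constant'`` keeps
    ``base_total`` at every year.  The default triples the population between
    2011 and 2017, the growth the study period saw.
    """

    kind: str = "factor"
    base_year: int = 2011
    base_total: float = 10_000.0
    factor: float = 3.0
    end_year: int = 2017

    def total(self, year: int) -> float:
        if self.kind == "constant":
            return self.base_total
        span = self.end_year - self.base_year
        return self.base_total * self.factor ** ((year - self.base_year) / span)


@dataclass
class RiskModel:
    """Generative fatality-risk model: logit(p_fatal) = intercept + linear
    effects + smooth effects + log hotspot multiplier.

    ``linear`` keys are ``"column:level"`` for categoricals (e.g.
    ``"vehicle_type:cargo"``) or plain column names for 0/1 flags.
    ``smooth`` maps a continuous column to a callable contribution in
    log-odds.  ``hotspot_centers`` are (x, y, radius_m, odds_multiplier).
    """

    intercept: float = float(logit(358 / 9950))
    linear: dict[str, float] = field(default_factory=dict)
    smooth: dict[str, Callable[[np.ndarray], np.ndarray]] = field(
        default_factory=dict)
    hotspot_centers: list[tuple[float, float, float, float]] = field(
        default_factory=list)
    #: when set, the intercept is shifted so the realized marginal fatality
    #: fraction matches this target despite the planted effects (the planted
    #: slopes are untouched; with all effects null the shift is ~0).
    target_marginal: float | None = None

    def validate(self) -> None:
        marginal = float(expit(self.intercept))
        if not (0.0 < marginal < 0.2):
            raise InvalidArgumentError(
                f"intercept implies marginal fatality fraction {marginal:.3f} "
                "outside (0, 0.2)"
            )


@dataclass
class GroundTruth:
    """Everything the generators planted, for downstream validation."""

    true_population: pd.DataFrame  # zone_id, year, sex, age_group, population
    true_trips: pd.DataFrame       # origin_zone, dest_zone, year, trips_per_day
    true_vkmt: pd.DataFrame | None  # zone_id, year, daily_vkmt
    risk: RiskModel | None
    seed: int

    def population_by_zone_year(self) -> pd.DataFrame:
        return (self.true_population
                .groupby(["zone_id", "year"], as_index=False)["population"]
                .sum())


# ---------------------------------------------------------------------------
# City geometry
# ---------------------------------------------------------------------------

def generate_city(
    n_zones: int,
    window: tuple[float, float],
    seed: int,
    tessellation: str = "voronoi",
    network_spacing: float | None = None,
) -> tuple[ZoneMap, RoadNetwork]:
    """Generate a zone tessellation and a jittered-lattice road network.

    Parameters
    ----------
    n_zones : number of planning zones (>= 4).
    window : (width_m, height_m) of the rectangular study window.
    seed : RNG seed; identical seeds give identical cities.
    tessellation : 'voronoi' (irregular cells around uniform seed points,
        the default) or 'grid'.
    network_spacing : lattice spacing in metres; defaults to a spacing that
        puts roughly one node per zone plus a margin.
    """
    w, h = float(window[0]), float(window[1])
    if n_zones < 4:
        raise InvalidArgumentError("n_zones must be >= 4")
    if w <= 0 or h <= 0:
        raise InvalidArgumentError("window must have positive area")
    rng = np.random.default_rng(seed)
    win = box(0.0, 0.0, w, h)

    if tessellation == "voronoi":
        pts = np.column_stack([rng.uniform(0, w, n_zones),
                               rng.uniform(0, h, n_zones)])
        cells = voronoi_diagram(MultiPoint(pts.tolist()), envelope=win)
        polys: list[Polygon | None] = [None] * n_zones
        tree = STRtree(list(cells.geoms))
        for i, (px, py) in enumerate(pts):
            p = Point(px, py)
            for j in tree.query(p):
                if cells.geoms[int(j)].intersects(p):
                    polys[i] = cells.geoms[int(j)].intersection(win)
                    break
        if any(p is None or p.is_empty for p in polys):
            raise InvalidArgumentError("degenerate Voronoi tessellation")
    elif tessellation == "grid":
        nx_cells = max(d for d in range(1, int(math.isqrt(n_zones)) + 1)
                       if n_zones % d == 0)
        ny_cells = n_zones // nx_cells
        dx, dy = w / ny_cells, h / nx_cells
        polys = [box(i * dx, j * dy, (i + 1) * dx, (j + 1) * dy)
                 for j in range(nx_cells) for i in range(ny_cells)]
    else:
        raise InvalidArgumentError(f"unknown tessellation {tessellation!r}")

    strata = rng.choice(["low", "middle", "high"], size=n_zones,
                        p=[0.45, 0.40, 0.15])
    width = max(3, len(str(n_zones)))
    zones = [Zone(f"Z{i:0{width}d}", poly, s)
             for i, (poly, s) in enumerate(zip(polys, strata))]
    zone_map = ZoneMap(zones=zones, window=win)

    # Jittered lattice network: jitter < spacing/2 keeps the planar layout
    # and makes edge lengths generically unique (no shortest-path ties).
    if network_spacing is None:
        network_spacing = min(w, h) / (math.ceil(math.sqrt(n_zones)) + 1)
    nxn = max(2, int(round(w / network_spacing)) + 1)
    nyn = max(2, int(round(h / network_spacing)) + 1)
    gx = np.linspace(0, w, nxn)
    gy = np.linspace(0, h, nyn)
    jx = rng.uniform(-0.2, 0.2, (nyn, nxn)) * (w / (nxn - 1))
    jy = rng.uniform(-0.2, 0.2, (nyn, nxn)) * (h / (nyn - 1))
    g = nx.Graph()
    node_id = {}
    for j in range(nyn):
        for i in range(nxn):
            nid = f"N{j * nxn + i:05d}"
            node_id[(i, j)] = nid
            x = float(np.clip(gx[i] + jx[j, i], 0, w))
            y = float(np.clip(gy[j] + jy[j, i], 0, h))
            g.add_node(nid, x=x, y=y)
    eid = 0
    for j in range(nyn):
        for i in range(nxn):
            for (i2, j2) in ((i + 1, j), (i, j + 1)):
                if i2 < nxn and j2 < nyn:
                    a, b = node_id[(i, j)], node_id[(i2, j2)]
                    dx = g.nodes[a]["x"] - g.nodes[b]["x"]
                    dy = g.nodes[a]["y"] - g.nodes[b]["y"]
                    g.add_edge(
                        a, b,
                        edge_id=f"E{eid:05d}",
                        length=float(math.hypot(dx, dy)),
                        lanes=int(rng.integers(1, 5)),
                        lane_width=float(rng.uniform(2.7, 3.6)),
                        speed_limit=float(rng.choice([30, 40, 50, 60])),
                        has_bike_path=bool(rng.random() < 0.25),
                        has_transit_route=bool(rng.random() < 0.30),
                    )
                    eid += 1
    return zone_map, RoadNetwork(graph=g)


# ---------------------------------------------------------------------------
# Surveys
# ---------------------------------------------------------------------------

def _true_population(zones: ZoneMap, years: Sequence[int],
                     trend: GrowthTrend, rng: np.random.Generator
                     ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Expected bicyclist counts per zone-year-stratum plus the fixed zone
    residence shares and destination attraction shares."""
    n = len(zones.zones)
    # heavy-tailed zone shares: residence and especially trip attraction
    # concentrate in a few zones, as in real cities
    home_share = rng.dirichlet(np.full(n, 1.0))
    attraction = rng.dirichlet(np.full(n, 0.6))
    rows = []
    for year in years:
        total = trend.total(year)
        for zid, share in zip(zones.zone_ids, home_share):
            for sex, psex in (("M", MALE_SHARE), ("F", 1 - MALE_SHARE)):
                for grp, page in zip(AGE_GROUPS, _AGE_PROFILE):
                    rows.append((zid, year, sex, grp,
                                 total * share * psex * page))
    pop = pd.DataFrame(rows, columns=["zone_id", "year", "sex", "age_group",
                                      "population"])
    return pop, home_share, attraction


def generate_surveys(
    zones: ZoneMap,
    years: Sequence[int] = SURVEY_YEARS_DEFAULT,
    trend: GrowthTrend | None = None,
    seed: int = 0,
    n_sample_persons: int = 4000,
    n_sample_trips: int = 4000,
    trips_per_bicyclist: float = 2.0,
    non_bicyclist_fraction: float = 0.3,
) -> tuple[list[pd.DataFrame], GroundTruth]:
    """Generate weighted person and trip records for each survey year.

    Sampling is Poisson: each population unit enters the sample independently
    with probability pi = n_sample / N(year) and carries design weight 1/pi,
    so the Horvitz-Thompson expansion is unbiased for the planted totals with
    variance N/pi per total.

    Returns the list of survey tables (one per year, person and trip records
    stacked with a ``kind`` column) and a :class:`GroundTruth` holding the
    planted population and OD-trip truth (``true_vkmt`` is left None; it
    requires routing — see :func:`true_vkmt_panel`).
    """
    if len(years) == 0:
        raise InvalidArgumentError("years must be non-empty")
    years = list(years)
    if any(b <= a for a, b in zip(years, years[1:])):
        raise InvalidArgumentError("years must be strictly increasing")
    trend = trend or GrowthTrend()
    rng = np.random.default_rng(seed)

    pop, home_share, attraction = _true_population(zones, years, trend, rng)
    zone_ids = zones.zone_ids
    n_zones = len(zone_ids)

    trip_rows = []
    surveys = []
    for year in years:
        ydf = pop[pop["year"] == year]
        total = float(ydf["population"].sum())
        pi_p = min(1.0, n_sample_persons / total)
        cells = ydf.reset_index(drop=True)
        m = rng.poisson(cells["population"].to_numpy() * pi_p)
        rec = cells.loc[cells.index.repeat(m),
                        ["year", "zone_id", "sex", "age_group"]].copy()
        rec = rec.rename(columns={"zone_id": "home_zone"})
        rec["kind"] = "person"
        rec["weight"] = 1.0 / pi_p
        rec["is_bicyclist"] = 1
        rec["origin_zone"] = ""
        rec["dest_zone"] = ""
        # Non-bicyclist padding records: exercise the is_bicyclist filter.
        n_nb = rng.poisson(n_sample_persons * non_bicyclist_fraction)
        nb = pd.DataFrame({
            "year": year,
            "home_zone": rng.choice(zone_ids, n_nb),
            "sex": rng.choice(["M", "F"], n_nb),
            "age_group": rng.choice(AGE_GROUPS, n_nb),
            "kind": "person",
            "weight": 1.0 / pi_p,
            "is_bicyclist": 0,
            "origin_zone": "",
            "dest_zone": "",
        })

        # OD trip truth: trips/day from origin o to destination d.
        od = (trips_per_bicyclist * trend.total(year)
              * np.outer(home_share, attraction))
        for oi in range(n_zones):
            for di in range(n_zones):
                trip_rows.append((zone_ids[oi], zone_ids[di], year,
                                  float(od[oi, di])))
        t_total = float(od.sum())
        pi_t = min(1.0, n_sample_trips / t_total)
        mt = rng.poisson(od * pi_t)
        oi, di = np.nonzero(mt)
        counts = mt[oi, di]
        origin = np.repeat(np.array(zone_ids)[oi], counts)
        dest = np.repeat(np.array(zone_ids)[di], counts)
        n_t = len(origin)
        trips = pd.DataFrame({
            "year": year,
            "home_zone": origin,
            "sex": rng.choice(["M", "F"], n_t,
                              p=[MALE_SHARE, 1 - MALE_SHARE]),
            "age_group": rng.choice(AGE_GROUPS, n_t, p=_AGE_PROFILE),
            "kind": "trip",
            "weight": 1.0 / pi_t,
            "is_bicyclist": 1,
            "origin_zone": origin,
            "dest_zone": dest,
        })
        table = pd.concat([rec, nb, trips], ignore_index=True)
        surveys.append(table[["year", "kind", "weight", "sex", "age_group",
                              "home_zone", "origin_zone", "dest_zone",
                              "is_bicyclist"]])

    true_trips = pd.DataFrame(
        trip_rows, columns=["origin_zone", "dest_zone", "year",
                            "trips_per_day"])
    truth = GroundTruth(true_population=pop, true_trips=true_trips,
                        true_vkmt=None, risk=None, seed=seed)
    return surveys, truth


def true_vkmt_panel(zones: ZoneMap, network: RoadNetwork,
                    true_trips: pd.DataFrame) -> pd.DataFrame:
    """Route the planted OD trips and allocate km to zones: the VKmT truth."""
    from . import exposure  # local import: exposure does not import us

    return exposure.estimate_vkmt(
        true_trips.rename(columns={"trips_per_day": "weight"}),
        network, zones)


# ---------------------------------------------------------------------------
# Collisions
# ---------------------------------------------------------------------------

def _slope_field(x: np.ndarray, y: np.ndarray, window: Polygon) -> np.ndarray:
    """Terrain slope (%) as a smooth spatial field over the window.

    Mostly flat (as in a real street network) with a hilly quadrant: the
    resulting slope distribution is right-skewed, roughly 0.5-12%, with
    about a fifth of events above 3%.
    """
    minx, miny, maxx, maxy = window.bounds
    u = (x - minx) / (maxx - minx)
    v = (y - miny) / (maxy - miny)
    hill = np.exp(-(((u - 0.85) ** 2) + ((v - 0.85) ** 2)) / (2 * 0.22**2))
    ripple = 0.6 + 0.5 * np.sin(2 * np.pi * u) * np.cos(np.pi * v)
    return 0.5 + 11.0 * hill + ripple


def _sample_time_of_day(n: int, rng: np.random.Generator) -> np.ndarray:
    """Two-component circular day/night mixture on [0, 24)."""
    comp = rng.random(n) < 0.8
    t = np.where(comp,
                 rng.normal(14.0, 3.0, n),   # daytime commuting bulk
                 rng.normal(2.0, 2.0, n))    # night-time tail
    return np.mod(t, 24.0)


def place_hotspot_centers(
    zones: ZoneMap,
    network: RoadNetwork,
    trips: pd.DataFrame,
    n_centers: int = 3,
    radius: float | None = None,
    multiplier: float = 8.0,
    seed: int = 0,
    path_cache: dict | None = None,
) -> list[tuple[float, float, float, float]]:
    """Plant hotspot centers on the exposure field.

    High-risk locations are busy intersections and corridors, so centers are
    sampled from the same exposure-proportional point process that places
    collisions (an OD flow drawn with probability proportional to its VKmT,
    a point uniform along its shortest path), thinned to keep centers at
    least four radii apart.  A center placed where nobody rides would
    generate no fatalities and could never register in an area-based rate
    analysis.
    """
    from . import exposure as expo

    minx, miny, maxx, maxy = zones.window.bounds
    if radius is None:
        radius = 0.04 * ((maxx - minx) + (maxy - miny)) / 2
    rng = np.random.default_rng(seed)
    od = (trips.groupby(["origin_zone", "dest_zone"], as_index=False)
          ["trips_per_day"].mean())
    od = od[od["trips_per_day"] > 0].reset_index(drop=True)
    if path_cache is None:
        path_cache = {}
    paths, w_od = [], []
    for o, d, t in zip(od["origin_zone"], od["dest_zone"],
                       od["trips_per_day"]):
        if (o, d) not in path_cache:
            path_cache[(o, d)] = expo.shortest_path(network, zones, o, d)
        p = path_cache[(o, d)]
        paths.append(p)
        w_od.append(t * p.length_km)
    w_od = np.asarray(w_od)
    if w_od.sum() <= 0:
        raise InvalidArgumentError("zero total exposure")
    probs = w_od / w_od.sum()
    centers: list[tuple[float, float, float, float]] = []
    for _ in range(2000):
        if len(centers) == n_centers:
            break
        k = rng.choice(len(paths), p=probs)
        x, y, _, _ = paths[k].point_at(rng.random() * paths[k].length_km)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= (4 * radius) ** 2
               for cx, cy, _, _ in centers):
            centers.append((float(x), float(y), float(radius),
                            float(multiplier)))
    if len(centers) < n_centers:
        raise InvalidArgumentError("could not place separated hotspot "
                                   "centers; reduce n_centers or radius")
    return centers


def default_risk(window: Polygon | None = None,
                 hotspot_centers=None) -> RiskModel:
    """Default planted severity model mirroring the emulated study setting:
    heavier counterpart vehicles raise the fatality odds, motorcycles lower
    them, a slope effect kicks in above ~3%, and a night-time excess.
    Hotspot centers should come from :func:`place_hotspot_centers` so they
    sit on the exposure field."""
    centers = list(hotspot_centers) if hotspot_centers else []
    return RiskModel(
        intercept=float(logit(358 / 9950)),
        linear={"vehicle_type:cargo": 2.0, "vehicle_type:motorcycle": -0.8,
                "vehicle_type:bus": 1.0, "sex:M": 0.1},
        smooth={
            "slope_pct": lambda s: 0.25 * np.maximum(np.asarray(s) - 3.0, 0.0),
            "time_of_day": lambda t: 0.6 * np.cos(2 * np.pi
                                                  * (np.asarray(t) - 1.0) / 24),
        },
        hotspot_centers=centers,
        target_marginal=358 / 9950,
    )


def generate_collisions(
    zones: ZoneMap,
    network: RoadNetwork,
    exposure_truth: pd.DataFrame,
    risk: RiskModel,
    period: tuple[int, int] = (2011, 2017),
    seed: int = 0,
    n_events: int = 9950,
    placement: str = "exposure",
    jitter_m: float = 30.0,
    population_truth: pd.DataFrame | None = None,
    event_year_growth: float = 1.4,
    path_cache: dict | None = None,
) -> pd.DataFrame:
    """Generate the collision table.

    Events are placed with spatial intensity proportional to exposure:
    an origin-destination trip flow is drawn proportional to (trips x path
    length), i.e. to its VKmT share, and the event location is uniform along
    the flow's shortest path, then jittered by ``jitter_m`` to emulate
    geocoding noise.  ``placement='uniform'`` instead scatters events
    uniformly in the window (the calibration null for spatial tests).
    The fatal flag is Bernoulli with log-odds from ``risk``; hotspot centers
    multiply the fatality *odds* inside their radius.

    ``exposure_truth`` is the OD-trip truth table (origin_zone, dest_zone,
    year, trips_per_day) from :func:`generate_surveys`.  Yearly event counts
    grow geometrically by ``event_year_growth`` over the period (default
    1.4: collisions grow 40% while the default bicyclist population
    triples, so rates per bicyclist fall).
    """
    from . import exposure

    risk.validate()
    y0, y1 = int(period[0]), int(period[1])
    years = np.arange(y0, y1 + 1)
    rng = np.random.default_rng(seed)
    zone_ids = zones.zone_ids
    minx, miny, maxx, maxy = zones.window.bounds

    g = network.graph

    if placement == "exposure":
        od = (exposure_truth.groupby(["origin_zone", "dest_zone"],
                                     as_index=False)["trips_per_day"].mean())
        od = od[od["trips_per_day"] > 0].reset_index(drop=True)
        if len(od) == 0:
            raise InvalidArgumentError("zero total exposure")
        if path_cache is None:
            path_cache = {}
        paths, lengths = [], []
        for o, d in zip(od["origin_zone"], od["dest_zone"]):
            if (o, d) not in path_cache:
                path_cache[(o, d)] = exposure.shortest_path(network, zones,
                                                            o, d)
            p = path_cache[(o, d)]
            paths.append(p)
            lengths.append(p.length_km)
        lengths = np.asarray(lengths)
        w_od = od["trips_per_day"].to_numpy() * lengths
        keep = w_od > 0
        if not np.any(keep):
            raise InvalidArgumentError("zero total exposure")
        od_idx = np.flatnonzero(keep)
        probs = w_od[keep] / w_od[keep].sum()
        pick = rng.choice(od_idx, size=n_events, p=probs)
        frac = rng.random(n_events)
        xs = np.empty(n_events)
        ys = np.empty(n_events)
        edge_u = np.empty(n_events, dtype=object)
        edge_v = np.empty(n_events, dtype=object)
        for k in range(n_events):
            p = paths[pick[k]]
            xk, yk, u, v = p.point_at(frac[k] * p.length_km)
            xs[k], ys[k] = xk, yk
            edge_u[k], edge_v[k] = u, v
        xs = np.clip(xs + rng.normal(0, jitter_m, n_events), minx, maxx)
        ys = np.clip(ys + rng.normal(0, jitter_m, n_events), miny, maxy)
    elif placement == "uniform":
        xs = rng.uniform(minx, maxx, n_events)
        ys = rng.uniform(miny, maxy, n_events)
        edge_u = edge_v = None
    else:
        raise InvalidArgumentError(f"unknown placement {placement!r}")

    # Nearest edge attributes (uniform placement or after jitter the event
    # keeps the attributes of the sampled/nearest edge).
    if edge_u is None:
        edges = list(g.edges)
        segs = [LineString([(g.nodes[a]["x"], g.nodes[a]["y"]),
                            (g.nodes[b]["x"], g.nodes[b]["y"])])
                for a, b in edges]
        tree = STRtree(segs)
        pts = [Point(x, y) for x, y in zip(xs, ys)]
        idx = tree.nearest(pts)
        edge_u = np.array([edges[int(i)][0] for i in idx], dtype=object)
        edge_v = np.array([edges[int(i)][1] for i in idx], dtype=object)

    edge_attr = {k: np.empty(n_events) for k in
                 ("lanes", "lane_width", "speed_limit")}
    on_bike_path = np.empty(n_events, dtype=int)
    transit = np.empty(n_events, dtype=int)
    for k in range(n_events):
        e = g.edges[edge_u[k], edge_v[k]]
        edge_attr["lanes"][k] = e["lanes"]
        edge_attr["lane_width"][k] = e["lane_width"]
        edge_attr["speed_limit"][k] = e["speed_limit"]
        on_bike_path[k] = int(e["has_bike_path"])
        transit[k] = int(e["has_transit_route"])

    # Zone assignment; boundary ties go to the smaller zone_id.
    polys = [z.polygon for z in zones.zones]
    tree = STRtree(polys)
    pts = [Point(x, y) for x, y in zip(xs, ys)]
    zone_of = np.array([""] * n_events, dtype=object)
    qi, qj = tree.query(pts, predicate="intersects")
    for i, j in zip(qi, qj):
        zid = zone_ids[int(j)]
        if zone_of[int(i)] == "" or zid < zone_of[int(i)]:
            zone_of[int(i)] = zid
    missing = zone_of == ""
    if missing.any():  # numerically on the window edge: snap to nearest zone
        for i in np.flatnonzero(missing):
            zone_of[i] = zone_ids[int(tree.nearest(pts[i]))]

    # Timestamps: geometric year growth, uniform date within year,
    # circular day/night time.
    yw = event_year_growth ** ((years - y0) / max(y1 - y0, 1))
    year = rng.choice(years, n_events, p=yw / yw.sum())
    day_of_year = rng.integers(0, 365, n_events)
    tod = _sample_time_of_day(n_events, rng)
    base = pd.to_datetime({"year": year, "month": 1, "day": 1})
    dt = (base + pd.to_timedelta(day_of_year, unit="D")
          + pd.to_timedelta(np.round(tod * 3600).astype(int), unit="s"))
    weekday = dt.dt.day_name()

    # Individual covariates.
    sex = rng.choice(["M", "F"], n_events, p=[MALE_SHARE, 1 - MALE_SHARE])
    age = np.clip(rng.gamma(6.0, 5.5, n_events) + 5, 5, 79)
    vehicle = rng.choice(VEHICLE_TYPES, n_events, p=_VEHICLE_PROBS)
    slope = _slope_field(xs, ys, zones.window)

    # Zone-level context, fixed per zone for the whole period.
    zrng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    zctx = pd.DataFrame({
        "zone_id": zone_ids,
        "surface_failures": zrng.poisson(5.0, len(zone_ids)),
        "lighting_pct": zrng.uniform(40, 100, len(zone_ids)),
        "office_share": zrng.uniform(0.0, 0.5, len(zone_ids)),
    })
    zlut = zctx.set_index("zone_id")

    if population_truth is not None:
        popzy = (population_truth.groupby(["zone_id", "year"])["population"]
                 .sum())
        bpop = np.array([popzy.get((z, int(t)), np.nan)
                         for z, t in zip(zone_of, year)])
    else:
        bpop = np.full(n_events, np.nan)

    from .severity import DEFAULT_LTS_RULES, lts_rating
    lts = lts_rating(pd.DataFrame({
        "lanes": edge_attr["lanes"],
        "lane_width": edge_attr["lane_width"],
        "speed_limit": edge_attr["speed_limit"],
        "has_bike_path": on_bike_path.astype(bool),
        "has_transit_route": transit.astype(bool),
    }), DEFAULT_LTS_RULES)

    tbl = pd.DataFrame({
        "event_id": [f"C{k:06d}" for k in range(n_events)],
        "x": xs, "y": ys,
        "zone_id": zone_of.astype(str),
        "datetime": dt,
        "sex": sex,
        "age": age,
        "vehicle_type": vehicle,
        "weekday": weekday,
        "time_of_day": tod,
        "slope_pct": slope,
        "surface_failures": zlut.loc[zone_of, "surface_failures"].to_numpy(),
        "lighting_pct": zlut.loc[zone_of, "lighting_pct"].to_numpy(),
        "office_share": zlut.loc[zone_of, "office_share"].to_numpy(),
        "bicyclist_population": bpop,
        "on_bike_path": on_bike_path,
        "has_transit_route": transit,
        "lanes": edge_attr["lanes"].astype(int),
        "lane_width": edge_attr["lane_width"],
        "speed_limit": edge_attr["speed_limit"],
        "lts": lts,
    })
    tbl["lts4"] = (tbl["lts"] == 4).astype(int)

    eta = np.full(n_events, risk.intercept)
    for key, coef in risk.linear.items():
        if ":" in key:
            col, level = key.split(":", 1)
            eta += coef * (tbl[col].astype(str) == level).to_numpy()
        else:
            eta += coef * tbl[key].to_numpy(dtype=float)
    for col, fn in risk.smooth.items():
        eta += np.asarray(fn(tbl[col].to_numpy(dtype=float)), dtype=float)
    for cx, cy, radius, mult in risk.hotspot_centers:
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
        eta += np.log(mult) * inside
    if risk.target_marginal is not None:
        from scipy.optimize import brentq
        delta = brentq(
            lambda d: expit(eta + d).mean() - risk.target_marginal, -20, 20)
        eta = eta + delta
    tbl["fatal"] = rng.binomial(1, expit(eta))
    return tbl
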
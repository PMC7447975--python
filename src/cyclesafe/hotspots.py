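"""Spatial hotspot detection for fatal collisions.

The chain mirrors standard point-pattern practice: Ripley's K with a
Monte-Carlo envelope establishes whether fatal events cluster at all; a
Gaussian kernel density with leave-one-out likelihood bandwidth selection
estimates the risk surface; the 95% highest-density region of that surface
sets the quadrat size; a chi-square index-of-dispersion test on quadrat
counts confirms non-uniformity; and the quadrats in the top 5% of the
fatality rate per km^2 are flagged as high-risk areas.

All coordinates are planar metres; geographic input must be projected
before entering this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .errors import InsufficientDataError, InvalidArgumentError

import pandas as pd


# ---------------------------------------------------------------------------
# Point pattern
# ---------------------------------------------------------------------------

@dataclass
class PointPattern:
    """Planar point pattern on a rectangular observation window (metres)."""

    points: np.ndarray                      # (n, 2)
    window: tuple[float, float, float, float]  # (x0, y0, x1, y1)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        x0, y0, x1, y1 = self.window
        if x1 <= x0 or y1 <= y0:
            raise InvalidArgumentError("window must have positive area")
        if len(self.points) < 1:
            raise InvalidArgumentError("pattern needs at least one point")
        inside = ((self.points[:, 0] >= x0) & (self.points[:, 0] <= x1)
                  & (self.points[:, 1] >= y0) & (self.points[:, 1] <= y1))
        if not inside.all():
            raise InvalidArgumentError(
                f"{int((~inside).sum())} point(s) outside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)


# ---------------------------------------------------------------------------
# Ripley's K
# ---------------------------------------------------------------------------

def ripleys_k(pattern: PointPattern, radii,
              correction: str = "translation") -> pd.DataFrame:
    """Ripley's K function with CSR reference pi*r^2.

    K(r) = |W|^2 / (n (n-1)) * sum_{i != j} 1(d_ij <= r) / A_ij, where A_ij
    is the area of the window intersected with itself translated by the pair
    displacement (translation edge correction; A_ij = |W| when
    ``correction='none'``).  Monotone non-decreasing in r by construction.
    """
    if pattern.n < 2:
        raise InsufficientDataError("Ripley's K needs at least 2 points")
    radii = np.asarray(radii, dtype=float)
    x0, y0, x1, y1 = pattern.window
    w, h = x1 - x0, y1 - y0
    pts = pattern.points
    dx = np.abs(pts[:, 0, None] - pts[None, :, 0])
    dy = np.abs(pts[:, 1, None] - pts[None, :, 1])
    d = np.hypot(dx, dy)
    iu = ~np.eye(pattern.n, dtype=bool)
    if correction == "translation":
        a_ij = (w - dx) * (h - dy)
        if (a_ij[iu] <= 0).any():
            raise InvalidArgumentError(
                "pair displacement exceeds the window: radii too large for "
                "translation correction")
    elif correction == "none":
        a_ij = np.full_like(d, pattern.area)
    else:
        raise InvalidArgumentError(f"unknown correction {correction!r}")
    const = pattern.area**2 / (pattern.n * (pattern.n - 1))
    inv_a = np.where(iu, 1.0 / a_ij, 0.0)
    k = np.array([const * (inv_a * (d <= r) * iu).sum() / pattern.area
                  for r in radii])
    return pd.DataFrame({"r": radii, "k": k, "csr": np.pi * radii**2})


def csr_envelope(pattern: PointPattern, radii, n_sim: int = 199,
                 seed: int = 0, correction: str = "translation",
                 alpha: float = 0.05) -> pd.DataFrame:
    """Pointwise CSR envelope for Ripley's K from uniform simulations.

    Simulates ``n_sim`` uniform patterns with the same n and window, and
    returns the alpha/2 and 1-alpha/2 quantiles of K(r) per radius together
    with the observed K and a ``clustered`` flag (observed above the upper
    envelope).
    """
    if n_sim < 39:
        raise InvalidArgumentError("n_sim must be >= 39 for a usable "
                                   "envelope")
    rng = np.random.default_rng(seed)
    radii = np.asarray(radii, dtype=float)
    obs = ripleys_k(pattern, radii, correction)["k"].to_numpy()
    x0, y0, x1, y1 = pattern.window
    sims = np.empty((n_sim, len(radii)))
    for s in range(n_sim):
        pts = np.column_stack([rng.uniform(x0, x1, pattern.n),
                               rng.uniform(y0, y1, pattern.n)])
        sims[s] = ripleys_k(PointPattern(pts, pattern.window),
                            radii, correction)["k"].to_numpy()
    lo = np.quantile(sims, alpha / 2, axis=0)
    hi = np.quantile(sims, 1 - alpha / 2, axis=0)
    return pd.DataFrame({"r": radii, "k": obs, "lo": lo, "hi": hi,
                         "csr": np.pi * radii**2,
                         "clustered": obs > hi})


# ---------------------------------------------------------------------------
# Kernel density surface
# ---------------------------------------------------------------------------

@dataclass
class RiskSurface:
    """Gaussian-kernel density raster over the window.

    ``values[j, i]`` is the probability density (per m^2) at the centre of
    the cell in column i, row j; rows follow increasing y.
    """

    values: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    sigma: float
    window: tuple[float, float, float, float]

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0])
                     * (self.y_edges[1] - self.y_edges[0]))

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.cell_area)


def kde_surface(pattern: PointPattern, sigma: float,
                grid_res: float) -> RiskSurface:
    """Fixed-bandwidth isotropic Gaussian kernel estimate on a raster.

    f(u) = (1/n) sum_i N(u; point_i, sigma^2 I), evaluated at cell centres.
    The Gaussian factorizes over x and y, so the raster is the product of
    two one-dimensional kernel matrices.
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be positive")
    if grid_res <= 0:
        raise InvalidArgumentError("grid_res must be positive")
    x0, y0, x1, y1 = pattern.window
    nx = max(1, int(math.ceil((x1 - x0) / grid_res)))
    ny = max(1, int(math.ceil((y1 - y0) / grid_res)))
    x_edges = np.linspace(x0, x1, nx + 1)
    y_edges = np.linspace(y0, y1, ny + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    pts = pattern.points
    gx = np.exp(-0.5 * ((xc[None, :] - pts[:, 0, None]) / sigma) ** 2)
    gy = np.exp(-0.5 * ((yc[None, :] - pts[:, 1, None]) / sigma) ** 2)
    values = (gy.T @ gx) / (2 * np.pi * sigma**2 * pattern.n)
    return RiskSurface(values=values, x_edges=x_edges, y_edges=y_edges,
                       sigma=sigma, window=pattern.window)


def loocv_bandwidth(pattern: PointPattern, sigma_candidates=None,
                    refine: bool = True) -> float:
    """Bandwidth maximizing the leave-one-out point-process log-likelihood.

    For each candidate sigma, sum_i log f_{-i}(x_i) with
    f_{-i}(x) = (1/(n-1)) sum_{j != i} N(x; x_j, sigma^2 I).  Ties pick the
    smallest sigma.  With ``refine``, a golden-section pass between the
    neighbours of the best grid candidate sharpens the estimate.

    Defaults to a log-spaced grid from 10 m to 5 km.
    """
    pts = pattern.points
    if len(np.unique(pts, axis=0)) < 2:
        raise InsufficientDataError("need at least 2 distinct points")
    if sigma_candidates is None:
        sigma_candidates = np.geomspace(10.0, 5000.0, 30)
    cands = np.asarray(sorted(sigma_candidates), dtype=float)
    if len(cands) == 0 or cands[0] <= 0:
        raise InvalidArgumentError("candidates must be positive and "
                                   "non-empty")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)  # exclude self: exp(-inf) = 0
    n = len(pts)

    def loo_ll(sigma: float) -> float:
        log_k = -d2 / (2 * sigma**2)
        m = log_k.max(axis=1)
        # rows with all -inf (coincident-free impossible here) guard:
        with np.errstate(over="ignore"):
            s = np.exp(log_k - m[:, None]).sum(axis=1)
        ll = m + np.log(s) - np.log(2 * np.pi * sigma**2 * (n - 1))
        return float(ll.sum()) if np.isfinite(ll).all() else -np.inf

    scores = np.array([loo_ll(s) for s in cands])
    if not np.isfinite(scores).any():
        raise InvalidArgumentError("all candidate bandwidths give -inf "
                                   "likelihood")
    best = int(np.argmax(scores))  # argmax returns first max: smallest sigma
    sigma_star = float(cands[best])
    if refine and 0 < best < len(cands) - 1:
        lo, hi = cands[best - 1], cands[best + 1]
        phi = (math.sqrt(5) - 1) / 2
        a, b = math.log(lo), math.log(hi)
        c, d = b - phi * (b - a), a + phi * (b - a)
        fc, fd = loo_ll(math.exp(c)), loo_ll(math.exp(d))
        for _ in range(25):
            if fc >= fd:
                b, d, fd = d, c, fc
                c = b - phi * (b - a)
                fc = loo_ll(math.exp(c))
            else:
                a, c, fc = c, d, fd
                d = a + phi * (b - a)
                fd = loo_ll(math.exp(d))
        refined = math.exp((a + b) / 2)
        if loo_ll(refined) >= scores[best]:
            sigma_star = float(refined)
    return sigma_star


# ---------------------------------------------------------------------------
# Highest-density region
# ---------------------------------------------------------------------------

@dataclass
class HdrRegion:
    """Highest-density region of a surface: cells holding >= mass of the
    total, with 4-connected components."""

    mask: np.ndarray            # boolean raster, same shape as the surface
    threshold: float            # density cut
    mass: float                 # requested probability mass
    components: list[dict] = field(default_factory=list)
    # each component: {"label", "n_cells", "area_m2", "polygon"}

    @property
    def smallest_component_area(self) -> float:
        if not self.components:
            return float("nan")
        return min(c["area_m2"] for c in self.components)


def contour_region(surface: RiskSurface, mass: float = 0.95) -> HdrRegion:
    """Highest-density region holding at least ``mass`` of the surface mass.

    The threshold is the largest density value t such that cells with
    f >= t hold at least ``mass`` of the raster's total mass; components are
    extracted by 4-connectivity and returned with their areas and cell-union
    polygons.
    """
    vals = surface.values
    total = vals.sum()
    if not np.isfinite(total) or total <= 0:
        raise InvalidArgumentError("degenerate surface: no mass")
    if not (0 < mass <= 1):
        raise InvalidArgumentError("mass must be in (0, 1]")
    flat = np.sort(vals.ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, mass * total))
    k = min(k, len(flat) - 1)
    threshold = float(flat[k])
    mask = vals >= threshold
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_comp = ndimage.label(mask, structure=structure)
    cell_area = surface.cell_area
    comps = []
    for lab in range(1, n_comp + 1):
        cells = labels == lab
        n_cells = int(cells.sum())
        boxes = []
        js, is_ = np.nonzero(cells)
        for j, i in zip(js, is_):
            boxes.append(box(surface.x_edges[i], surface.y_edges[j],
                             surface.x_edges[i + 1], surface.y_edges[j + 1]))
        comps.append({
            "label": lab,
            "n_cells": n_cells,
            "area_m2": n_cells * cell_area,
            "polygon": unary_union(boxes),
        })
    return HdrRegion(mask=mask, threshold=threshold, mass=mass,
                     components=comps)


# ---------------------------------------------------------------------------
# Quadrat analysis
# ---------------------------------------------------------------------------

@dataclass
class QuadratGrid:
    """Quadrat counts over the window with the dispersion test result."""

    quadrats: pd.DataFrame  # id, x0, y0, x1, y1, area_km2, count, rate
    side: float
    statistic: float
    df: int
    p_value: float
    flagged: pd.DataFrame | None = None
    uniform_rates: bool = False


def quadrat_test(pattern: PointPattern, side: float) -> QuadratGrid:
    """Chi-square index-of-dispersion test on quadrat counts.

    The window is tiled by side x side quadrats from its lower-left corner;
    partial quadrats at the upper/right edges keep their true clipped area.
    Counts use half-open cells [x0, x1) x [y0, y1) with the last row/column
    closed, so every point lands in exactly one quadrat.  The statistic is
    X^2 = sum (n_i - E_i)^2 / E_i with E_i proportional to quadrat area and
    df = #quadrats - 1; the p-value is the upper chi-square tail.
    """
    if side <= 0:
        raise InvalidArgumentError("side must be positive")
    x0, y0, x1, y1 = pattern.window
    nx = int(math.ceil((x1 - x0) / side))
    ny = int(math.ceil((y1 - y0) / side))
    if nx * ny < 2:
        raise InvalidArgumentError("grid has fewer than 2 quadrats; "
                                   "shrink side")
    ix = np.minimum(((pattern.points[:, 0] - x0) // side).astype(int), nx - 1)
    iy = np.minimum(((pattern.points[:, 1] - y0) // side).astype(int), ny - 1)
    counts = np.zeros((ny, nx), dtype=int)
    np.add.at(counts, (iy, ix), 1)
    rows = []
    for j in range(ny):
        for i in range(nx):
            qx0 = x0 + i * side
            qy0 = y0 + j * side
            qx1 = min(qx0 + side, x1)
            qy1 = min(qy0 + side, y1)
            area_km2 = (qx1 - qx0) * (qy1 - qy0) / 1e6
            rows.append((f"Q{j:03d}-{i:03d}", qx0, qy0, qx1, qy1,
                         area_km2, counts[j, i],
                         counts[j, i] / area_km2 if area_km2 > 0 else 0.0))
    quad = pd.DataFrame(rows, columns=["id", "x0", "y0", "x1", "y1",
                                       "area_km2", "count", "rate"])
    n = pattern.n
    expected = n * quad["area_km2"] / quad["area_km2"].sum()
    stat = float(((quad["count"] - expected) ** 2 / expected).sum())
    df = len(quad) - 1
    p = float(stats.chi2.sf(stat, df))
    return QuadratGrid(quadrats=quad, side=float(side), statistic=stat,
                       df=df, p_value=p)


def top_risk_areas(grid: QuadratGrid, fraction: float = 0.05) -> QuadratGrid:
    """Flag quadrats at or above the (1 - fraction) quantile of the fatality
    rate per km^2; ties at the cutoff are all included.

    Returns the grid with ``flagged`` filled (sorted by rate descending).
    If every rate is identical the whole grid ties at the cutoff: all
    quadrats are flagged and ``uniform_rates`` is set as a warning.
    """
    if not (0 < fraction < 1):
        raise InvalidArgumentError("fraction must be in (0, 1)")
    quad = grid.quadrats[grid.quadrats["area_km2"] > 0]
    rates = quad["rate"].to_numpy(dtype=float)
    cutoff = float(np.quantile(rates, 1 - fraction))
    flagged = quad[quad["rate"] >= cutoff].sort_values(
        "rate", ascending=False).reset_index(drop=True)
    uniform = bool(np.all(rates == rates[0]))
    return QuadratGrid(quadrats=grid.quadrats, side=grid.side,
                       statistic=grid.statistic, df=grid.df,
                       p_value=grid.p_value, flagged=flagged,
                       uniform_rates=uniform)


# ---------------------------------------------------------------------------
# End-to-end hotspot pipeline
# ---------------------------------------------------------------------------

@dataclass
class HotspotResult:
    pattern: PointPattern
    sigma: float
    surface: RiskSurface
    hdr: HdrRegion
    grid: QuadratGrid

    @property
    def flagged(self) -> pd.DataFrame:
        return self.grid.flagged


def detect_hotspots(points: np.ndarray,
                    window: tuple[float, float, float, float],
                    mass: float = 0.95,
                    top_fraction: float = 0.05,
                    sigma: float | None = None,
                    grid_res: float | None = None,
                    side: float | None = None) -> HotspotResult:
    """Full hotspot chain on a fatal-event point set.

    Bandwidth defaults to the LOO-CV likelihood choice; raster resolution to
    sigma / 2; the quadrat side to the square root of the area of the
    smallest connected component of the ``mass`` highest-density region
    (tying the grid to the kernel's significant-cluster scale), capped at
    the side of a square with the area of a single kernel's own 95%
    highest-density disk (radius sigma * sqrt(2 ln 20)) so one merged
    component cannot degrade the grid to a handful of quadrats.  All
    overridable.
    """
    pattern = PointPattern(np.asarray(points, dtype=float), window)
    if sigma is None:
        sigma = loocv_bandwidth(pattern)
    if grid_res is None:
        x0, y0, x1, y1 = window
        grid_res = max(sigma / 2.0, min(x1 - x0, y1 - y0) / 400.0)
    surface = kde_surface(pattern, sigma, grid_res)
    hdr = contour_region(surface, mass)
    if side is None:
        kernel_hdr_area = math.pi * (sigma * math.sqrt(2 * math.log(20)))**2
        side = min(math.sqrt(hdr.smallest_component_area),
                   math.sqrt(kernel_hdr_area))
    grid = quadrat_test(pattern, side)
    grid = top_risk_areas(grid, top_fraction)
    return HotspotResult(pattern=pattern, sigma=sigma, surface=surface,
                         hdr=hdr, grid=grid)
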
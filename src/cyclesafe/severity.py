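"""Fatality-severity modelling for bicyclist collisions.

The probability that a collision is fatal is modelled with a binomial
generalized additive mixed model: unpenalized linear terms for categorical
and binary covariates (counterpart vehicle type, weekday, sex, bike-path
and transit flags, the high-stress LTS-4 indicator), penalized smooths for
continuous covariates (terrain slope, time of day as a cyclic smooth, age,
road geometry, zone context), a two-dimensional spatial smooth over the
event coordinates, and Gaussian random intercepts for zone and for year
nested in zone.  Covariates are screened beforehand (bivariate association,
missingness, collinearity), and the rare fatal class can be rebalanced by
random oversampling to a target prevalence before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import gam
from .errors import InvalidArgumentError

SIGNIFICANCE_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def stars(p: float) -> str:
    for cut, mark in SIGNIFICANCE_STARS:
        if p < cut:
            return mark
    return ""


# ---------------------------------------------------------------------------
# Covariate screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    selected: list[str]
    exclusions: pd.DataFrame  # columns: covariate, reason, detail


def _is_categorical(s: pd.Series) -> bool:
    return (s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)
            or s.dtype == bool or s.nunique(dropna=True) <= 8)


def screen_covariates(data: pd.DataFrame, candidates: list[str],
                      outcome: str = "fatal",
                      p_threshold: float = 0.2,
                      missing_threshold: float = 0.10,
                      collinearity_threshold: float = 0.8) -> ScreenResult:
    """Select model covariates by bivariate association with the outcome.

    A candidate survives if its missingness is below ``missing_threshold``,
    it is non-degenerate, and its bivariate test against the outcome has
    p < ``p_threshold`` (chi-square for categoricals, Welch t for
    continuous).  Among survivors, numeric pairs with |r| at or above
    ``collinearity_threshold`` drop the member with more missingness (ties:
    the later candidate).  Every exclusion is logged with the failing rule.
    """
    y = data[outcome]
    if y.nunique(dropna=True) < 2:
        raise InvalidArgumentError("outcome has no variation")
    y = y.astype(int)
    selected: list[str] = []
    log: list[tuple[str, str, str]] = []
    pvals: dict[str, float] = {}
    for cov in candidates:
        s = data[cov]
        miss = float(s.isna().mean())
        if miss >= missing_threshold:
            log.append((cov, "missingness", f"{100 * miss:.1f}% missing"))
            continue
        if s.nunique(dropna=True) < 2:
            log.append((cov, "degenerate", "constant covariate"))
            continue
        ok = s.notna()
        if _is_categorical(s):
            tab = pd.crosstab(s[ok], y[ok])
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                log.append((cov, "degenerate", "single-level crosstab"))
                continue
            p = float(stats.chi2_contingency(tab.to_numpy())[1])
        else:
            a = s[ok & (y == 1)].astype(float)
            b = s[ok & (y == 0)].astype(float)
            if len(a) < 2 or len(b) < 2:
                log.append((cov, "degenerate", "outcome class too small"))
                continue
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if not p < p_threshold:
            log.append((cov, "bivariate p", f"p={p:.3f} >= {p_threshold}"))
            continue
        pvals[cov] = p
        selected.append(cov)

    numeric = [c for c in selected if not _is_categorical(data[c])]
    dropped: set[str] = set()
    for i, a in enumerate(numeric):
        for b in numeric[i + 1:]:
            if a in dropped or b in dropped:
                continue
            ok = data[a].notna() & data[b].notna()
            if ok.sum() < 3:
                continue
            r = float(np.corrcoef(data.loc[ok, a].astype(float),
                                  data.loc[ok, b].astype(float))[0, 1])
            if abs(r) >= collinearity_threshold:
                ma, mb = data[a].isna().mean(), data[b].isna().mean()
                victim = a if ma > mb else b
                dropped.add(victim)
                log.append((victim, "collinearity",
                            f"|r|={abs(r):.2f} with "
                            f"{'%s' % (b if victim == a else a)}"))
    selected = [c for c in selected if c not in dropped]
    return ScreenResult(
        selected=selected,
        exclusions=pd.DataFrame(log, columns=["covariate", "reason",
                                              "detail"]))


# ---------------------------------------------------------------------------
# Oversampling
# ---------------------------------------------------------------------------

def oversample(data: pd.DataFrame, target_positive_fraction: float = 0.30,
               seed: int = 0, outcome: str = "fatal") -> pd.DataFrame:
    """Random oversampling of the minority (positive) class.

    Positive rows are resampled with replacement until the positive fraction
    first reaches ``target_positive_fraction``; negatives are untouched.
    With counts that divide evenly the target is hit exactly.  If the data
    already meet the target the table is returned unchanged with a warning.
    """
    if not 0 < target_positive_fraction < 1:
        raise InvalidArgumentError("target fraction must be in (0, 1)")
    pos = data[data[outcome] == 1]
    neg = data[data[outcome] == 0]
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0:
        raise InvalidArgumentError("no positive rows to oversample")
    current = n_pos / (n_pos + n_neg)
    if current >= target_positive_fraction:
        warnings.warn("positive fraction already at or above target; "
                      "returning data unchanged")
        return data
    # smallest m with m/(m+n_neg) >= target
    m = int(np.ceil(target_positive_fraction * n_neg
                    / (1 - target_positive_fraction) - 1e-9))
    rng = np.random.default_rng(seed)
    extra_idx = rng.choice(pos.index.to_numpy(), size=m - n_pos,
                           replace=True)
    out = pd.concat([data, pos.loc[extra_idx]], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Model specification and fitting
# ---------------------------------------------------------------------------

@dataclass
class SmoothSpec:
    column: str
    k: int = 10
    cyclic: bool = False
    period: float = 24.0


@dataclass
class ModelSpec:
    """GAMM structure: what enters linearly, what is smoothed, and the
    random-intercept grouping.

    ``linear_terms`` maps a column to its reference level for categoricals
    (None for already-numeric 0/1 flags).  Default baselines follow the
    field convention: automobile for the counterpart vehicle, Sunday for the
    weekday.
    """

    linear_terms: dict[str, str | None] = field(default_factory=dict)
    smooth_terms: list[SmoothSpec] = field(default_factory=list)
    spatial_smooth: tuple[str, str] | None = None
    spatial_k: int = 30
    random_intercepts: list[str | tuple[str, str]] = field(
        default_factory=list)
    outcome: str = "fatal"

    def __post_init__(self):
        smooth_cols = {s.column for s in self.smooth_terms}
        overlap = smooth_cols & set(self.linear_terms)
        if overlap:
            raise InvalidArgumentError(
                f"covariates in both linear and smooth lists: {sorted(overlap)}")


def default_model_spec() -> ModelSpec:
    return ModelSpec(
        linear_terms={"sex": "F", "vehicle_type": "automobile",
                      "weekday": "Sunday", "on_bike_path": None,
                      "has_transit_route": None, "lts4": None},
        smooth_terms=[
            SmoothSpec("slope_pct"),
            SmoothSpec("surface_failures", k=6),
            SmoothSpec("time_of_day", cyclic=True, period=24.0),
            SmoothSpec("age"),
        ],
        spatial_smooth=("x", "y"),
        random_intercepts=["zone_id", ("zone_id", "year")],
    )


@dataclass
class SeverityFit:
    coefficients: pd.DataFrame  # term, level, estimate, se, z, p, stars, flag
    smooths: dict[str, pd.DataFrame]  # x, fit, se, lo, hi (log-odds scale)
    random_sd: dict[str, float]
    n_obs: int
    converged: bool
    edf: float
    deviance: float
    spec: ModelSpec
    raw: gam.GamFit


def _build_blocks(data: pd.DataFrame, spec: ModelSpec
                  ) -> tuple[np.ndarray, list[gam.Block], list[dict]]:
    y = data[spec.outcome].to_numpy(dtype=float)
    blocks = [gam.Block("intercept", np.ones((len(data), 1)))]
    coef_meta: list[dict] = [{"term": "intercept", "level": ""}]

    for col, baseline in spec.linear_terms.items():
        s = data[col]
        if baseline is None:
            X = s.to_numpy(dtype=float).reshape(-1, 1)
            blocks.append(gam.Block(col, X))
            coef_meta.append({"term": col, "level": ""})
        else:
            levels = [lv for lv in pd.unique(s.astype(str))
                      if lv != str(baseline)]
            levels.sort()
            X = np.column_stack([(s.astype(str) == lv).to_numpy(float)
                                 for lv in levels])
            blocks.append(gam.Block(col, X))
            coef_meta.extend({"term": col, "level": lv} for lv in levels)

    for sm in spec.smooth_terms:
        x = data[sm.column].to_numpy(dtype=float)
        if sm.cyclic:
            X, S, meta = gam.cyclic_bspline_basis(x, k=sm.k,
                                                  period=sm.period)
        else:
            X, S, meta = gam.bspline_basis(x, k=sm.k)
        Xc, Sc, Z = gam.center_constraint(X, S)
        blocks.append(gam.Block(f"s({sm.column})", Xc, Sc, kind="smooth",
                                meta=meta, Z=Z))
        coef_meta.extend({"term": f"s({sm.column})", "level": str(j)}
                         for j in range(Xc.shape[1]))

    if spec.spatial_smooth is not None:
        cx, cy = spec.spatial_smooth
        xy = data[[cx, cy]].to_numpy(dtype=float)
        X, S, meta = gam.thinplate_2d_basis(xy, k=spec.spatial_k)
        Xc, Sc, Z = gam.center_constraint(X, S)
        blocks.append(gam.Block(f"s({cx},{cy})", Xc, Sc, kind="smooth",
                                meta=meta, Z=Z))
        coef_meta.extend({"term": f"s({cx},{cy})", "level": str(j)}
                         for j in range(Xc.shape[1]))

    for group in spec.random_intercepts:
        if isinstance(group, tuple):
            name = ":".join(group)
            labels = data[list(group)].astype(str).agg("/".join, axis=1)
        else:
            name = group
            labels = data[group].astype(str)
        codes, levels = pd.factorize(labels, sort=True)
        X = np.zeros((len(data), len(levels)))
        X[np.arange(len(data)), codes] = 1.0
        blocks.append(gam.Block(f"re({name})", X, np.eye(len(levels)),
                                kind="random",
                                meta={"levels": list(levels)}))
        coef_meta.extend({"term": f"re({name})", "level": str(lv)}
                         for lv in levels)
    return y, blocks, coef_meta


def fit_gamm(data: pd.DataFrame, spec: ModelSpec | None = None,
             lambdas=None, optimize_lambda: bool = True,
             grid_size: int = 100) -> SeverityFit:
    """Fit the binomial GAMM and extract the reporting surfaces.

    Returns linear coefficients with Wald SE/p and significance stars,
    each smooth evaluated on a covariate grid with a 95% CI band (log-odds
    scale, centered contribution), and the random-intercept standard
    deviations.  Coefficients drifting beyond |15| log-odds are flagged as
    separation artifacts rather than reported as infinite.
    """
    spec = spec or ModelSpec()
    data = data.reset_index(drop=True)
    y, blocks, coef_meta = _build_blocks(data, spec)
    n_pen_basis = sum(b.X.shape[1] for b in blocks if b.S is not None)
    if n_pen_basis and len(data) < 10 * n_pen_basis:
        warnings.warn(
            f"n = {len(data)} below 10x the {n_pen_basis} penalized basis "
            "functions; smooths may be undersmoothed")
    fit = gam.fit_penalized_glm(y, blocks, lambdas=lambdas,
                                optimize_lambda=optimize_lambda)

    se_all = np.sqrt(np.clip(np.diag(fit.cov), 0, None))
    rows = []
    for j, meta in enumerate(coef_meta):
        term = meta["term"]
        if term.startswith(("s(", "re(")):
            continue
        est, se = float(fit.beta[j]), float(se_all[j])
        z = est / se if se > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        rows.append({"term": term, "level": meta["level"],
                     "estimate": est, "se": se, "z": z, "p": p,
                     "stars": stars(p) if np.isfinite(p) else "",
                     "flag": "separation" if fit.separation_flags[j]
                     else ""})
    coefficients = pd.DataFrame(rows)

    smooths: dict[str, pd.DataFrame] = {}
    for blk in fit.blocks:
        if blk.kind != "smooth" or blk.meta.get("kind") == "thinplate2d":
            continue
        sl = fit.block_slice(blk.name)
        col = blk.name[2:-1]
        x = data[col].to_numpy(dtype=float)
        if blk.meta["kind"] == "cyclic":
            grid = np.linspace(0, blk.meta["period"], grid_size,
                               endpoint=False)
        else:
            grid = np.linspace(x.min(), x.max(), grid_size)
        Xg = gam.evaluate_basis(blk.meta, grid) @ blk.Z
        fit_vals = Xg @ fit.beta[sl]
        var = np.einsum("ij,jk,ik->i", Xg, fit.cov[sl, sl], Xg)
        se = np.sqrt(np.clip(var, 0, None))
        smooths[col] = pd.DataFrame({
            "x": grid, "fit": fit_vals, "se": se,
            "lo": fit_vals - 1.96 * se, "hi": fit_vals + 1.96 * se})

    return SeverityFit(coefficients=coefficients, smooths=smooths,
                       random_sd=fit.random_sd(), n_obs=fit.n_obs,
                       converged=fit.converged, edf=fit.edf,
                       deviance=fit.deviance, spec=spec, raw=fit)


def smooth_thresholds(fit: SeverityFit, term: str) -> list[float]:
    """Covariate values where the 95% band for a smooth's log-odds
    contribution crosses zero (odds-ratio contribution crosses 1).

    Crossings are located by linear interpolation on the evaluation grid.
    An empty list means the band never excludes zero (term not significant
    anywhere); if the band excludes zero over the whole range there is no
    crossing either, but the significance is reported by the band itself.
    """
    if term not in fit.smooths:
        raise KeyError(f"no fitted smooth for {term!r}")
    sm = fit.smooths[term]
    sig = ((sm["lo"] > 0) | (sm["hi"] < 0)).to_numpy()
    x = sm["x"].to_numpy()
    out = []
    for i in range(1, len(sig)):
        if sig[i] != sig[i - 1]:
            # interpolate on the band edge that crosses zero here
            for band in ("lo", "hi"):
                v0, v1 = sm[band].iloc[i - 1], sm[band].iloc[i]
                if v0 == v1 or (v0 > 0) == (v1 > 0):
                    continue
                out.append(float(x[i - 1] - v0 * (x[i] - x[i - 1])
                                 / (v1 - v0)))
                break
            else:
                out.append(float(0.5 * (x[i - 1] + x[i])))
    return sorted(out)


def significant_intervals(fit: SeverityFit, term: str
                          ) -> list[tuple[float, float]]:
    """Covariate intervals over which the 95% band excludes zero.

    A band entirely above (or below) zero gives a single interval covering
    the whole evaluation range; a band that never excludes zero gives an
    empty list (term not significant anywhere).
    """
    if term not in fit.smooths:
        raise KeyError(f"no fitted smooth for {term!r}")
    sm = fit.smooths[term]
    sig = ((sm["lo"] > 0) | (sm["hi"] < 0)).to_numpy()
    x = sm["x"].to_numpy()
    out = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = x[i]
        elif not s and start is not None:
            out.append((float(start), float(x[i - 1])))
            start = None
    if start is not None:
        out.append((float(start), float(x[-1])))
    return out


# ---------------------------------------------------------------------------
# Level of Traffic Stress
# ---------------------------------------------------------------------------

#: Ordered first-match rules mapping segment attributes to an LTS rating.
#: Simplified from the published LTS criteria: dedicated bike infrastructure
#: gives low stress; few lanes and low speed without heavy vehicles stays
#: moderate; everything else is high stress.
DEFAULT_LTS_RULES: list[tuple[dict, int]] = [
    ({"has_bike_path": True}, 1),
    ({"lanes": ("<=", 2), "speed_limit": ("<=", 40),
      "has_transit_route": False}, 2),
    ({"lanes": ("<=", 2), "speed_limit": ("<=", 50)}, 3),
    ({"lanes": ("<=", 3), "speed_limit": ("<=", 50),
      "has_transit_route": False}, 3),
    ({}, 4),
]


def _match(row, cond: dict) -> bool:
    for key, rule in cond.items():
        v = row[key]
        if isinstance(rule, tuple):
            op, val = rule
            ok = {"<=": v <= val, ">=": v >= val, "<": v < val,
                  ">": v > val, "==": v == val}[op]
        else:
            ok = bool(v) == bool(rule)
        if not ok:
            return False
    return True


def lts_rating(segments: pd.DataFrame | dict,
               rules: list[tuple[dict, int]] = DEFAULT_LTS_RULES):
    """Level-of-traffic-stress rating 1-4 by first-matching-rule lookup.

    Accepts a single segment (dict) or a table; the final catch-all rule
    makes the table total.  The high-stress indicator is ``rating == 4``.
    """
    if isinstance(segments, dict):
        for cond, rating in rules:
            if _match(segments, cond):
                return rating
        raise InvalidArgumentError("rule table is not total")
    out = np.empty(len(segments), dtype=int)
    for i, (_, row) in enumerate(segments.iterrows()):
        out[i] = lts_rating(row.to_dict(), rules)
    return out


# ---------------------------------------------------------------------------
# Stratified fits
# ---------------------------------------------------------------------------

def stratified_fit(data: pd.DataFrame, spec: ModelSpec,
                   strata: str = "sex", **fit_kwargs
                   ) -> dict[str, SeverityFit | None]:
    """Independent fits per stratum plus the pooled fit, same specification.

    The stratifying covariate is removed from the linear terms inside each
    stratum.  Strata with a single outcome class are skipped (None, with a
    warning) rather than fitted.
    """
    out: dict[str, SeverityFit | None] = {}
    for level, grp in data.groupby(strata, observed=True):
        if grp[spec.outcome].nunique() < 2:
            warnings.warn(f"stratum {strata}={level}: single outcome class; "
                          "skipped")
            out[str(level)] = None
            continue
        sub_spec = ModelSpec(
            linear_terms={k: v for k, v in spec.linear_terms.items()
                          if k != strata},
            smooth_terms=spec.smooth_terms,
            spatial_smooth=spec.spatial_smooth,
            spatial_k=spec.spatial_k,
            random_intercepts=spec.random_intercepts,
            outcome=spec.outcome)
        out[str(level)] = fit_gamm(grp, sub_spec, **fit_kwargs)
    out["pooled"] = fit_gamm(data, spec, **fit_kwargs)
    return out
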
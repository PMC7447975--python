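"""Standardized collision-rate trends and standardized mortality ratios.

Monthly fatal and nonfatal collision rates are directly standardized by age
(quinquennial groups) against a standard population — by default the WHO
World Standard Population 2000-2025 — with two exposure denominators: the
bicyclist population (events per 100,000 persons) and the distance ridden
(events per 100 million vehicle-km travelled).  Yearly summaries are the
mean of the 12 monthly rates with a t-based 95% CI (df = months - 1), and
between-year changes are tested on the two sets of monthly rates.  Indirect
standardization gives the monthly SMR: observed deaths over the deaths
expected if reference age-specific rates applied to the study population.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError, SchemaError

#: WHO World Standard Population 2000-2025 weights by quinquennial age group.
WHO_STANDARD_2000 = {
    "00-04": 0.0886, "05-09": 0.0869, "10-14": 0.0860, "15-19": 0.0847,
    "20-24": 0.0822, "25-29": 0.0793, "30-34": 0.0761, "35-39": 0.0715,
    "40-44": 0.0659, "45-49": 0.0604, "50-54": 0.0537, "55-59": 0.0455,
    "60-64": 0.0372, "65-69": 0.0296, "70-74": 0.0221, "75-79": 0.0152,
    "80-84": 0.0091, "85+": 0.0064,
}

PER_100K = 1e5
PER_100M_VKMT = 1e8


@dataclass
class StandardPopulation:
    """Age-group weights used for direct standardization (sum to 1)."""

    weights: pd.DataFrame  # columns: age_group, weight
    source: str = "WHO World Standard Population 2000-2025"

    def __post_init__(self):
        w = self.weights["weight"].to_numpy(dtype=float)
        if (w < 0).any():
            raise InvalidArgumentError("standard weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("standard weights must sum to 1")

    def restricted(self, age_groups) -> pd.Series:
        """Weights renormalized over the given age groups."""
        sub = self.weights[self.weights["age_group"].isin(age_groups)]
        if sub.empty:
            raise SchemaError("no overlap between standard and study "
                              "age groups")
        w = sub.set_index("age_group")["weight"]
        return w / w.sum()


def who_standard() -> StandardPopulation:
    df = pd.DataFrame({"age_group": list(WHO_STANDARD_2000),
                       "weight": list(WHO_STANDARD_2000.values())})
    df["weight"] = df["weight"] / df["weight"].sum()
    return StandardPopulation(weights=df)


def percent_reduction(value_a: float, value_b: float) -> float:
    """100 * (a - b) / a: the percent reduction from a to b."""
    if value_a == 0:
        raise InvalidArgumentError("baseline value is zero: undefined change")
    return 100.0 * (value_a - value_b) / value_a


def _prepare_collisions(collisions: pd.DataFrame) -> pd.DataFrame:
    df = collisions.copy()
    dt = pd.to_datetime(df["datetime"])
    df["year"] = dt.dt.year
    df["month"] = dt.dt.month
    if "age_group" not in df.columns:
        from .synthetic_city import age_to_group
        df["age_group"] = age_to_group(df["age"])
    return df


def monthly_rates(
    collisions: pd.DataFrame,
    exposure: pd.DataFrame,
    denominator_kind: str = "population",
    scale: float | None = None,
    standard: StandardPopulation | None = None,
    period: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Directly age-standardized monthly rates by outcome and sex.

    rate(month) = scale * sum_age w_age * count(month, age) / denom(year, age)
    with standard weights renormalized over the age groups that have positive
    denominators.  The VKmT denominator is daily VKmT x days in the month.
    Cells where a positive count falls on a zero denominator are flagged
    ``undefined`` (rate NaN) rather than silently dropped.

    Returns columns: year, month, outcome {fatal, nonfatal}, sex {F, M, all},
    denominator_kind, rate, n_events, undefined.
    """
    if denominator_kind not in ("population", "vkmt"):
        raise InvalidArgumentError("denominator_kind must be 'population' "
                                   "or 'vkmt'")
    value_col = "population" if denominator_kind == "population" \
        else "daily_vkmt"
    if value_col not in exposure.columns:
        raise SchemaError(f"exposure panel lacks '{value_col}'")
    if scale is None:
        scale = PER_100K if denominator_kind == "population" else \
            PER_100M_VKMT
    standard = standard or who_standard()

    df = _prepare_collisions(collisions)
    if period is None:
        period = (int(df["year"].min()), int(df["year"].max()))
    years = range(period[0], period[1] + 1)
    missing = set(years) - set(exposure["year"].unique())
    if missing:
        raise SchemaError(f"exposure panel does not cover years {sorted(missing)}")

    has_sex = "sex" in exposure.columns
    denom_keys = ["year", "age_group"] + (["sex"] if has_sex else [])
    denom = (exposure.groupby(denom_keys, observed=True)[value_col]
             .sum().reset_index())

    rows = []
    for outcome in ("fatal", "nonfatal"):
        sub_o = df[df["fatal"] == (1 if outcome == "fatal" else 0)]
        for sex in ("F", "M", "all"):
            sub = sub_o if sex == "all" else sub_o[sub_o["sex"] == sex]
            d = denom if (sex == "all" or not has_sex) else \
                denom[denom["sex"] == sex]
            d_age = (d.groupby(["year", "age_group"], observed=True)
                     [value_col].sum())
            for year in years:
                for month in range(1, 13):
                    cnt = (sub[(sub["year"] == year) &
                               (sub["month"] == month)]
                           .groupby("age_group", observed=True)
                           .size())
                    dy = d_age.loc[year] if year in d_age.index.get_level_values(0) \
                        else pd.Series(dtype=float)
                    if denominator_kind == "vkmt":
                        dy = dy * calendar.monthrange(year, month)[1]
                    pos = dy[dy > 0]
                    undefined = bool(
                        (cnt.reindex(dy.index, fill_value=0)[dy <= 0] > 0)
                        .any()) or pos.empty
                    if undefined:
                        rate = float("nan")
                    else:
                        w = standard.restricted(pos.index)
                        c = cnt.reindex(pos.index, fill_value=0).astype(float)
                        rate = float(scale * (w * c / pos).sum())
                    rows.append((year, month, outcome, sex,
                                 denominator_kind, rate,
                                 int(cnt.sum()), undefined))
    return pd.DataFrame(rows, columns=[
        "year", "month", "outcome", "sex", "denominator_kind", "rate",
        "n_events", "undefined"])


def yearly_summary(panel: pd.DataFrame,
                   rate_col: str = "rate") -> pd.DataFrame:
    """Mean of the monthly rates per year with a t-based 95% CI.

    Requires all 12 month rows per group (error listing gaps otherwise);
    months flagged undefined are excluded from the mean and counted in
    ``n_months_excluded``.  CI uses df = n_months - 1.
    """
    group_cols = [c for c in ("year", "outcome", "sex", "denominator_kind")
                  if c in panel.columns]
    out = []
    for key, grp in panel.groupby(group_cols, observed=True, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        months = set(grp["month"])
        gaps = sorted(set(range(1, 13)) - months)
        if gaps:
            raise InsufficientDataError(
                f"group {key}: missing months {gaps}")
        ok = grp if "undefined" not in grp.columns else \
            grp[~grp["undefined"].astype(bool)]
        vals = ok[rate_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        m = len(vals)
        if m < 2:
            raise InsufficientDataError(
                f"group {key}: only {m} defined monthly rates")
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(m))
        tq = float(stats.t.ppf(0.975, m - 1))
        out.append((*key, mean, mean - tq * se, mean + tq * se, m, 12 - m))
    return pd.DataFrame(out, columns=[
        *group_cols, "mean_rate", "ci_lo", "ci_hi",
        "n_months", "n_months_excluded"])


@dataclass
class YearComparison:
    pct_change: float          # 100 * (mean_a - mean_b) / mean_a
    p_value: float             # Welch two-sample t on the monthly rates
    sex_difference_p: float | None = None  # interaction contrast, if by_sex


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_years(panel: pd.DataFrame, year_a: int, year_b: int,
                  outcome: str | None = None,
                  denominator_kind: str | None = None,
                  sex: str = "all",
                  rate_col: str = "rate",
                  by_sex: bool = False) -> YearComparison:
    """Percent change and significance between two years' monthly rates.

    The change is 100 * (mean_a - mean_b) / mean_a (positive = reduction from
    year_a to year_b); the p-value is a Welch two-sample t-test on the 12+12
    monthly rates.  With ``by_sex`` the sex difference in the change is the
    interaction term of a two-way linear model on the F/M monthly rates.
    """
    sel = panel
    if outcome is not None and "outcome" in sel.columns:
        sel = sel[sel["outcome"] == outcome]
    if denominator_kind is not None and "denominator_kind" in sel.columns:
        sel = sel[sel["denominator_kind"] == denominator_kind]
    if "undefined" in sel.columns:
        sel = sel[~sel["undefined"].astype(bool)]

    def pick(year, s):
        sub = sel[sel["year"] == year]
        if "sex" in sub.columns:
            sub = sub[sub["sex"] == s]
        v = sub[rate_col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise InsufficientDataError(
                f"year {year}, sex {s}: fewer than 2 monthly rates")
        return v

    a = pick(year_a, sex)
    b = pick(year_b, sex)
    if a.mean() == 0:
        raise InvalidArgumentError("mean rate in year_a is zero: "
                                   "undefined change")
    pct = 100.0 * (a.mean() - b.mean()) / a.mean()
    p = _welch_p(a, b)

    sex_p = None
    if by_sex:
        import statsmodels.formula.api as smf

        frames = []
        for year in (year_a, year_b):
            for s in ("F", "M"):
                v = pick(year, s)
                frames.append(pd.DataFrame(
                    {"rate": v, "year": str(year), "sex": s}))
        dd = pd.concat(frames, ignore_index=True)
        fit = smf.ols("rate ~ C(year) * C(sex)", data=dd).fit()
        inter = [n for n in fit.pvalues.index if ":" in n]
        sex_p = float(fit.pvalues[inter[0]])
    return YearComparison(pct_change=float(pct), p_value=p,
                          sex_difference_p=sex_p)


# ---------------------------------------------------------------------------
# Indirect standardization (SMR)
# ---------------------------------------------------------------------------

def internal_reference_rates(collisions: pd.DataFrame,
                             exposure: pd.DataFrame) -> pd.DataFrame:
    """Pooled all-years monthly death rates per age group and sex: the
    internal reference for the SMR when no external table is supplied."""
    df = _prepare_collisions(collisions)
    fatal = df[df["fatal"] == 1]
    deaths = (fatal.groupby(["age_group", "sex"], observed=True).size()
              .rename("deaths").reset_index())
    pop = (exposure.groupby(["age_group", "sex"], observed=True)["population"]
           .sum().rename("pop_years").reset_index())
    ref = deaths.merge(pop, on=["age_group", "sex"], how="right")
    ref["deaths"] = ref["deaths"].fillna(0.0)
    # person-months at risk = sum over years of population x 12
    ref["monthly_rate"] = ref["deaths"] / (ref["pop_years"] * 12.0)
    ref.loc[ref["pop_years"] <= 0, "monthly_rate"] = 0.0
    return ref[["age_group", "sex", "monthly_rate"]]


def smr(collisions: pd.DataFrame, exposure: pd.DataFrame,
        reference_rates: pd.DataFrame | None = None,
        period: tuple[int, int] | None = None) -> pd.DataFrame:
    """Monthly standardized mortality ratios by sex (and combined).

    expected(year, month, sex) = sum_age reference_rate(age, sex) x
    population(age, sex, year); smr = observed / expected.  Reference rates
    are monthly death rates per person; the default is the internal pooled
    reference (see :func:`internal_reference_rates`), against which the
    all-period mean SMR is ~1 by construction.
    """
    if "population" not in exposure.columns:
        raise SchemaError("exposure panel lacks 'population'")
    if reference_rates is None:
        reference_rates = internal_reference_rates(collisions, exposure)
    req = {"age_group", "sex", "monthly_rate"}
    if not req.issubset(reference_rates.columns):
        raise SchemaError(f"reference rates need columns {sorted(req)}")
    study_ages = set(exposure["age_group"].unique())
    ref_ages = set(reference_rates["age_group"].unique())
    if not study_ages <= ref_ages:
        raise SchemaError(
            f"age groups missing from reference: {sorted(study_ages - ref_ages)}")

    df = _prepare_collisions(collisions)
    fatal = df[df["fatal"] == 1]
    if period is None:
        period = (int(df["year"].min()), int(df["year"].max()))

    pop = (exposure.groupby(["year", "age_group", "sex"], observed=True)
           ["population"].sum().reset_index())
    exp_sex = pop.merge(reference_rates, on=["age_group", "sex"])
    exp_sex["expected"] = exp_sex["population"] * exp_sex["monthly_rate"]
    exp_by = exp_sex.groupby(["year", "sex"])["expected"].sum()
    exp_all = exp_sex.groupby("year")["expected"].sum()

    rows = []
    for year in range(period[0], period[1] + 1):
        for month in range(1, 13):
            sub = fatal[(fatal["year"] == year) & (fatal["month"] == month)]
            for sex in ("F", "M", "all"):
                obs = len(sub) if sex == "all" else \
                    int((sub["sex"] == sex).sum())
                if sex == "all":
                    expd = float(exp_all.get(year, 0.0))
                else:
                    expd = float(exp_by.get((year, sex), 0.0))
                ratio = obs / expd if expd > 0 else float("nan")
                rows.append((year, month, sex, obs, expd, ratio))
    return pd.DataFrame(rows, columns=["year", "month", "sex", "observed",
                                       "expected", "smr"])


def yearly_smr_summary(smr_panel: pd.DataFrame) -> pd.DataFrame:
    """Yearly mean of the 12 monthly SMRs with t-based 95% CI."""
    panel = smr_panel.rename(columns={"smr": "rate"})
    panel["undefined"] = ~np.isfinite(panel["rate"])
    return (yearly_summary(panel)
            .rename(columns={"mean_rate": "mean_smr"}))
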
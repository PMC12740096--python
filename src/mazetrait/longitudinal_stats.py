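"""Standardisation, Z-score combination, trait stability and decline screening.

The longitudinal analysis standardises every metric within each age
(Z = (x - mu)/sigma, population sigma by default), sign-inverts the two
metrics where lower raw values mean better performance, combines metric
subsets per mouse with Stouffer's method (sum of Z over sqrt(k)), and asks
how well performance at 4 months predicts performance at 18 months via a
slope-penalised linear fit and Pearson's r.  An exhaustive search scores all
2^11 - 1 = 2047 metric subsets by mean R-squared across age comparisons, a
resampling scheme maps the variance of r against degrees of freedom, and a
consensus rule over the five maze metrics screens individual mice for
consistent cognitive decline.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import INVERTED_METRICS, MAZE_METRICS, METRIC_NAMES, ValidationError

logger = logging.getLogger("mazetrait")

DEFAULT_AGE_PAIRS = ((4, 8), (4, 12), (4, 18))

#: Sign of a raw-metric slope that indicates worsening performance.
ADVERSE_SIGN = {
    "USS": -1.0,
    "errors": +1.0,
    "DMT": +1.0,
    "exploration_ratio": -1.0,
    "cumulative_arm_time": -1.0,
}


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StabilityResult:
    """Fitted linear relation between two measurements of a trait."""

    metrics: tuple[str, ...]
    ages: tuple[int, ...] | tuple[()]
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int
    ridge_lambda: float = 0.0

    def __post_init__(self) -> None:
        if not math.isnan(self.r) and not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation {self.r} outside [-1, 1]")


@dataclass(frozen=True)
class DeclinerFlag:
    """One mouse's decline screen: which metrics trended adversely and how."""

    mouse_id: str
    flagged: bool
    n_adverse: int
    p_values: dict = field(default_factory=dict)
    std_slopes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# standardisation and combination
# ---------------------------------------------------------------------------


def zscore(
    table: pd.DataFrame,
    population_sd: bool = True,
    invert: frozenset[str] = INVERTED_METRICS,
) -> pd.DataFrame:
    """Standardise each metric column within one age.

    Population (ddof=0) standard deviation by default; the inverted metrics
    (decision time, errors) are multiplied by -1 after standardisation so a
    higher Z always means better performance.  Missing values stay missing.
    The choice of sigma convention is recorded in ``result.attrs``.
    """
    ddof = 0 if population_sd else 1
    out = {}
    for col in table.columns:
        x = table[col].astype(float)
        ok = x.dropna()
        if len(ok) < 2:
            raise ValidationError(f"metric {col!r} has fewer than 2 values")
        sigma = ok.std(ddof=ddof)
        if sigma == 0 or not np.isfinite(sigma):
            raise ValidationError(f"metric {col!r} is constant; Z-score undefined")
        z = (x - ok.mean()) / sigma
        if col in invert:
            z = -z
        out[col] = z
    zdf = pd.DataFrame(out, index=table.index)
    zdf.attrs["population_sd"] = population_sd
    zdf.attrs["inverted"] = sorted(invert & set(table.columns))
    if "age_months" in table.attrs:
        zdf.attrs["age_months"] = table.attrs["age_months"]
    return zdf


def stouffer_combine(ztable: pd.DataFrame, metrics: list[str]) -> pd.Series:
    """Combine metric Z-scores per mouse: Z = sum(Z_i) / sqrt(k).

    k counts the metrics actually available for that mouse; a mouse with no
    available metric gets NaN.
    """
    if not metrics:
        raise ValidationError("stouffer_combine needs a non-empty metric subset")
    missing = [m for m in metrics if m not in ztable.columns]
    if missing:
        raise ValidationError(f"metrics {missing} not present in Z-table")
    sub = ztable[list(metrics)].astype(float)
    k = sub.notna().sum(axis=1)
    combined = sub.sum(axis=1, min_count=1) / np.sqrt(k.where(k > 0))
    return combined


# ---------------------------------------------------------------------------
# fitting primitives
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson_r needs paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("pearson_r: constant input, correlation undefined")
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def weighted_linear_fit(
    x,
    y,
    ridge_lambda: float = 0.0,
    metrics: tuple[str, ...] = (),
    ages: tuple[int, ...] = (),
) -> StabilityResult:
    """Linear fit of y on x with an optional L2 penalty on the slope.

    Minimises sum((y - (w0*x + w1))**2) + lambda*w0**2; the intercept is not
    penalised, so lambda = 0 reduces exactly to ordinary least squares and
    lambda -> infinity shrinks the slope to 0 and the intercept to mean(y).
    r and R^2 describe the (x, y) association; the p-value is the F-test of
    the unpenalised fit.
    """
    if ridge_lambda < 0:
        raise ValidationError("ridge_lambda must be >= 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 paired observations, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope undefined")

    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / (sxx + ridge_lambda)
    intercept = ybar - slope * xbar

    if np.ptp(y) == 0:
        r = math.nan
        p = math.nan
        logger.warning("weighted_linear_fit: constant response, r undefined")
    else:
        ols = stats.linregress(x, y)
        r = float(ols.rvalue)
        p = float(ols.pvalue)
    return StabilityResult(
        metrics=tuple(metrics),
        ages=tuple(ages),
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        r_squared=r * r if not math.isnan(r) else math.nan,
        p_value=p,
        n=n,
        ridge_lambda=ridge_lambda,
    )


# ---------------------------------------------------------------------------
# per-mouse lifespan trends
# ---------------------------------------------------------------------------


def lifespan_trend(
    ages,
    values,
    metric: str = "",
    ridge_lambda: float = 0.0,
) -> StabilityResult | None:
    """Per-mouse trend of one metric against age in months.

    ``ages`` may repeat (day-level observations within an age).  Requires
    data at >= 3 distinct ages, else returns None (missing).  A constant
    metric yields slope 0 with r flagged NaN.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    ages, values = ages[keep], values[keep]
    if len(np.unique(ages)) < 3:
        return None
    return weighted_linear_fit(
        ages, values, ridge_lambda=ridge_lambda, metrics=(metric,) if metric else (),
        ages=tuple(sorted(set(int(a) for a in ages))),
    )


# ---------------------------------------------------------------------------
# cross-age prediction
# ---------------------------------------------------------------------------


def predictive_correlation(
    ztable_early: pd.DataFrame,
    ztable_late: pd.DataFrame,
    metrics: list[str],
    ridge_lambda: float = 0.0,
    ages: tuple[int, int] = (4, 18),
) -> StabilityResult:
    """How well a combined Z at the early age predicts the same at the late age.

    Stouffer-combines the metric subset within each age, aligns mice present
    at both ages, and fits the late combined Z on the early one.
    """
    early = stouffer_combine(ztable_early, metrics)
    late = stouffer_combine(ztable_late, metrics)
    joined = pd.concat({"early": early, "late": late}, axis=1).dropna()
    if len(joined) < 3:
        raise ValidationError(
            f"only {len(joined)} mice present at both ages; need >= 3"
        )
    return weighted_linear_fit(
        joined["early"].to_numpy(),
        joined["late"].to_numpy(),
        ridge_lambda=ridge_lambda,
        metrics=tuple(metrics),
        ages=ages,
    )


# ---------------------------------------------------------------------------
# exhaustive subset search
# ---------------------------------------------------------------------------


def combination_search(
    ztables: dict[int, pd.DataFrame],
    universe: list[str] | None = None,
    age_pairs: tuple[tuple[int, int], ...] = DEFAULT_AGE_PAIRS,
    ridge_lambda: float = 0.0,
) -> pd.DataFrame:
    """Score every non-empty metric subset by mean R^2 across age comparisons.

    With the full 11-metric universe this evaluates 2^11 - 1 = 2047 subsets.
    Returned ranking is sorted by mean R^2 descending with a deterministic
    lexicographic tie-break on the (sorted) metric names; every subset appears
    exactly once.
    """
    if universe is None:
        universe = list(METRIC_NAMES)
    if not universe:
        raise ValidationError("empty metric universe")
    for a, b in age_pairs:
        if a not in ztables or b not in ztables:
            raise ValidationError(f"age pair ({a}, {b}) missing from Z-tables")

    rows = []
    for size in range(1, len(universe) + 1):
        for subset in itertools.combinations(universe, size):
            r2s = []
            for a, b in age_pairs:
                try:
                    res = predictive_correlation(
                        ztables[a], ztables[b], list(subset),
                        ridge_lambda=ridge_lambda, ages=(a, b),
                    )
                    r2s.append(res.r_squared)
                except ValidationError:
                    r2s.append(math.nan)
            rows.append(
                {
                    "metrics": "+".join(sorted(subset)),
                    "size": size,
                    "mean_r_squared": float(np.nanmean(r2s)) if r2s else math.nan,
                }
            )
    ranking = pd.DataFrame(rows)
    ranking = ranking.sort_values(
        ["mean_r_squared", "metrics"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


# ---------------------------------------------------------------------------
# resampling robustness
# ---------------------------------------------------------------------------


def resampling_variance_curve(
    x,
    y,
    n_resamples_per_size: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Variance of the fitted correlation as a function of degrees of freedom.

    For every subset size s = 1..n, draws ``n_resamples_per_size`` (default n)
    random mouse subsets without replacement and records Pearson's r of the
    paired values (NaN when s < 3, where no line can be fitted).  The default
    therefore produces n * n resampled datasets -- 441 for a 21-mouse cohort.
    The returned frame has one row per degrees of freedom (dof = s - 2) with
    the variance of r across draws; at the full sample size only one subset
    exists, so the variance there is exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValidationError("resampling needs paired samples with n >= 4")
    draws = n if n_resamples_per_size is None else int(n_resamples_per_size)
    rng = np.random.default_rng(seed)

    records = []
    for size in range(1, n + 1):
        for _ in range(draws):
            idx = rng.choice(n, size=size, replace=False)
            if size >= 3 and np.ptp(x[idx]) > 0 and np.ptp(y[idx]) > 0:
                r = float(stats.pearsonr(x[idx], y[idx]).statistic)
            else:
                r = math.nan
            records.append({"size": size, "dof": size - 2, "r": r})
    frame = pd.DataFrame(records)
    curve = (
        frame.groupby("dof")["r"]
        .agg(variance=lambda s: float(np.var(s.dropna())) if s.notna().any() else math.nan,
             n_fits=lambda s: int(s.notna().sum()))
        .reset_index()
    )
    curve.attrs["total_resamples"] = len(frame)
    curve.attrs["fits"] = frame
    return curve


# ---------------------------------------------------------------------------
# metric-table assembly
# ---------------------------------------------------------------------------


def build_metric_tables(blocks, bouts=()) -> dict[int, pd.DataFrame]:
    """Assemble per-age mice x metrics tables from sessions and object bouts.

    ``blocks`` is an iterable of session blocks (one mouse at one age);
    ``bouts`` the object-exploration records whose choice-phase preference
    ratios fill the OR1/OR15/OL1/OL15 columns.  Each returned table carries
    its age in ``attrs['age_months']``.
    """
    from .maze_metrics import session_metrics
    from .object_openfield import preference_table

    rows: dict[int, dict[str, dict[str, float]]] = {}
    for block in blocks:
        rows.setdefault(block.age_months, {})[block.mouse_id] = session_metrics(block)
    prefs = preference_table(bouts) if bouts else pd.DataFrame()

    tables = {}
    for age, by_mouse in sorted(rows.items()):
        df = pd.DataFrame.from_dict(by_mouse, orient="index").sort_index()
        if not prefs.empty and age in prefs.index.get_level_values("age_months"):
            p = prefs.xs(age, level="age_months")
            df = df.join(p, how="left")
        df = df.reindex(columns=[m for m in METRIC_NAMES if m in df.columns])
        df.index.name = "mouse_id"
        df.attrs["age_months"] = age
        tables[age] = df
    return tables


# ---------------------------------------------------------------------------
# decline screening
# ---------------------------------------------------------------------------


def detect_decliners(
    daily_tables: dict[str, dict[int, pd.DataFrame]],
    metrics: list[str] | None = None,
    m_required: int = 3,
    alpha: float = 0.05,
    bonferroni: bool = True,
    min_slope: float = 0.60,
) -> list[DeclinerFlag]:
    """Screen every mouse for consistent adverse trends across maze metrics.

    ``daily_tables[mouse][age]`` holds that mouse's day-level metric table
    (from :func:`mazetrait.maze_metrics.daily_metrics`).  For each of the five
    maze metrics a day-level regression against age (months) is fitted; the
    metric counts as adverse when

    * its slope has the metric's adverse sign,
    * the regression p-value clears alpha (Bonferroni-divided by the number
      of metrics by default), and
    * the standardized slope magnitude -- slope per mean age step, in units
      of the cohort's between-mouse population SD of that metric (estimated
      leave-one-out, pooled over ages) -- exceeds ``min_slope``.

    A mouse is flagged when >= ``m_required`` metrics are adverse.  The
    effect-size threshold is what separates genuine monotone decline from the
    session-to-session trait fluctuation every mouse shows; p-values alone
    cannot, because with 16 trials per age even small real fluctuations are
    statistically significant.
    """
    if metrics is None:
        metrics = list(MAZE_METRICS)
    bad = [m for m in metrics if m not in ADVERSE_SIGN]
    if bad:
        raise ValidationError(f"no adverse-direction convention for {bad}")
    mice = sorted(daily_tables)
    if len(mice) < 3:
        raise ValidationError("decline screening needs >= 3 mice")

    ages = sorted({a for tabs in daily_tables.values() for a in tabs})
    step = float(np.mean(np.diff(ages))) if len(ages) > 1 else 1.0
    threshold_p = alpha / len(metrics) if bonferroni else alpha

    # session means per mouse x age x metric, for the LOO population SD
    sess = {
        mouse: {age: tab[metrics].mean() for age, tab in tabs.items()}
        for mouse, tabs in daily_tables.items()
    }
    sess_df = pd.concat(
        {m: pd.DataFrame(v).T for m, v in sess.items()}, names=["mouse_id", "age"]
    )

    flags: list[DeclinerFlag] = []
    for mouse in mice:
        others = sess_df.drop(index=mouse, level="mouse_id")
        # population SD per metric: SD across mice within age, pooled over ages
        sd0 = others.groupby(level="age").std(ddof=1).mean()
        xs, frames = [], []
        for age, tab in sorted(daily_tables[mouse].items()):
            xs.append(np.full(len(tab), float(age)))
            frames.append(tab[metrics])
        x = np.concatenate(xs)
        ydf = pd.concat(frames, axis=0)
        n_adverse = 0
        pvals: dict[str, float] = {}
        std_slopes: dict[str, float] = {}
        for metric in metrics:
            y = ydf[metric].to_numpy(dtype=float)
            keep = np.isfinite(y)
            if keep.sum() < 3 or np.ptp(x[keep]) == 0:
                pvals[metric] = math.nan
                std_slopes[metric] = math.nan
                continue
            res = stats.linregress(x[keep], y[keep])
            denom = sd0[metric]
            ss = res.slope * step / denom if denom > 0 else math.nan
            pvals[metric] = float(res.pvalue)
            std_slopes[metric] = float(ss)
            if (
                np.isfinite(ss)
                and res.pvalue < threshold_p
                and ADVERSE_SIGN[metric] * ss > min_slope
            ):
                n_adverse += 1
        flags.append(
            DeclinerFlag(
                mouse_id=mouse,
                flagged=n_adverse >= m_required,
                n_adverse=n_adverse,
                p_values=pvals,
                std_slopes=std_slopes,
            )
        )
    return flags
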
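"""Temporal trend statistics for slice-level metrics.

Linear fits against period midpoints, quadratic-vs-linear nested-model
comparison, Welch early-vs-recent tests, Pearson metric couplings, an
edges~nodes model, an additive two-way fixed-effects ANOVA on Gini, and the
sensitivity-analysis driver (edge-weight thresholds, Gini variants,
alternative binnings).

With four period midpoints per family these fits have very few residual
degrees of freedom; every TrendFit carries a ``low_n`` flag so downstream
reporting can qualify the inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inequality import gini_by_slice
from .network import METRIC_NAMES, metrics_by_slice
from .periods import PERIOD_PRESETS, PeriodSpec, default_periods

DEFAULT_MIDPOINTS = (1915.0, 1945.0, 1975.0, 2005.0)

#: early vs recent split of the default periods
EARLY_PERIODS = ("1900-1929", "1930-1959")
RECENT_PERIODS = ("1960-1989", "1990-2020")

TREND_METRICS = ("nodes", "edges", "density", "reciprocity",
                 "giant_fraction", "gini")


@dataclass(frozen=True)
class TrendFit:
    metric: str
    family: str
    slope: float
    slope_se: float
    p_value: float
    r_squared: float
    intercept: float
    n_points: int
    low_n: bool


@dataclass(frozen=True)
class ModelComparison:
    family: str
    metric: str
    f_statistic: float
    p_value: float
    df: tuple[int, int]
    preferred: str  # "linear" | "quadratic"


def fit_linear_trend(values, midpoints=DEFAULT_MIDPOINTS,
                     metric: str = "", family: str = "") -> TrendFit:
    """OLS of metric on midpoint; two-sided p from t with n-2 df."""
    x = np.asarray(midpoints, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 finite points")
    res = stats.linregress(x, y)
    if np.allclose(y, y[0]):
        r2, p = 0.0, 1.0
    else:
        r2 = res.rvalue ** 2
        p = res.pvalue
    return TrendFit(metric=metric, family=family,
                    slope=float(res.slope), slope_se=float(res.stderr),
                    p_value=float(p), r_squared=float(r2),
                    intercept=float(res.intercept), n_points=int(n),
                    low_n=n <= 4)


def _poly_rss(x: np.ndarray, y: np.ndarray, degree: int) -> float:
    coef = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    return float(resid @ resid)


def quadratic_vs_linear(values, midpoints=DEFAULT_MIDPOINTS,
                        metric: str = "", family: str = "",
                        alpha: float = 0.05) -> ModelComparison:
    """Nested-model F test for curvature (U-shaped patterns).

    With 4 points the quadratic leaves a single residual df, so
    F = (RSS_lin - RSS_quad) / (RSS_quad / 1) on (1, 1) df.
    """
    x = np.asarray(midpoints, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 points for the quadratic comparison")
    # centre x for numerical conditioning; RSS is invariant to the shift
    xc = x - x.mean()
    rss_lin = _poly_rss(xc, y, 1)
    rss_quad = _poly_rss(xc, y, 2)
    df_num = 1
    df_den = x.size - 3
    scale = float(np.sum(y ** 2))
    if rss_lin <= 1e-12 * max(scale, 1e-300):
        # linear model already fits to machine precision
        return ModelComparison(family=family, metric=metric, f_statistic=0.0,
                               p_value=1.0, df=(df_num, df_den),
                               preferred="linear")
    if rss_quad <= 0:
        f = float("inf")
        p = 0.0
    else:
        f = (rss_lin - rss_quad) / df_num / (rss_quad / df_den)
        f = max(f, 0.0)
        p = float(stats.f.sf(f, df_num, df_den))
    return ModelComparison(family=family, metric=metric, f_statistic=float(f),
                           p_value=p, df=(df_num, df_den),
                           preferred="quadratic" if p < alpha else "linear")


def welch_t(early, recent) -> tuple[float, float, float]:
    """Welch's t, Satterthwaite df and two-sided p."""
    a = np.asarray(early, dtype=float)
    b = np.asarray(recent, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 0.0, float(res.df), 1.0
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def gini_two_way_anova(gini_table: pd.DataFrame) -> pd.DataFrame:
    """Additive fixed-effects two-way ANOVA on a complete family × period grid.

    One observation per cell, so the interaction is untestable and the
    residual is the interaction term.  Returns F and p per main effect.
    """
    pivot = gini_table.pivot_table(index="family", columns="period",
                                   values="gini", aggfunc="first")
    if pivot.isna().any().any():
        raise ValueError("incomplete family × period design")
    y = pivot.to_numpy(dtype=float)
    a, b = y.shape
    if a < 2 or b < 2:
        raise ValueError("need >= 2 levels per factor")
    grand = y.mean()
    ss_family = b * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_period = a * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = ss_total - ss_family - ss_period
    df_family, df_period = a - 1, b - 1
    df_resid = (a - 1) * (b - 1)
    ms_resid = ss_resid / df_resid
    rows = []
    tiny = 1e-12 * max(ss_total, 1.0)
    for effect, ss, df in (("family", ss_family, df_family),
                           ("period", ss_period, df_period)):
        ms = ss / df
        if ms_resid <= tiny:
            f = 0.0 if ms <= tiny else float("inf")
        else:
            f = ms / ms_resid
        p = float(stats.f.sf(f, df, df_resid)) if np.isfinite(f) else 0.0
        rows.append({"effect": effect, "ss": ss, "df": df, "F": f, "p": p})
    rows.append({"effect": "residual", "ss": ss_resid, "df": df_resid,
                 "F": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows)


def trend_table(metrics: pd.DataFrame, gini: pd.DataFrame,
                period_spec: PeriodSpec | None = None,
                pooled: bool = True) -> pd.DataFrame:
    """Linear trend fits per metric, per family and (optionally) pooled."""
    spec = period_spec or default_periods()
    merged = metrics.merge(
        gini[gini["variant"] == gini["variant"].iloc[0]]
        [["family", "period", "gini"]] if not gini.empty else
        pd.DataFrame(columns=["family", "period", "gini"]),
        on=["family", "period"], how="left")
    rows = []

    def _fit(sub: pd.DataFrame, fam: str):
        sub = sub.sort_values("midpoint")
        for metric in TREND_METRICS:
            if metric not in sub.columns:
                continue
            y = sub[metric].to_numpy(dtype=float)
            x = sub["midpoint"].to_numpy(dtype=float)
            if np.isfinite(y).sum() < 3:
                continue
            fit = fit_linear_trend(y, x, metric=metric, family=fam)
            rows.append({"family": fam, "metric": metric,
                         "slope": fit.slope, "slope_se": fit.slope_se,
                         "p_value": fit.p_value, "r_squared": fit.r_squared,
                         "intercept": fit.intercept, "n_points": fit.n_points,
                         "low_n": fit.low_n})

    for fam, sub in merged.groupby("family"):
        _fit(sub, str(fam))
    if pooled and merged["family"].nunique() > 1:
        pooled_df = merged.groupby(["period", "midpoint"], as_index=False).mean(
            numeric_only=True)
        pooled_df["family"] = "pooled"
        _fit(pooled_df, "pooled")
    return pd.DataFrame(rows)


def early_vs_recent(metrics: pd.DataFrame,
                    early_labels=EARLY_PERIODS,
                    recent_labels=RECENT_PERIODS) -> pd.DataFrame:
    """Welch tests comparing early vs recent periods across families."""
    rows = []
    for metric in ("nodes", "edges", "density", "reciprocity",
                   "giant_fraction"):
        if metric not in metrics.columns:
            continue
        early = metrics.loc[metrics["period"].isin(early_labels),
                            metric].dropna().to_numpy(dtype=float)
        recent = metrics.loc[metrics["period"].isin(recent_labels),
                             metric].dropna().to_numpy(dtype=float)
        if early.size < 2 or recent.size < 2:
            continue
        t, df, p = welch_t(early, recent)
        rows.append({"metric": metric, "t": t, "df_welch": df, "p_value": p,
                     "mean_early": early.mean(), "mean_recent": recent.mean()})
    return pd.DataFrame(rows)


def metric_couplings(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among slice metrics plus the edges~nodes model."""
    rows = []
    pairs = (("nodes", "edges"), ("nodes", "density"),
             ("edges", "density"), ("nodes", "giant_fraction"))
    for xcol, ycol in pairs:
        sub = metrics[[xcol, ycol]].dropna()
        if len(sub) < 3 or sub[xcol].nunique() < 2 or sub[ycol].nunique() < 2:
            continue
        r, p = pearson(sub[xcol], sub[ycol])
        rows.append({"kind": "pearson", "x": xcol, "y": ycol, "estimate": r,
                     "p_value": p, "n": len(sub)})
    sub = metrics[["nodes", "edges"]].dropna()
    if len(sub) >= 3 and sub["nodes"].nunique() > 1:
        fit = fit_linear_trend(sub["edges"], sub["nodes"],
                               metric="edges~nodes", family="all")
        rows.append({"kind": "ols", "x": "nodes", "y": "edges",
                     "estimate": fit.slope, "p_value": fit.p_value,
                     "n": fit.n_points})
    return pd.DataFrame(rows)


def sensitivity_suite(records, thresholds=(1, 5, 10),
                      gini_variants=("participants_only", "include_zeros"),
                      binnings=("default", "decadal", "forty_year"),
                      seed: int = 0) -> pd.DataFrame:
    """Recompute metrics, Gini and trend directions per configuration.

    Long-format output: one row per (binning, threshold, variant, family,
    metric) with the fitted slope and its sign.  Threshold 1 with the
    default binning and participants-only Gini reproduces the baseline.
    """
    rows = []
    families = sorted({r.family for r in records})
    for binning in binnings:
        spec = PERIOD_PRESETS[binning]()
        for threshold in thresholds:
            metrics = metrics_by_slice(records, spec, families, seed=seed,
                                       min_weight=threshold)
            for variant in gini_variants:
                gtab = gini_by_slice(records, spec, families,
                                     variants=(variant,),
                                     min_weight=threshold)
                merged = metrics.merge(gtab[["family", "period", "gini"]],
                                       on=["family", "period"], how="left")
                for fam, sub in merged.groupby("family"):
                    sub = sub.sort_values("midpoint")
                    for metric in TREND_METRICS:
                        y = sub[metric].to_numpy(dtype=float)
                        x = sub["midpoint"].to_numpy(dtype=float)
                        if np.isfinite(y).sum() < 3:
                            continue
                        fit = fit_linear_trend(y, x, metric=metric,
                                               family=str(fam))
                        rows.append({
                            "binning": binning, "threshold": threshold,
                            "gini_variant": variant, "family": str(fam),
                            "metric": metric, "slope": fit.slope,
                            "p_value": fit.p_value,
                            "direction": int(np.sign(fit.slope)),
                        })
    return pd.DataFrame(rows)
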
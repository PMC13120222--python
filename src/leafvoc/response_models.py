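"""Treatment-level statistics for the temperature × CO2 factorial design.

* 4-parameter logistic ("sigmoidal") temperature-response fits,
* substrate-control linear regressions of isoprene emission on DMADP pool
  size or on the apparent IspS rate constant, with a configurable
  excluded-temperature set (default {40 °C}, the decoupled regime),
* per-temperature two-sample pooled-variance Student's t-tests between CO2
  levels, with the conventional star codes (* p<0.05, ** p<0.01,
  *** p<0.001).  No multiple-testing correction is applied; the report
  records the number of tests performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .ptr_flux import GROUPS


def logistic4(t: np.ndarray, y_min: float, y_max: float, t_mid: float,
              scale: float) -> np.ndarray:
    """4-parameter logistic: y_min + (y_max - y_min) / (1 + exp(-(t-t_mid)/scale))."""
    return y_min + (y_max - y_min) * expit((np.asarray(t, float) - t_mid) / scale)


@dataclass
class SigmoidFit:
    """A fitted 4-parameter logistic temperature response."""

    y_min: float
    y_max: float
    t_mid_c: float
    slope_scale_c: float
    resid_sd: float
    converged: bool
    flags: tuple[str, ...] = ()

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return logistic4(t, self.y_min, self.y_max, self.t_mid_c,
                         self.slope_scale_c)


def fit_sigmoid(t_values: Sequence[float], y_values: Sequence[float]
                ) -> SigmoidFit:
    """Least-squares 4PL fit with deterministic multi-start initialisation.

    Requires >= 4 distinct temperatures.  Normalised so y_max >= y_min (a
    decreasing response gets a negative slope_scale).  Nearly constant data
    return a flat fit flagged ``degenerate``.
    """
    t = np.asarray(t_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and y must have the same length")
    if np.unique(t).size < 4:
        raise ValueError("fit_sigmoid needs >= 4 distinct temperatures")

    span = float(np.ptp(y))
    if span == 0 or span < 1e-12 * max(1.0, abs(float(y.mean()))):
        return SigmoidFit(float(y.mean()), float(y.mean()), float(np.median(t)),
                          1.0, float(np.std(y)), True, ("degenerate",))

    t_range = float(np.ptp(t))
    starts = []
    rising = float(np.corrcoef(t, y)[0, 1]) >= 0
    for q in (0.25, 0.5, 0.75):
        for sc in (t_range / 20, t_range / 5):
            sgn = 1.0 if rising else -1.0
            starts.append((float(y.min()), float(y.max()),
                           float(np.quantile(t, q)), sgn * sc))

    best, best_sse = None, math.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                # some starts sit on flat likelihood ridges; only the SSE matters
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(logistic4, t, y, p0=p0,
                                             maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = y - logistic4(t, *popt)
        sse = float(resid @ resid)
        if sse < best_sse:
            best, best_sse = popt, sse

    if best is None:
        return SigmoidFit(float(y.min()), float(y.max()), float(np.median(t)),
                          1.0, float(np.std(y)), False, ("no-convergence",))

    y_min, y_max, t_mid, scale = (float(v) for v in best)
    if y_max < y_min:  # normalise orientation
        y_min, y_max, scale = y_max, y_min, -scale
    flags = []
    if not (t.min() - 10.0 <= t_mid <= t.max() + 10.0):
        flags.append("t-mid-out-of-range")
    dof = max(1, t.size - 4)
    resid_sd = math.sqrt(best_sse / dof)
    return SigmoidFit(y_min, y_max, t_mid, scale, resid_sd, True, tuple(flags))


@dataclass
class SubstrateControlFit:
    """OLS of emission on a substrate/kinetic predictor, with the excluded
    (decoupled) temperature points recorded rather than silently dropped."""

    slope: float
    intercept: float
    r2: float
    n_used: int
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_substrate_control(
    x_values: Sequence[float],
    y_values: Sequence[float],
    temps_c: Sequence[float],
    exclude_temps: Iterable[float] = (40.0,),
) -> SubstrateControlFit:
    """Linear regression of emission (y) on pool size or rate constant (x),
    excluding the configured temperature set (default the 40 °C cells)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    temps = np.asarray(temps_c, dtype=float)
    if not (x.shape == y.shape == temps.shape):
        raise ValueError("x, y and temps must have the same length")
    excl_set = {float(t) for t in exclude_temps}
    keep = ~np.isin(temps, sorted(excl_set))
    if not keep.any():
        raise ValueError("all points excluded from the regression")
    if np.count_nonzero(keep) < 3:
        raise ValueError("fewer than 3 points retained for the regression")
    if np.unique(x[keep]).size < 2:
        raise ValueError("retained points have a single x value")
    res = stats.linregress(x[keep], y[keep])
    excluded = pd.DataFrame({
        "x": x[~keep], "y": y[~keep], "t_leaf_c": temps[~keep],
    })
    return SubstrateControlFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        n_used=int(np.count_nonzero(keep)),
        excluded=excluded,
    )


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TreatmentComparison:
    """Pooled-variance two-sample t-test between CO2 levels at one temperature."""

    temperature_c: float
    co2_low: float
    co2_high: float
    mean_low: float
    sd_low: float
    n_low: int
    mean_high: float
    sd_high: float
    n_high: int
    t_stat: float
    df: int
    p_value: float
    stars: str
    note: str = ""


def compare_treatments(
    table: pd.DataFrame,
    value_col: str,
    temp_col: str = "t_leaf_c",
    co2_col: str = "co2_umol_mol",
    equal_var: bool = True,
) -> list[TreatmentComparison]:
    """Per-temperature independent two-tailed Student's t-tests between the
    two CO2 levels.  The pooled-variance test (df = n1 + n2 - 2) is the
    default; ``equal_var=False`` switches to Welch's variant explicitly.
    Temperatures with fewer than 2 leaves in either cell are skipped with a
    note, never silently."""
    out: list[TreatmentComparison] = []
    for temp, sub in table.groupby(temp_col, sort=True):
        levels = sorted(sub[co2_col].unique())
        if len(levels) != 2:
            out.append(TreatmentComparison(
                float(temp), float(levels[0]) if levels else math.nan,
                float(levels[-1]) if levels else math.nan,
                math.nan, math.nan, 0, math.nan, math.nan, 0,
                math.nan, 0, math.nan, "",
                note=f"expected 2 CO2 levels, found {len(levels)}",
            ))
            continue
        a = sub.loc[sub[co2_col] == levels[0], value_col].dropna().to_numpy()
        b = sub.loc[sub[co2_col] == levels[1], value_col].dropna().to_numpy()
        base = dict(
            temperature_c=float(temp),
            co2_low=float(levels[0]), co2_high=float(levels[1]),
            mean_low=float(np.mean(a)) if a.size else math.nan,
            sd_low=float(np.std(a, ddof=1)) if a.size > 1 else math.nan,
            n_low=int(a.size),
            mean_high=float(np.mean(b)) if b.size else math.nan,
            sd_high=float(np.std(b, ddof=1)) if b.size > 1 else math.nan,
            n_high=int(b.size),
        )
        if a.size < 2 or b.size < 2:
            out.append(TreatmentComparison(
                **base, t_stat=math.nan, df=0, p_value=math.nan, stars="",
                note="insufficient replication (n < 2)",
            ))
            continue
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        df = a.size + b.size - 2 if equal_var else int(res.df)
        out.append(TreatmentComparison(
            **base, t_stat=float(res.statistic), df=df,
            p_value=float(res.pvalue), stars=significance_stars(float(res.pvalue)),
        ))
    return out


def comparisons_to_frame(comparisons: Iterable[TreatmentComparison],
                         variable: str = "") -> pd.DataFrame:
    rows = []
    for c in comparisons:
        d = c.__dict__.copy()
        if variable:
            d = {"variable": variable, **d}
        rows.append(d)
    cols = (["variable"] if variable else []) + [
        "temperature_c", "co2_low", "co2_high", "mean_low", "sd_low", "n_low",
        "mean_high", "sd_high", "n_high", "t_stat", "df", "p_value", "stars",
        "note",
    ]
    return pd.DataFrame(rows, columns=cols)


def _cell_stats(df: pd.DataFrame, value_cols: Sequence[str],
                temp_col: str, co2_col: str) -> pd.DataFrame:
    long = df.melt(id_vars=[temp_col, co2_col], value_vars=list(value_cols),
                   var_name="variable", value_name="value")
    g = long.groupby(["variable", temp_col, co2_col], sort=True)["value"]
    stats_df = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    return stats_df.reset_index()


def _sigmoid_rows(df: pd.DataFrame, value_col: str, temp_col: str,
                  co2_col: str) -> list[dict]:
    rows = []
    for co2, sub in df.groupby(co2_col, sort=True):
        sub = sub.dropna(subset=[value_col])
        try:
            fit = fit_sigmoid(sub[temp_col].to_numpy(),
                              sub[value_col].to_numpy())
            rows.append({
                "variable": value_col, "co2_umol_mol": float(co2),
                "y_min": fit.y_min, "y_max": fit.y_max,
                "t_mid_c": fit.t_mid_c, "slope_scale_c": fit.slope_scale_c,
                "resid_sd": fit.resid_sd, "converged": fit.converged,
                "flags": ";".join(fit.flags),
            })
        except ValueError as err:
            rows.append({
                "variable": value_col, "co2_umol_mol": float(co2),
                "y_min": math.nan, "y_max": math.nan, "t_mid_c": math.nan,
                "slope_scale_c": math.nan, "resid_sd": math.nan,
                "converged": False, "flags": f"error: {err}",
            })
    return rows


def build_report(
    leaf_summary: pd.DataFrame,
    exclude_temps: Iterable[float] = (40.0,),
    drop_flagged: bool = True,
    temp_col: str = "t_leaf_c",
    co2_col: str = "co2_umol_mol",
) -> dict[str, pd.DataFrame]:
    """Assemble tidy report tables from a per-leaf summary.

    Expected columns of ``leaf_summary``: ``trace_id``, ``t_leaf_c``,
    ``co2_umol_mol``, ``replicate``, ``a_net``, ``e_iso``, ``s_pool_nmol_m2``,
    ``k_loglin_s``, ``flux_<group>`` for each VOC group, and ``flags``.

    Tables: ``fig1`` (assimilation + isoprene per cell), ``fig2`` (DMADP pool
    per cell), ``fig3`` (substrate-control regressions with the excluded
    temperature cells echoed), ``fig4`` (per-group emissions per cell),
    ``ttests`` (all CO2 comparisons), ``sigmoid_params``.
    """
    df = leaf_summary.copy()
    if drop_flagged and "flags" in df.columns:
        bad = df["flags"].fillna("").str.contains("baseline-not-reached")
        df = df.loc[~bad]
    if df.empty:
        empty = pd.DataFrame()
        return {k: empty.copy() for k in
                ("fig1", "fig2", "fig3", "fig4", "ttests", "sigmoid_params")}

    group_cols = [f"flux_{g}" for g in GROUPS if f"flux_{g}" in df.columns]

    fig1 = _cell_stats(df, [c for c in ("a_net", "e_iso") if c in df.columns],
                       temp_col, co2_col)
    fig2 = _cell_stats(df, ["s_pool_nmol_m2"], temp_col, co2_col)
    fig4 = _cell_stats(df, group_cols, temp_col, co2_col)

    fig3_rows = []
    for co2, sub in df.groupby(co2_col, sort=True):
        for predictor in ("s_pool_nmol_m2", "k_loglin_s"):
            if predictor not in sub.columns:
                continue
            data = sub.dropna(subset=[predictor, "e_iso"])
            try:
                fit = fit_substrate_control(
                    data[predictor], data["e_iso"], data[temp_col],
                    exclude_temps=exclude_temps,
                )
                fig3_rows.append({
                    "co2_umol_mol": float(co2), "predictor": predictor,
                    "slope": fit.slope, "intercept": fit.intercept,
                    "r2": fit.r2, "n_used": fit.n_used,
                    "n_excluded": len(fit.excluded),
                    "excluded_temps": ";".join(
                        f"{t:g}" for t in sorted(set(fit.excluded["t_leaf_c"]))),
                })
            except ValueError as err:
                fig3_rows.append({
                    "co2_umol_mol": float(co2), "predictor": predictor,
                    "slope": math.nan, "intercept": math.nan, "r2": math.nan,
                    "n_used": 0, "n_excluded": 0,
                    "excluded_temps": f"error: {err}",
                })
    fig3 = pd.DataFrame(fig3_rows)

    ttest_frames = []
    for col in ["e_iso", "a_net", "s_pool_nmol_m2", "k_loglin_s"] + group_cols:
        if col not in df.columns:
            continue
        comps = compare_treatments(df, col, temp_col=temp_col, co2_col=co2_col)
        ttest_frames.append(comparisons_to_frame(comps, variable=col))
    ttests = pd.concat(ttest_frames, ignore_index=True) if ttest_frames \
        else pd.DataFrame()
    ttests.attrs["n_tests"] = int(ttests["p_value"].notna().sum()) \
        if "p_value" in ttests.columns else 0

    sig_rows = []
    for col in ["e_iso", "s_pool_nmol_m2"] + group_cols:
        if col in df.columns:
            sig_rows.extend(_sigmoid_rows(df, col, temp_col, co2_col))
    sigmoid_params = pd.DataFrame(sig_rows)

    return {"fig1": fig1, "fig2": fig2, "fig3": fig3, "fig4": fig4,
            "ttests": ttests, "sigmoid_params": sigmoid_params}
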
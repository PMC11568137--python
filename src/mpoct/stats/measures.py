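"""Derived statistics: marginal R2, eccentricity-dependent slopes,
Spearman correlations, dichotomized/univariate deposit models and the
descriptive device-by-run summary."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lmm import ModelFit, ModelSpec, SingularDesignError, fit_lmm

_VOLUME_COLUMNS = ("drusen_nl", "sdd_nl", "hrf_nl")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Display rounding with ties away from zero (journal-table style).

    Values are first snapped to 10 decimals so that 1-ulp float noise
    (e.g. 0.148 - 0.0375 = 0.11049999999999999) still rounds like the
    exact decimal quantity.
    """
    q = Decimal(1).scaleb(-decimals)
    snapped = repr(round(value, max(decimals + 4, 10)))
    return float(Decimal(snapped).quantize(q, rounding=ROUND_HALF_UP))


def marginal_r2(fit: ModelFit) -> float:
    """Variance explained by the fixed effects (Nakagawa-Schielzeth):
    var(X beta) / (var(X beta) + var_random + var_resid)."""
    vf = float(np.var(fit.fixed_predictor(), ddof=1))
    total = vf + fit.var_random + fit.var_resid
    if total <= 0:
        raise ValueError("total variance is zero; marginal R2 undefined")
    return vf / total


def linear_slope(beta_main: float, beta_interaction: float, r_deg: float) -> float:
    """Slope of a thickness effect at eccentricity ``r``:
    beta_main + r * beta_interaction."""
    return beta_main + r_deg * beta_interaction


@dataclass(frozen=True)
class EccentricitySlope:
    variable: str
    r_deg: float
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float


def slope_at_eccentricity(fit: ModelFit, variable: str,
                          r_deg: float) -> EccentricitySlope:
    """Per-eccentricity slope of ``variable`` ('onl' or 'ez') with Wald CI.

    Var = Var(main) + r^2 Var(int) + 2 r Cov(main, int).
    """
    inter = f"eccentricity:{variable}"
    if variable not in fit.params.index or inter not in fit.params.index:
        raise ValueError(
            f"fit lacks main and/or interaction term for {variable!r}")
    bm = float(fit.params[variable])
    bi = float(fit.params[inter])
    est = linear_slope(bm, bi, r_deg)
    c = fit.cov_params
    var = (float(c.loc[variable, variable])
           + r_deg ** 2 * float(c.loc[inter, inter])
           + 2.0 * r_deg * float(c.loc[variable, inter]))
    se = math.sqrt(max(var, 0.0))
    z = sps.norm.ppf(0.975)
    return EccentricitySlope(variable=variable, r_deg=r_deg, estimate=est,
                             se=se, ci_lower=est - z * se, ci_upper=est + z * se)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def dichotomize(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``*_present`` flags (volume > 0) next to the volume columns."""
    out = table.copy()
    for col in _VOLUME_COLUMNS:
        if col not in out.columns:
            raise ValueError(f"missing volume column {col!r}")
        out[col.replace("_nl", "_present")] = out[col] > 0
    return out


def univariate_sdd_models(table: pd.DataFrame) -> tuple[ModelFit, ModelFit]:
    """Two univariate random-intercept models: PWS ~ SDD volume and
    PWS ~ SDD presence."""
    metric = fit_lmm(table, ModelSpec(mains=("sdd",), interactions=(),
                                      reml=True))
    t = dichotomize(table)
    t2 = t.copy()
    # reuse the 'sdd' design slot for the presence indicator
    t2["sdd_nl"] = t["sdd_present"].astype(float)
    binary = fit_lmm(t2, ModelSpec(mains=("sdd",), interactions=(),
                                   reml=True))
    return metric, binary


def prevalence_percent(n_positive: int, n_total: int, decimals: int = 2) -> float:
    """Feature-positive prevalence in percent, rounded for display."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return round_half_up(100.0 * n_positive / n_total, decimals)


def descriptive_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Device-by-run descriptive statistics.

    PWS/EZ/ONL as mean +/- SD; deposit volumes as median [min-max] over
    the strictly positive values, with the positive count.
    """
    if table.empty:
        raise ValueError("empty table")
    t = table[table["included"].astype(bool)] if "included" in table.columns else table
    rows = []
    for (device, run), g in t.groupby(["device", "run"], sort=True):
        row = {"device": device, "run": run, "n": len(g)}
        for label, col in (("pws_db", "pws_db"), ("ez_um", "ez_um"),
                           ("onl_um", "onl_um")):
            row[f"{label}_mean"] = g[col].mean()
            row[f"{label}_sd"] = g[col].std(ddof=1)
        for col in _VOLUME_COLUMNS:
            pos = g.loc[g[col] > 0, col]
            stub = col.replace("_nl", "")
            row[f"{stub}_median"] = pos.median() if len(pos) else np.nan
            row[f"{stub}_min"] = pos.min() if len(pos) else np.nan
            row[f"{stub}_max"] = pos.max() if len(pos) else np.nan
            row[f"{stub}_n_positive"] = int(len(pos))
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_device_mean(summary: pd.DataFrame, device: str,
                       decimals: int = 2) -> float:
    """Equal-weight pooled mean PWS across the two runs of one device."""
    runs = summary.loc[summary["device"] == device, "pws_db_mean"]
    if runs.empty:
        raise ValueError(f"no rows for device {device!r}")
    return round_half_up(float(runs.mean()), decimals)


def rescale_per_unit(estimate_per_nl: float, unit_nl: float = 0.1,
                     decimals: int = 2) -> float:
    """Re-express a per-nl coefficient per ``unit_nl`` (e.g. per 0.1 nl)."""
    return round_half_up(estimate_per_nl * unit_nl, decimals)
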
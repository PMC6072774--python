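"""Hypothesis tests on the fitted BETPL parameters.

The theory makes three falsifiable claims about the per-trip estimates:
(i) the exponent mu clusters at the universal value 3/2 independent of
wind (checked by a Pearson correlation with mean wind and by convergence
of mu-hat toward 3/2 as trips grow longer, i.e. as statistical power
grows); (ii) log lambda1 falls linearly with log mean wind speed; (iii)
so does log lambda2 (clearest with mu pinned at 3/2, which sharpens the
lambda estimates).  Regressions are ordinary least squares on log-log
scales, with 95% confidence and prediction bands, optional trip-duration
subsetting, sequential-AIC screening of biological covariates (sex,
period) added to the reference model log(lambda) ~ log(<v>), and a
head/tail-wind decomposition probing a direct mechanical wind effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

#: trip-duration subsets offered in days; > 4 days is the default report
DURATION_SUBSETS = (2, 3, 4, 5, 6)


@dataclass
class RegressionResult:
    response: str
    beta: float
    se: float
    p: float
    df: int
    ci95: tuple
    intercept: float
    n: int
    n_excluded: int
    subset_rule: str
    prediction: pd.DataFrame = field(default_factory=pd.DataFrame)
    model: object = None


def _subset(records: pd.DataFrame, min_days=None, min_disp=None) -> tuple:
    df = records.copy()
    rule = "all"
    if min_days is not None:
        df = df[df["duration_days"] > min_days]
        rule = f"duration > {min_days} d"
    if min_disp is not None:
        df = df[df["max_disp_km"] > min_disp]
        rule += f", displacement > {min_disp} km"
    return df, rule


def regress_lambda_on_wind(records: pd.DataFrame, response: str = "lambda1",
                           wind_col: str = "mean_v", min_days=None,
                           min_disp=None) -> RegressionResult:
    """OLS of log(lambda) on log(mean wind) with CI and prediction bands.

    Trips with non-positive lambda estimates or wind are excluded (and
    counted); trips falling outside the 95% prediction band are flagged
    as outliers in the ``prediction`` frame.
    """
    df, rule = _subset(records, min_days, min_disp)
    usable = (df[response] > 0) & (df[wind_col] > 0)
    n_excl = int((~usable).sum())
    df = df[usable]
    if len(df) < 10:
        raise ValueError(f"need >= 10 usable records, have {len(df)} ({rule})")
    y = np.log(df[response].to_numpy())
    X = sm.add_constant(np.log(df[wind_col].to_numpy()))
    res = sm.OLS(y, X).fit()
    pred = res.get_prediction(X).summary_frame(alpha=0.05)
    pred.index = df.index
    pred["observed"] = y
    pred["outlier"] = (y < pred["obs_ci_lower"]) | (y > pred["obs_ci_upper"])
    ci = res.conf_int(alpha=0.05)
    return RegressionResult(
        response=f"log {response}", beta=float(res.params[1]),
        se=float(res.bse[1]), p=float(res.pvalues[1]),
        df=int(res.df_resid), ci95=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(res.params[0]), n=len(df), n_excluded=n_excl,
        subset_rule=rule, prediction=pred, model=res,
    )


def mu_wind_independence(records: pd.DataFrame, wind_col: str = "mean_v",
                         min_days=None) -> tuple:
    """Pearson correlation of fitted mu with mean wind: (r, p, df)."""
    df, _ = _subset(records, min_days)
    if len(df) < 10:
        raise ValueError(f"need >= 10 records, have {len(df)}")
    mu, v = df["mu"].to_numpy(), df[wind_col].to_numpy()
    if np.std(mu) == 0 or np.std(v) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    r, p = stats.pearsonr(mu, v)
    return float(r), float(p), len(df) - 2


def mu_convergence(records: pd.DataFrame, thresholds=None) -> tuple:
    """MSE of mu-hat about 3/2 in cumulative displacement subsets.

    Longer (farther-ranging) trips carry more steps, so the estimate
    should converge to the universal 3/2 as the threshold rises.
    Returns (table, trend) where trend is the Kendall tau of MSE against
    threshold (None with fewer than 3 non-empty bins).
    """
    disp = records["max_disp_km"].to_numpy()
    if thresholds is None:
        thresholds = np.quantile(disp, [0.0, 0.2, 0.4, 0.6, 0.8])
    rows = []
    for thr in thresholds:
        sub = records[records["max_disp_km"] >= thr]
        if len(sub) == 0:
            continue
        rows.append({"min_disp_km": float(thr), "n": len(sub),
                     "mse_mu": float(np.mean((sub["mu"] - 1.5) ** 2))})
    table = pd.DataFrame(rows)
    trend = None
    if len(table) >= 3:
        tau, p = stats.kendalltau(table["min_disp_km"], table["mse_mu"])
        trend = (float(tau), float(p))
    return table, trend


def wind_region_confounded(records: pd.DataFrame, wind_col: str = "mean_v",
                           alpha: float = 0.05) -> tuple:
    """Two-sample t of wind by marine region: (confounded, t, p).

    When wind differs strongly between regions the region covariate is
    collinear with wind and is dropped from the covariate models.
    """
    groups = [g[wind_col].to_numpy() for _, g in records.groupby("region")]
    if len(groups) != 2 or min(len(g) for g in groups) < 2:
        return False, np.nan, np.nan
    t, p = stats.ttest_ind(*groups)
    return bool(p < alpha), float(t), float(p)


def covariate_models(records: pd.DataFrame, response: str = "lambda1",
                     covariates=("sex", "period"), wind_col: str = "mean_v",
                     min_days=None, delta_aic_report: float = 4.0) -> pd.DataFrame:
    """Sequential-AIC screen of biological covariates.

    Each covariate is added to the reference model
    log(lambda) ~ log(<v>) as an interaction alone and as interaction +
    main effect; models within ``delta_aic_report`` of the reference are
    flagged ``reported``.  Region (and colony) are excluded whenever
    wind is confounded with region.  Rank-deficient models are dropped
    with a reason.
    """
    df, _ = _subset(records, min_days)
    usable = (df[response] > 0) & (df[wind_col] > 0)
    df = df[usable].copy()
    df["loglam"] = np.log(df[response])
    df["logv"] = np.log(df[wind_col])
    ref = smf.ols("loglam ~ logv", data=df).fit()
    rows = [{"model": "logv (reference)", "delta_aic": 0.0, "aic": ref.aic,
             "term": "", "t": np.nan, "p": np.nan, "reported": True}]
    covs = list(covariates)
    if "region" in covs and "region" in df.columns:
        confounded, t_reg, _ = wind_region_confounded(df, wind_col)
        if confounded:
            covs.remove("region")
            rows.append({"model": "region (dropped)", "delta_aic": np.nan,
                         "aic": np.nan, "term": "region",
                         "t": t_reg, "p": np.nan, "reported": False})
    for cov in covs:
        if df[cov].nunique() < 2:
            continue
        for formula, label in (
            (f"loglam ~ logv + logv:{cov}", f"logv + logv:{cov}"),
            (f"loglam ~ logv + logv:{cov} + {cov}", f"logv + logv:{cov} + {cov}"),
        ):
            try:
                fit = smf.ols(formula, data=df).fit()
            except Exception:
                rows.append({"model": label, "delta_aic": np.nan, "aic": np.nan,
                             "term": cov, "t": np.nan, "p": np.nan,
                             "reported": False})
                continue
            if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
                rows.append({"model": label + " (rank deficient)",
                             "delta_aic": np.nan, "aic": np.nan, "term": cov,
                             "t": np.nan, "p": np.nan, "reported": False})
                continue
            added = [name for name in fit.params.index if cov in name]
            t = float(fit.tvalues[added[0]]) if added else np.nan
            p = float(fit.pvalues[added[0]]) if added else np.nan
            d_aic = float(fit.aic - ref.aic)
            rows.append({"model": label, "delta_aic": d_aic, "aic": fit.aic,
                         "term": added[0] if added else cov, "t": t, "p": p,
                         "reported": d_aic <= delta_aic_report})
    return pd.DataFrame(rows)


def plot_wind_regression(result: RegressionResult, records: pd.DataFrame,
                         path, wind_col: str = "mean_v") -> None:
    """Log-log scatter of lambda against mean wind with the fitted line,
    95% confidence band (mean response) and 95% prediction band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred = result.prediction.copy()
    resp_col = result.response.replace("log ", "")
    df = records.loc[pred.index]
    x = np.log(df[wind_col].to_numpy())
    order = np.argsort(x)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, pred["observed"], s=18, c=np.where(pred["outlier"], "r", "k"),
               alpha=0.7)
    ax.plot(x[order], pred["mean"].to_numpy()[order], "b-")
    ax.plot(x[order], pred["mean_ci_lower"].to_numpy()[order], "b--", lw=0.8)
    ax.plot(x[order], pred["mean_ci_upper"].to_numpy()[order], "b--", lw=0.8)
    ax.plot(x[order], pred["obs_ci_lower"].to_numpy()[order], "r:", lw=0.8)
    ax.plot(x[order], pred["obs_ci_upper"].to_numpy()[order], "r:", lw=0.8)
    ax.set_xlabel(f"log {wind_col} (m/s)")
    ax.set_ylabel(f"log {resp_col}")
    ax.set_title(f"beta = {result.beta:.2f} +/- {result.se:.2f} "
                 f"(p = {result.p:.2g}, {result.subset_rule})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def headtail_regression(records: pd.DataFrame, response: str = "lambda1",
                        min_days=None) -> pd.DataFrame:
    """OLS of log(lambda) on mean head- and tail-wind components.

    Probes a direct mechanical effect of wind on the truncation scales,
    independent of the odor-signal pathway.
    """
    df, _ = _subset(records, min_days)
    if df.empty:
        raise ValueError("empty record set")
    usable = (df[response] > 0) & np.isfinite(df["mean_head"]) \
        & np.isfinite(df["mean_tail"])
    df = df[usable]
    if len(df) < 10:
        raise ValueError(f"need >= 10 usable records, have {len(df)}")
    y = np.log(df[response].to_numpy())
    X = sm.add_constant(df[["mean_head", "mean_tail"]].to_numpy())
    res = sm.OLS(y, X).fit()
    return pd.DataFrame({
        "term": ["intercept", "mean_head", "mean_tail"],
        "coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    })
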
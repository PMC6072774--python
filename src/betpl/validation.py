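"""End-to-end validation experiments for the whole analysis chain.

Each function runs one self-contained study on synthetic data and
returns its headline numbers: emergence of the universal 3/2 exponent
from the mechanistic simulator, the wind-theory proportionalities of the
truncation parameters, oracle equivalences for the numerical kernels,
calibration of the grid-likelihood estimator, and the statistical power
and specificity of the full trajectory pipeline.  The problem sizes are
chosen to give stable answers on a single CPU in minutes; they are the
package's reference study conditions, shared by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alternatives import compare_models
from .geometry import extract_steps, project_to_plane
from .gof import weighted_ks_from_cdf
from .model import (BetplGridFit, BetplParams, betpl_cdf, betpl_norm,
                    betpl_sample)
from .pipeline import build_trip_records
from .regression import regress_lambda_on_wind
from .synthetic import (OdorSignalParams, gen_betpl_walk, gen_cohort,
                        odor_segment_lengths)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,))
               .generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# 1. universal exponent


def universal_exponent_experiment(seed: int = 0, duration_days: float = 150.0,
                                  lim_a: float = 0.3) -> dict:
    """Fit the free-mu grid to pooled flight bouts of the odor simulator.

    The simulator knows nothing about 3/2: bout durations arise from
    Euler-simulated threshold first passages of the concentration signal.
    """
    odor = OdorSignalParams(sim_dt=1500.0 / 400)
    seg = odor_segment_lengths(odor, duration_days * 86400.0, seed=seed)
    seg = np.sort(seg[(seg >= lim_a) & (seg <= 600.0)])
    fit = BetplGridFit(mode="free", lim_a=lim_a).fit(seg)
    return {"mu": fit.mu_, "mu_ci": fit.ci_["mu"], "n": int(seg.size),
            "lambda1": fit.lambda1_, "lambda2": fit.lambda2_}


# ---------------------------------------------------------------------------
# 2. truncation-parameter proportionality suite


def truncation_scaling_experiment(seed: int = 0,
                                  T_values=(600.0, 1200.0, 2400.0),
                                  C_values=(0.9, 1.2, 1.6),
                                  seeds_per_cell: int = 20,
                                  segments_per_run: int = 1500) -> dict:
    """Log-log slopes of fitted (lambda1, lambda2) across a 3x3 grid of
    (T, C/c_tau), fixed-mu fits on raw flight bouts.

    Theory: lambda1 prop 1/T (slope -1 against T) and
    lambda2 prop T (c_tau/C)^2 (slope +1 against T and against
    (c_tau/C)^2; the factorial design makes the two regressors
    orthogonal, so both slopes come from one joint OLS).
    """
    rows = []
    k = 0
    for T in T_values:
        for C in C_values:
            odor = OdorSignalParams(T=T, C=C, sim_dt=T / 400.0)
            # duration sized for ~segments_per_run bouts: one flight+lost
            # cycle lasts about 2 gap / v = T / C seconds
            duration_s = (segments_per_run + 100) * T / C
            for s in range(seeds_per_cell):
                seg = odor_segment_lengths(odor, duration_s,
                                           seed=_sub_seed(seed, k))
                k += 1
                seg = np.sort(seg[(seg >= 0.05) & (seg <= 600.0)])
                fit = BetplGridFit(mode="fixed", lim_a=0.05).fit(seg)
                rows.append({"T": T, "C": C, "ratio2": (odor.c_tau / C) ** 2,
                             "lambda1": fit.lambda1_, "lambda2": fit.lambda2_,
                             "n": seg.size})
    df = pd.DataFrame(rows)
    X = np.column_stack([np.ones(len(df)), np.log(df["T"]),
                         np.log(df["ratio2"])])
    b1 = np.linalg.lstsq(X, np.log(df["lambda1"]), rcond=None)[0]
    b2 = np.linalg.lstsq(X, np.log(df["lambda2"]), rcond=None)[0]
    return {"lambda1_vs_T_slope": float(b1[1]),
            "lambda2_vs_T_slope": float(b2[1]),
            "lambda2_vs_ratio2_slope": float(b2[2]),
            "n_fits": len(df), "table": df}


# ---------------------------------------------------------------------------
# 3. oracle equivalences


def oracle_equivalences(seed: int = 0) -> dict:
    """Numerical kernels against independent brute-force oracles."""
    rng = np.random.default_rng(seed)
    # (a) BETPL normalization vs dense trapezoid
    norm_err = 0.0
    for _ in range(3):
        p = BetplParams(mu=rng.uniform(1.1, 2.5), lambda1=rng.uniform(0, 0.1),
                        lambda2=rng.uniform(0, 2.0), lim_a=0.3)
        l = np.linspace(p.lim_a, p.l_max, 1_000_000)
        f = l ** -p.mu * np.exp(-p.lambda1 * l - p.lambda2 / l)
        norm_err = max(norm_err, abs(betpl_norm(p) * np.trapezoid(f, l) - 1.0))
    # (b) weighted KS vs explicit per-point scan
    p = BetplParams(1.5, 0.02, 0.5, 0.3)
    l = np.sort(betpl_sample(p, 1000, seed=rng))
    P = np.asarray(betpl_cdf(l, p))
    n = l.size
    brute = 0.0
    for i in range(n):
        if 0.0 < P[i] < 1.0:
            w = np.sqrt(P[i] * (1 - P[i]))
            brute = max(brute, abs((i + 1) / n - P[i]) / w,
                        abs(i / n - P[i]) / w)
    ks_err = abs(weighted_ks_from_cdf(P) - brute)
    # (c) trilinear wind interpolation vs 8-corner weighted average
    from .wind import WindGrid, interp_wind
    time = (np.datetime64("2015-06-01T00:00:00")
            + np.arange(4) * np.timedelta64(6, "h"))
    lat = 38.0 + 0.5 * np.arange(5)
    lon = -10.0 + 0.5 * np.arange(5)
    u = rng.normal(3, 2, (4, 5, 5))
    v = rng.normal(-1, 2, (4, 5, 5))
    grid = WindGrid(time=time, lat=lat, lon=lon, u=u, v=v)
    taxis = time.astype("int64")
    interp_err = 0.0
    for _ in range(30):
        qla = rng.uniform(lat[0], lat[-1])
        qlo = rng.uniform(lon[0], lon[-1])
        qt = float(taxis[0] + rng.integers(0, taxis[-1] - taxis[0] + 1))
        it = min(int(np.searchsorted(taxis, qt, "right")) - 1, 2)
        ila = min(int(np.searchsorted(lat, qla, "right")) - 1, 3)
        ilo = min(int(np.searchsorted(lon, qlo, "right")) - 1, 3)
        wt = (qt - taxis[it]) / (taxis[it + 1] - taxis[it])
        wa = (qla - lat[ila]) / 0.5
        wo = (qlo - lon[ilo]) / 0.5
        brute_u = 0.0
        for dt, ft in ((0, 1 - wt), (1, wt)):
            for da, fa in ((0, 1 - wa), (1, wa)):
                for do, fo in ((0, 1 - wo), (1, wo)):
                    brute_u += ft * fa * fo * u[it + dt, ila + da, ilo + do]
        ui, _, _ = interp_wind(grid, qla, qlo,
                               np.datetime64(int(qt), "s"))
        interp_err = max(interp_err, abs(float(ui[0]) - brute_u))
    # (d) OLS vs closed-form normal equations
    from scipy import stats as sps
    import statsmodels.api as sm
    x = rng.uniform(0, 3, 40)
    y = 1.0 - 1.5 * x + rng.normal(0, 0.5, 40)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(x) - 2)
    se = np.sqrt((s2 * np.linalg.inv(X.T @ X))[1, 1])
    pval = 2 * sps.t.sf(abs(beta[1] / se), len(x) - 2)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ols_err = max(abs(res.params[1] - beta[1]), abs(res.bse[1] - se),
                  abs(res.pvalues[1] - pval))
    return {"norm_rel_err": float(norm_err), "ks_abs_err": float(ks_err),
            "wind_interp_abs_err": float(interp_err),
            "ols_abs_err": float(ols_err)}


# ---------------------------------------------------------------------------
# 4. estimator calibration


def recovery_experiment(seed: int = 0, n_rep: int = 100, n: int = 5000) -> dict:
    """CI coverage of the free-mu fit and precision gain of fixed-mu."""
    p = BetplParams(1.5, 0.02, 0.5, 0.3)
    covered = 0
    l1_free, l1_fixed = [], []
    for k in range(n_rep):
        s = betpl_sample(p, n, seed=_sub_seed(seed, k))
        free = BetplGridFit(mode="free", lim_a=p.lim_a).fit(s)
        ok = all(free.ci_[name][0] <= truth <= free.ci_[name][1]
                 for name, truth in (("mu", p.mu), ("lambda1", p.lambda1),
                                     ("lambda2", p.lambda2)))
        covered += ok
        l1_free.append(free.lambda1_)
        l1_fixed.append(BetplGridFit(mode="fixed", lim_a=p.lim_a).fit(s).lambda1_)
    return {"joint_coverage": covered / n_rep,
            "sd_lambda1_free": float(np.std(l1_free)),
            "sd_lambda1_fixed": float(np.std(l1_fixed)),
            "n_rep": n_rep, "n": n}


# ---------------------------------------------------------------------------
# 5. pipeline power and specificity


def _cohort_beta1(scenario: str, seed: int, n_traj: int) -> dict:
    cohort = gen_cohort(n_traj, scenario, seed=seed)
    records, excl = build_trip_records(cohort.trajectories, wind=cohort.wind,
                                       mode="fixed")
    rr = regress_lambda_on_wind(records, "lambda1")
    return {"beta1": rr.beta, "p": rr.p, "n_records": rr.n,
            "n_excluded": len(excl)}


def power_specificity_experiment(seed: int = 0, n_seeds: int = 3,
                                 n_traj: int = 60) -> dict:
    """Wind-coupled cohorts must show significant negative beta1;
    wind-independent cohorts must not."""
    power_hits, spec_hits = 0, 0
    betas_c, betas_i = [], []
    for k in range(n_seeds):
        res = _cohort_beta1("wind_coupled", _sub_seed(seed, 100 + k), n_traj)
        betas_c.append(res["beta1"])
        if res["beta1"] < 0 and res["p"] < 0.05:
            power_hits += 1
        res = _cohort_beta1("wind_independent", _sub_seed(seed, 200 + k), n_traj)
        betas_i.append(res["beta1"])
        if res["p"] >= 0.05:
            spec_hits += 1
    return {"power_fraction": power_hits / n_seeds,
            "specificity_fraction": spec_hits / n_seeds,
            "beta1_wind_coupled_mean": float(np.mean(betas_c)),
            "beta1_wind_independent_mean": float(np.mean(betas_i)),
            "n_seeds": n_seeds, "n_traj": n_traj}


def discrimination_experiment(seed: int = 0, n_traj: int = 8) -> dict:
    """On exponential-truth trajectories the exponential branch
    (exponential or biexponential) must be better supported than the
    BETPL by AIC.  (A BETPL+exponential mixture can still edge out both
    on raw AIC since it embeds the exponential; the discriminating
    comparison is exponential-family against pure BETPL.)"""
    cohort = gen_cohort(n_traj, "exponential_null", seed=_sub_seed(seed, 1))
    hits = 0
    rows = []
    for traj in cohort.trajectories:
        row = compare_models(traj, mode="free", seed=_sub_seed(seed, 2))
        rows.append(row.best_family)
        if min(row.aic["exponential"], row.aic["biexponential"]) < row.aic["betpl"]:
            hits += 1
    return {"exponential_family_fraction": hits / n_traj,
            "best_families": rows, "n_traj": n_traj}


# ---------------------------------------------------------------------------
# 6. projection method validation


def projection_validation_experiment(seed: int = 0, n_steps: int = 10_000,
                                     mu_true: float = 2.0,
                                     lim_a_fit: float = 0.6) -> dict:
    """Pure-power-law walk -> axis-projection extraction -> exponent refit.

    The fit cutoff sits well above the generative lower bound (0.1 km)
    where projection smearing contaminates the body; the upper bound is
    the truncated-Pareto MLE (the sample maximum).
    """
    from .alternatives import AlternativeStepModel
    p = BetplParams(mu_true, 0.0, 0.0, 0.1, 600.0)
    traj = gen_betpl_walk(p, n_steps, seed=seed, fix_interval=None)
    track = project_to_plane(traj, max_speed_kmh=np.inf)
    pooled = extract_steps(track, 0.0, 1e-4).lengths
    s = np.sort(pooled[(pooled >= lim_a_fit) & (pooled <= 600.0)])
    est = AlternativeStepModel(family="powerlaw", lim_a=lim_a_fit,
                               l_max=float(s.max())).fit(s)
    return {"mu_true": mu_true, "mu_hat": est.params_["mu"],
            "abs_error": abs(est.params_["mu"] - mu_true), "n": int(s.size)}
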
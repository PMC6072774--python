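"""Uniform-sensitivity KS goodness of fit and (lim_a, theta) selection.

The plain KS statistic is most sensitive near the distribution median.
Dividing the CDF deviation by sqrt(P (1 - P)) equalizes sensitivity
across the whole range — essential for heavy-tailed step-length samples
where the action is in the tails.  For each trajectory the analysis
tries 72 parametrizations (18 lower cutoffs lim_a x 4 rotations theta)
and keeps the one with the smallest weighted KS distance among samples
with enough steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (L_MAX_KM, MIN_STEPS, PlanarTrack, StepSample,
                       Trajectory, extract_steps, project_to_plane)
from .model import BetplFit, BetplParams, betpl_cdf, betpl_sample, fit_betpl

#: the 18 candidate lower cutoffs (km) scanned per trajectory
LIM_A_SCAN = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90,
              1.00, 1.20, 1.40, 1.60, 1.80, 2.00, 2.50, 3.00)

#: rotation angles (degrees) guarding against preferred travel directions
THETA_SCAN = (0.0, 15.0, 30.0, 45.0)


@dataclass
class GofResult:
    D_weighted: float
    n: int
    lim_a: float
    theta: float
    p_boot: float | None = None


@dataclass
class ParametrizationScan:
    """All candidate rows for one trajectory plus the selected winner."""

    source_id: str
    table: pd.DataFrame
    selected: dict | None           # winning row as a dict, or None
    fits: dict = field(default_factory=dict)   # (lim_a, theta) -> BetplFit
    reason: str = ""                # why nothing was selected, if so


def weighted_ks(sample: StepSample, params: BetplParams) -> GofResult:
    """Weighted KS distance between a sample and a fitted BETPL.

    D = max over the sorted sample of |S(l) - P(l)| / sqrt(P(l)(1-P(l))),
    with S the empirical CDF (both one-sided limits at each point) and P
    the model CDF; points where P is exactly 0 or 1 are excluded.
    """
    l = np.sort(np.asarray(sample.lengths, dtype=float))
    if l.size == 0:
        raise ValueError("empty sample")
    if l[0] < params.lim_a or l[-1] > params.l_max:
        raise ValueError("sample outside model support")
    D = weighted_ks_from_cdf(np.asarray(betpl_cdf(l, params)))
    return GofResult(D_weighted=D, n=l.size, lim_a=sample.lim_a, theta=sample.theta)


def weighted_ks_from_cdf(P_sorted: np.ndarray) -> float:
    """Weighted KS distance given model CDF values at the sorted sample."""
    P = np.asarray(P_sorted, dtype=float)
    n = P.size
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    dev = np.maximum(np.abs(hi - P), np.abs(lo - P))
    denom = np.sqrt(P * (1.0 - P))
    ok = (P > 0.0) & (P < 1.0)
    if not ok.any():
        raise ValueError("model CDF degenerate on the sample")
    return float(np.max(dev[ok] / denom[ok]))


def bootstrap_p(sample: StepSample, fit: BetplFit, n_boot: int = 199,
                seed=None) -> float:
    """Parametric-bootstrap p-value for the weighted KS statistic.

    Simulates ``n_boot`` samples of the observed size from the fitted
    BETPL, refits each in the same mode, and returns the fraction of
    bootstrap D values at or above the observed one.
    """
    if n_boot < 99:
        raise ValueError("n_boot >= 99 required")
    mode = "fixed" if fit.fixed_mu else "free"
    d_obs = weighted_ks(sample, fit.params_mean).D_weighted
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        draw = betpl_sample(fit.params_mean, sample.n, seed=rng)
        boot = StepSample(lengths=draw, lim_a=sample.lim_a, theta=sample.theta,
                          source_id=sample.source_id, l_max=sample.l_max,
                          min_steps=1)
        bfit = fit_betpl(boot, mode=mode)
        if weighted_ks(boot, bfit.params_mean).D_weighted >= d_obs:
            count += 1
    return count / n_boot


def _pooled_steps_by_theta(track: PlanarTrack, thetas) -> dict:
    """Pooled unsorted axis-projection steps per rotation (before cuts)."""
    from .geometry import rotate, steps_1d
    out = {}
    for theta in thetas:
        rot = rotate(track, theta)
        pooled = np.concatenate([steps_1d(rot.x), steps_1d(rot.y)])
        out[theta] = pooled[pooled > 0]
    return out


def scan_parametrizations(traj: Trajectory, mode: str = "free",
                          lim_a_list=LIM_A_SCAN, thetas=THETA_SCAN,
                          l_max: float = L_MAX_KM, min_steps: int = MIN_STEPS,
                          keep_fits: bool = True) -> ParametrizationScan:
    """Fit every (lim_a, theta) candidate and select by weighted KS.

    The per-candidate fit runs in the same mode (free/fixed mu) as the
    downstream analysis so that selection and inference are consistent.
    Ties on D are broken by larger n, then smaller lim_a, then smaller
    theta (maximizing information, deterministically).
    """
    track = project_to_plane(traj)
    pooled = _pooled_steps_by_theta(track, thetas)
    rows, fits = [], {}
    for lim_a in lim_a_list:
        for theta in thetas:
            raw = pooled[theta]
            kept = raw[(raw >= lim_a) & (raw <= l_max)]
            sample = StepSample(lengths=np.sort(kept), lim_a=lim_a, theta=theta,
                                source_id=traj.id, n_raw=len(raw), l_max=l_max,
                                min_steps=min_steps)
            row = {"id": traj.id, "lim_a": lim_a, "theta": theta, "n": sample.n,
                   "sufficient": sample.sufficient}
            if sample.sufficient:
                fit = fit_betpl(sample, mode=mode)
                gof = weighted_ks(sample, fit.params_mean)
                fit.gof_D = gof.D_weighted
                row.update(
                    D=gof.D_weighted, mu=fit.params_mean.mu,
                    lambda1=fit.params_mean.lambda1, lambda2=fit.params_mean.lambda2,
                    mu_ml=fit.params_ml.mu, lambda1_ml=fit.params_ml.lambda1,
                    lambda2_ml=fit.params_ml.lambda2,
                    loglik=fit.loglik, boundary=fit.boundary,
                )
                if keep_fits:
                    fits[(lim_a, theta)] = fit
            else:
                row.update(D=np.nan, reason=f"{sample.n} steps < {min_steps}")
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["sufficient"]].copy()
    if ok.empty:
        return ParametrizationScan(source_id=traj.id, table=table, selected=None,
                                   fits={}, reason="insufficient steps at all parametrizations")
    ok = ok.sort_values(["D", "n", "lim_a", "theta"],
                        ascending=[True, False, True, True], kind="mergesort")
    sel = ok.iloc[0].to_dict()
    table["selected"] = (table["lim_a"] == sel["lim_a"]) & (table["theta"] == sel["theta"])
    return ParametrizationScan(source_id=traj.id, table=table, selected=sel, fits=fits)


def selected_fit(scan: ParametrizationScan) -> BetplFit | None:
    if scan.selected is None:
        return None
    return scan.fits.get((scan.selected["lim_a"], scan.selected["theta"]))
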
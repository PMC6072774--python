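# betpl

Wind-dependent Lévy-walk analysis of seabird GPS tracks, built around
the step-length law predicted by olfactory-cued navigation.

Pelagic birds such as shearwaters home over hundreds of kilometres of
featureless ocean, plausibly by navigating on wind-borne odors (e.g.
phytoplankton DMS). Because atmospheric turbulence delivers odor only
intermittently, a bird that flies straight while in contact with its
"odor map" and reorients when contact is lost should produce flight
segments whose lengths follow a **bi-exponentially truncated power law
(BETPL)**

```
p(l) = N l^(−μ) e^(−λ₁ l) e^(−λ₂ / l),   l ∈ [lim_a, 600 km]
```

with a universal exponent μ = 3/2, while the truncation parameters
track the odor signal: λ₁ ∝ 1/T and λ₂ ∝ T·c_τ²/C², where T is the
signal correlation time, C the mean odor concentration and c_τ the
detection threshold. Both T and C depend on mean wind speed U (the
volatile flux grows as U^γ, γ ∈ [2,3], and concentration dilutes as
C ∝ U^(γ−1)), so λ₁ and λ₂ must be wind-dependent while μ is not —
a falsifiable, mechanism-specific signature that this package tests on
trajectory data.

The package provides, for movement ecologists and biophysicists:

* **step extraction** from GPS fixes by the axis-projection
  turning-point method (planar projection, rotations θ ∈ {0,15,30,45}°,
  1-D direction reversals, pooled axes);
* **grid likelihood fitting** of the BETPL (mean-likelihood estimates,
  marginal-likelihood CIs, free-μ and fixed-μ = 3/2 modes) as
  scikit-learn-style estimators;
* **goodness-of-fit selection** of the lower cutoff lim_a (18 values ×
  4 rotations = 72 parametrizations per trajectory) by a
  uniform-sensitivity weighted KS statistic;
* **model comparison** against exponential, bi-exponential, power-law,
  upper-truncated power-law and BETPL+exponential families by AIC;
* **wind annotation** (trilinear interpolation of gridded 10-m wind to
  fixes, ⟨v⟩ / rms / cubic averages, head/tail decomposition) and the
  **hypothesis tests** (log–log OLS of λ on wind with CI/PI bands,
  μ-wind independence, μ-convergence, covariate ΔAIC screening);
* a **synthetic-data module**, including a mechanistic odor-threshold
  simulator in which the BETPL *emerges* from first passages of a
  drifting, diffusing concentration signal — μ = 3/2 is never an input.

## Worked example

Simulate a 16-trip wind-coupled cohort, run the scan pipeline and
regress the fitted λ₁ on mean wind:

```python
from betpl.synthetic import gen_cohort
from betpl.pipeline import build_trip_records
from betpl.regression import regress_lambda_on_wind

cohort = gen_cohort(16, "wind_coupled", seed=5)
records, excluded = build_trip_records(cohort.trajectories,
                                       wind=cohort.wind, mode="fixed")
rr = regress_lambda_on_wind(records, "lambda1")
print(f"beta1 = {rr.beta:.2f} +/- {rr.se:.2f}  (p = {rr.p:.2g}, n = {rr.n})")
```

prints

```
beta1 = -1.30 +/- 0.10  (p = 4e-09, n = 16)
```

i.e. the large-scale truncation weakens with wind speed with a log–log
slope of −1.30 ± 0.10, recovering the generator's λ₁ ∝ U^(−1.5)
coupling through the full extract → select → fit → annotate → regress
chain (the slope attenuates slightly because each λ̂₁ carries
estimation noise). Fitting a single sample directly:

```python
from betpl.model import BetplGridFit, BetplParams, betpl_sample

p = BetplParams(mu=1.5, lambda1=0.02, lambda2=0.5, lim_a=0.3)
fit = BetplGridFit(mode="free", lim_a=0.3).fit(betpl_sample(p, 5000, seed=7))
print(fit.mu_, fit.lambda1_, fit.lambda2_)   # 1.4996 0.0210 0.4976
print(fit.ci_["mu"])                         # (1.42, 1.57)
```

The same stages are scriptable from the shell:

```
betpl simulate --scenario wind_coupled --n 20 --seed 1 --out data/
betpl scan --tracks data/tracks.csv --mode fixed --out scan.csv
betpl wind-summarize --tracks data/tracks.csv --wind data/wind.csv --out ws.csv
betpl run --config run.toml
```

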
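# pagsem

Generalized structural equation modelling of latent physical-activity
dimensions and obesity in adult survey data.

Population surveys record weekly minutes of screen use (computer/smartphone,
television, video games) and transportation (motor vehicle, cycling,
walking) alongside obesity status (BMI ≥ 30 kg/m²). These six indicators are
noisy reflections of two unobserved behavioural dimensions — **Screens use**
and **Active transportation** — and the scientific question is how those
latent dimensions, together with sociodemographic covariates and
leisure-time physical activity, relate to obesity occurrence. `pagsem` is
for epidemiologists and biostatisticians who want that analysis as a
reproducible, testable pipeline.

## The model

One joint likelihood combines three sub-models:

* **Measurement**: each indicator time is Weibull with shape *k‌ⱼ* and scale
  exp(κⱼ + λⱼL) — an accelerated-failure-time form on the log scale, suited
  to the right-skew of weekly-minute data. One reference indicator per
  latent has λ fixed at 1.
* **Structural**: the latents (L₁, L₂) are bivariate normal with free
  residual covariance and means γ·PA, where PA is leisure-time physical
  activity (min/week).
* **Disease**: obesity is Bernoulli with a log link,
  log π = α + β₁L₁ + β₂L₂ + x′β, so exponentiated coefficients are
  prevalence ratios (the "modified Poisson" reading), with robust
  (sandwich) variance.

Estimation is maximum likelihood with adaptive Gauss–Hermite quadrature
over the latents (details in `docs/methods.md`). The package also provides
a synthetic survey generator whose defaults reproduce the published study
conditions, Table-1-style descriptives, measurement diagnostics
(KMO, Bartlett, distribution selection, exploratory loadings), direct and
indirect (path-product) effects, empirical-Bayes adherence scores with
tertiles, and department-level prevalence/adherence attribute tables.

## Worked example

```python
from pagsem import SyntheticConfig, generate_dataset
from pagsem.descriptives import weighted_prevalence
from pagsem.diagnostics import indicator_correlations, kmo_statistic, bartlett_sphericity
from pagsem.synthetic import INDICATORS

ds = generate_dataset(SyntheticConfig(), seed=42)   # n = 9,658 persons
df = ds.data

est = weighted_prevalence(df["obesity"].to_numpy(), df["expansion_factor"].to_numpy())
print(f"prevalence {est.estimate:.3f} ({est.ci_low:.3f}, {est.ci_high:.3f})")

R, n = indicator_correlations(df, INDICATORS)
kmo, _ = kmo_statistic(R)
bart = bartlett_sphericity(R, n)
print(f"KMO {kmo:.3f}, Bartlett {bart.statistic:.1f} (df {bart.df}, p {bart.p_value:.2g})")
```

prints

```
prevalence 0.185 (0.178, 0.193)
KMO 0.673, Bartlett 9422.5 (df 15, p 0)
```

— the simulated obesity prevalence sits at the calibrated ~19% with a
survey-weighted Wald interval, and the sphericity test confirms the
indicator correlations induced by the two latent dimensions. Fitting the
joint model and decomposing effects:

```bash
pagsem simulate --n 9658 --seed 42 --out data.csv
pagsem fit      --in data.csv --out fit.json
pagsem effects  --fit fit.json --out table2.csv
pagsem score    --fit fit.json --in data.csv --out scores.csv
pagsem map-summaries --in data.csv --scores scores.csv --out departments.csv
```

or everything at once with a manifest:

```bash
pagsem run --config study.yaml --outdir results/
```

where `study.yaml` holds one seed and optional overrides:

```yaml
seed: 42
n_persons: 9658
synthetic: {latent_corr: 0.2}   # any generator field
fit: {n_quad: 15, max_iter: 500}
score: {condition_on_outcome: true}
```

The run writes `data.csv`, `table1.csv`, `diagnostics.json`, `fit.json`,
`effects.csv`, `scores.csv`, `departments.csv` and a `manifest.json` with
content digests; rerunning the same config and seed reproduces the digests.

`table2.csv` contains one row per disease-model term with the prevalence
ratio, 95% CI and p-value (robust variance), plus indirect rows carrying
the unexponentiated path products γ̂·β̂ — e.g. a leisure-PA →
Active-transportation path of 0.00424 per min/week combined with a latent
prevalence-ratio coefficient of ln(0.86) yields an indirect effect near
−0.0006.

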
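# trdspat

Spatially adjusted analysis of **tobacco retailer density (TRD)** at the
census-tract level.

Tobacco retailers cluster where people are poor, and — in most US states
examined to date — where tracts are rural. Quantifying those disparities
means modelling a per-capita rate (retailers per 1000 residents) over
thousands of small areal units whose residuals are spatially
autocorrelated: tracts near each other have more similar densities than
their covariates explain, and analyses that ignore this understate
standard errors. `trdspat` packages the full workflow:

* **Data model** (`trdspat.tract_data`) — census tracts with population,
  retailer counts (supplied directly or assigned from geocoded retailer
  points by point-in-polygon lookup, with near-duplicate removal),
  sociodemographic percentage covariates, USDA Rural–Urban Commuting Area
  (RUCA) primary codes collapsed to four rurality levels (Metropolitan
  1–3, Micropolitan 4–6, Small Town 7–9, Rural 10), and
  Appalachian-county indicators. Tracts with population below 100 are
  filtered before modelling.
* **Descriptives** (`trdspat.descriptives`) — median/IQR summaries of the
  TRD distribution by rurality, and Pearson correlations of
  log(TRD + 0.01) with covariates.
* **Core model** (`trdspat.nbgee`) — negative binomial regression with
  log link and offset log(population/1000), covariates scaled so each
  slope is the change in mean log TRD per 10-percentage-point increase.
  Dispersion is profiled by maximum likelihood. Inference uses a
  GEE-style sandwich covariance `A⁻¹BA⁻¹` whose middle matrix carries a
  working spatial correlation (exponential-decay kernel in tract-centroid
  distance, or contiguity indicator) fitted to the model's Pearson
  residuals by a method of moments that corrects for the attenuation
  induced by coefficient estimation.
* **Effects & contrasts** (`trdspat.effects_contrasts`) — multiplicative
  TRD changes `exp(β·Δ/10)` with Wald CIs, pairwise rurality density
  ratios with Bonferroni-simultaneous intervals, conditional Appalachia
  effects from poverty-by-Appalachia interactions, and effect curves
  clipped to observed covariate ranges.
* **Diagnostics** (`trdspat.diagnostics`) — NB deviance residuals and
  Moran's *I* (permutation, normal-approximation, or exhaustive modes)
  under queen-contiguity weights.
* **Synthetic data** (`trdspat.synthetic_tracts`) — lattice "states" with
  smooth poverty fields, county-block ethnic compositions, concentric
  rurality rings, an Appalachian block, and NB counts with a spatially
  correlated Gaussian random effect, so every estimator can be validated
  against known truth.

## Worked example

The package ships the published marginal-model coefficient tables for
California, Connecticut, North Carolina and Ohio
(`trdspat.examples`). Pushing them through the effect machinery:

```python
from trdspat.examples import fit_from_table, NC_POVERTY_MEDIAN
from trdspat import multiplicative_effect, ruca_ratio, conditional_appalachia_effect
from trdspat.tract_data import RucaLevel

fit = fit_from_table("NC")
eff = multiplicative_effect(fit, "pct_poverty")
print(f"NC poverty: x{eff.ratio:.2f} per 10-point increase "
      f"(95% CI {eff.ci_low:.2f}-{eff.ci_high:.2f})")

r = ruca_ratio(fit_from_table("CA"), RucaLevel.RURAL, RucaLevel.METROPOLITAN)
print(f"CA rural vs metro TRD ratio: {r.ratio:.2f} "
      f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")

a = conditional_appalachia_effect(fit_from_table("NC", model=2), NC_POVERTY_MEDIAN)
print(f"NC Appalachian vs non-Appalachian at median poverty: x{a.ratio:.2f}")
```

prints

```
NC poverty: x1.24 per 10-point increase (95% CI 1.18-1.29)
CA rural vs metro TRD ratio: 1.87 (95% CI 1.52-2.30)
NC Appalachian vs non-Appalachian at median poverty: x1.31
```

i.e. a 10-point rise in tract poverty multiplies expected retailer
density by 1.24 in North Carolina; rural Californian tracts carry 1.87
times the density of metropolitan ones; and at the NC median poverty
level (12.4%), Appalachian tracts have 1.31 times the density of
non-Appalachian tracts. (CIs built from the published tables treat
coefficients as uncorrelated, since covariance off-diagonals are not
published; ratios are exact.)

## Command-line pipeline

```sh
echo 'scenario: paperlike' > config.yaml
trdspat simulate --config config.yaml --out out --seed 1
trdspat fit       --config config.yaml --out out --seed 1
trdspat contrasts --config config.yaml --out out --seed 1
trdspat diagnose  --config config.yaml --out out --seed 1
```

fits the synthetic 30×30-lattice state (900 tracts; true rural-vs-metro
log ratio 0.4, poverty slope 0.2 per 10 points, dispersion θ = 5, spatial
random-effect SD 0.3) and writes, among other files,
`coefficients_SY.csv`:

```
term               estimate   model_se  sandwich_se   z       p
intercept          -0.500     0.219     0.399        -1.25    0.211
pct_poverty         0.183     0.017     0.026         7.10    1.2e-12
...
ruca_Rural          0.524     0.096     0.180         2.90    0.0037
```

Note the sandwich SEs running ~1.5–2× the independence-based model SEs —
that gap is the spatial correlation the adjustment exists for. Replace
`scenario:` with `tracts:`/`polygons:` paths (CSV + GeoJSON, schemas in
`trdspat.tract_data`) to analyse real data.

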
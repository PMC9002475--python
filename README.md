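# vegattrib

Attribution of vegetation change to climate and human drivers on gridded
monthly data: multi-scale SPEI water availability, pixelwise trend
detection, NDVI–SPEI correlation structure across timescales, and
residual-trend (RESTREND) separation of climate-driven from human-driven
greenness change.

## Who this is for

Researchers in ecological remote sensing who have ~30 years of monthly
gridded mean temperature (°C), precipitation PRE (mm), potential
evapotranspiration PET (mm) and NDVI, plus categorical land-cover and
climate-region masks, and want to answer: *where did vegetation improve or
degrade, how strongly is greenness coupled to water availability at which
timescale, and what share of the change is attributable to climate versus
human activity?* A seeded synthetic-scene generator with known ground
truth is a first-class part of the package, so every stage can be
validated end to end before touching real rasters.

## The method

**Water availability.** The climatic water balance D = PRE − PET is
accumulated over k ∈ {1, 3, 6, 12} months (window ending in the indexed
month). Per calendar month, a three-parameter log-logistic distribution is
fitted to the accumulated values by unbiased probability-weighted moments
and the fitted probabilities are mapped to standard-normal units — the
SPEI-k. SPEI < −1 is drought. PET can be derived from air temperature via
the Hargreaves equation, PET = 0.0023 · Ra · (T + 17.8) · √(Tmax − Tmin),
with Ra from standard solar geometry.

**Trends.** Per pixel, annual series get a Theil–Sen slope (median of
pairwise slopes), a Mann–Kendall Z (tie-corrected, continuity-corrected),
an OLS slope, and a 4-way category split at |Z| = 1.96: significant
decrease / decrease / increase / significant increase. A 5-year centered
moving average supports time-series plots.

**Correlation structure.** For growing-season months i (Apr–Oct) and
scales j, R_ij = cor(NDVI_i, SPEI_ij) across years. Per scale, the
coefficient of maximal |R| over months is kept — sign retained — and the
overall maximum R_max with its timescale maps where and on what horizon
water availability grips vegetation. The *maximum water surplus period* is
the largest scale still negatively correlated (drying still benefits
growth). First-order partial correlations give NDVI–PRE controlling PET
and NDVI–PET controlling PRE.

**Attribution.** Growing-season NDVI is regressed on growing-season PRE
and PET (OLS with intercept): NDVI_pre = a·PRE + b·PET + ε is the
climate-predicted part, NDVI_res = NDVI_obs − NDVI_pre the human signal.
Because OLS slopes add exactly (slope_pre + slope_res = slope_obs), the
sign pattern of the three slopes selects one of six scenarios and yields
climate/human contribution percentages that always sum to 100:

| slope_obs | slope_pre | slope_res | climate % | human % |
|-----------|-----------|-----------|-----------|---------|
| > 0 | > 0 | > 0 | 100·slope_pre/slope_obs | 100·slope_res/slope_obs |
| > 0 | > 0 | < 0 | 100 | 0 |
| > 0 | < 0 | > 0 | 0 | 100 |
| < 0 | < 0 | < 0 | 100·slope_pre/slope_obs | 100·slope_res/slope_obs |
| < 0 | < 0 | > 0 | 100 | 0 |
| < 0 | > 0 | < 0 | 0 | 100 |

An optional strict mode additionally requires Mann–Kendall significance
before a component counts as trending. Zonal summaries aggregate any
result raster by land cover, climate region or R_max timescale.

## Worked example

```python
import numpy as np
import vegattrib as va

cfg = va.SyntheticConfig(n_rows=20, n_cols=20, seed=42)   # 29 years monthly
scene = va.generate_scene(cfg)

spei = va.spei_grid(scene.pre, scene.pet)                  # scales 1/3/6/12
s12 = spei[12].data[:, 6, 0, 0]                            # July, pixel (0,0)
print(np.nanmean(s12).round(3), np.nanstd(s12).round(3))   # -0.001 0.974

att = va.attribution_grid(scene.ndvi, scene.pre, scene.pet,
                          landcover=scene.landcover, strict=True)
print(np.nanmean(att.fit.a).round(5))                      # 0.00399
print(np.nanmean(att.fit.b).round(5))                      # -0.00146
```

The SPEI comes back standardized (mean ≈ 0, SD ≈ 1 per calendar month);
the regression recovers the generator's coefficients a = 0.004 and
b = −0.0015 NDVI/mm. The attribution summary
(`att.summaries`) shows the implanted block structure: land-cover classes
with a positive implanted human trend are attributed ~97–99% to human
activity in their greening pixels, mirrored for the degrading classes —
97.9% of valid pixels land in their true scenario.

The same pipeline runs from the shell:

```bash
vegattrib simulate --seed 42 --rows 20 --cols 20 --out scene/
vegattrib spei --pre scene/pre.nc --pet scene/pet.nc --out spei/
vegattrib restrend --ndvi scene/ndvi.nc --pre scene/pre.nc --pet scene/pet.nc --out att/
vegattrib report --seed 42 --out run/     # full end-to-end pipeline
```

## Layout

```
src/vegattrib/
  grids.py        MonthlyGrid container (year, month, y, x)
  synthetic.py    seeded scene generator with per-pixel ground truth
  spei.py         accumulation, log-logistic PWM fit, SPEI, Hargreaves PET
  trends.py       Theil-Sen, Mann-Kendall, OLS, categories, smoothing
  correlation.py  month x scale correlation field, R_max, partial corr.
  restrend.py     climate model fit, residual trends, scenario engine
  zonal.py        area percentages and distribution statistics by class
  io.py           NetCDF/TIFF stacks, YAML pipeline config
  pipeline.py     end-to-end driver
  cli.py          vegattrib simulate|spei|trends|correlate|restrend|report
```
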
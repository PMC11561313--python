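# fuzzysdm

Fuzzy-logic species distribution modelling: presence/background SDMs, the
prevalence-free **environmental favourability** transform, and fuzzy-set
comparison of habitat surfaces — with a built-in virtual-species generator
so every analysis runs fully synthetic and reproducible.

## The problem

Species distribution models (SDMs) fitted to presence/background data
predict a probability of presence *P* that is tied to the **prevalence**
n₁/(n₁+n₀) of the training sample: a restricted species gets uniformly low
probabilities, a widespread one uniformly high, which makes maps of
different species incomparable. The favourability function removes that
dependence. For a logistic model

  P = e^(α+β₁x₁+⋯+βₙxₙ) / (1 + e^(α+β₁x₁+⋯+βₙxₙ)),

the favourability of a site is

  F = (P/(1−P)) / (n₁/n₀ + P/(1−P)),

equivalently the same logistic model with its intercept shifted to
α − ln(n₁/n₀). F = 0.5 exactly where P equals the training prevalence, and
F is a fuzzy membership degree in the set "areas favourable to the
species", directly comparable across species. On favourability surfaces
the package computes fuzzy intersections and unions (cellwise min/max),
the fuzzy overlap index FOvI = Σmin/Σmax, fuzzy and binary Jaccard
similarity, ten-bin shared-favourability profiles with confidence
intervals, and Kosko fuzzy entropy Σmin(μ,1−μ)/Σmax(μ,1−μ).

Intended users: ecologists and biosecurity analysts comparing potential
distributions of two or more species (e.g. invasive pests) across one
landscape, and method developers who need a controlled synthetic testbed.

## What is in the box

| module | contents |
|---|---|
| `fuzzysdm.synthetic` | correlated random predictor landscapes, virtual species with logistic niches, presence & background sampling |
| `fuzzysdm.preprocess` | spThin-style spatial thinning; Pearson-correlation predictor pruning (\|r\| > 0.8 rule) |
| `fuzzysdm.sdm` | GLM, spline GAM, boosted trees, Maxent-like (L1 PPM surrogate with cumulative output); stratified 5×10 cross-validation; raster prediction |
| `fuzzysdm.fuzzy` | favourability, fuzzy ops, FOvI, Jaccard similarity matrices, shared-favourability profile & plot, fuzzy entropy |
| `fuzzysdm.evaluation` | rank AUC, TSS/CCR/sensitivity/specificity, Hosmer–Lemeshow calibration test (decile bins) |
| `fuzzysdm.io` / `fuzzysdm.pipeline` / `fuzzysdm.cli` | ESRI ASCII grid + CSV/JSON formats, the end-to-end pipeline driver, `fuzzysdm` CLI |

## Worked example

```python
import numpy as np
import fuzzysdm as fz

# virtual landscape + two species with overlapping niches
grid, sp_a, sp_b, occ_a, occ_b, background = fz.default_study(
    seed=1, n_rows=50, n_cols=50, n_background=2000)

table = fz.build_table(grid, occ_a, background)
model = fz.fit(table, "glm")
prob = fz.predict_surface(model, grid)                   # P in [0, 1]
fav_a = fz.favourability_surface(prob, model.n1, model.n0)

table_b = fz.build_table(grid, occ_b, background)
model_b = fz.fit(table_b, "glm")
fav_b = fz.favourability_surface(fz.predict_surface(model_b, grid),
                                 model_b.n1, model_b.n0)

print(f"mean P  a: {np.nanmean(prob.values):.3f}")
print(f"mean F  a: {np.nanmean(fav_a.values):.3f}")
print(f"FOvI(a,b): {fz.fuzzy_overlap_index(fav_a, fav_b):.3f}")
print(f"entropy a: {fz.fuzzy_entropy(fav_a):.3f}")
```

prints

```
mean P  a: 0.090
mean F  a: 0.403
FOvI(a,b): 0.738
entropy a: 0.440
```

Mean probability (0.090) sits at the training prevalence
(222/(222+2000) ≈ 0.10) — the low-prevalence species looks "improbable"
everywhere — while mean favourability (0.403) is pulled toward 0.5: the
prevalence correction at work. The FOvI of 0.738 says the two species'
favourable areas overlap substantially; the entropy of 0.440 measures how
far the surface sits from the crisp 0/1 extremes.

The same study runs from the shell:

```bash
fuzzysdm run --demo --seed 1 --scale 0.2 --out demo_out
```

writing probability/favourability/suitability rasters (`.asc`),
intersection maps, comparison reports, shared-favourability plots,
cross-validation tables and a manifest into `demo_out/`.

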
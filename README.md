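# nichepheno

Integrated species-distribution and phenotypic-distribution modelling for
detecting population differentiation and defining ecotypes in managed
animal populations — built around the study design used for scavenging
indigenous chickens sampled along elevational gradients.

Smallholder poultry populations are shaped by strong local selective
pressures (heat, radiation, precipitation, feed availability).  Whether
phenotypically distinct groups of populations ("ecotypes") coincide with
distinct environmental niches is a question that neither habitat models
nor trait analyses answer alone.  `nichepheno` couples the two:

1. **SDM (species distribution model).**  A presence-background maximum
   entropy model estimates habitat suitability from occurrence points and
   environmental raster layers.  The raw output is the distribution
   `p(x) = exp(λ·f(x)) / Z` over background cells, with features `f`
   (linear, quadratic, product, hinge, threshold transforms of the
   covariates) and L1 penalty `β_j = RM·s_j/√m`.  Feature-class
   combinations and the regularization multiplier RM are tuned on a
   6 × 8 grid (48 model runs) by small-sample AICc; background sampling
   can be bias-corrected with a kernel-density surface; variables are
   pruned by percent contribution (< 4 %) and pairwise correlation
   (|r| > 0.6), and ranked by jackknife gains.
2. **Niche clustering.**  Per-population suitability maps are compared
   with overlap statistics — `I = 1 − ½Σ(√p−√q)²` (Hellinger-based),
   Schoener's `D = 1 − ½Σ|p−q|` — and sites are grouped into niches by
   agglomerative clustering (Ward, complete, average, single linkage,
   with agglomerative coefficients).
3. **Ecotype definition.**  Discriminating traits are selected by
   stepwise discriminant analysis on partial Wilks' Λ (F-to-enter /
   F-to-stay per sex); populations are clustered on standardized trait
   means (Ward), with the cluster count chosen by the average-silhouette
   method; least-squares means summarize trait differences.
4. **Concordance.**  Each ecotype is matched to its modal niche and the
   within/outside split is scored against alternative environment
   classifications (elevation bands, gradients, custom schemes).
5. **PDM (phenotypic distribution model).**  Per trait, a penalized
   Gaussian GAM `E(y_i) = α + β_j + γ_m + Σ_k f_k(X_ki)` with ecotype and
   niche as factors and Gaussian-process (Matérn ν = 3/2) smooths of the
   SDM-selected covariates, smoothing parameters by REML; reports edf,
   AIC, adjusted R², deviance explained, Wald smooth significance, and
   partial-dependence curves with 95 % intervals.

A synthetic-landscape generator reproduces the study design (4 gradients
× 3 elevation bands, 26 populations, 15 hens + 5 cocks each, 19 traits
with 8 carrying ecotype signal, 34 environmental layers with correlated
pairs) with known ground truth, so the whole pipeline is testable
offline.

## Worked example

```python
import nichepheno as nf
from nichepheno import geodata as gd, maxent as mx

cfg = nf.LandscapeConfig(grid_shape=(60, 60), n_layers=12, seed=0)
stack, sites, truth, traits = nf.simulate_study(cfg)
occ = nf.expand_occurrences(sites, n_extra=9, extent=stack.extent)
print(len(sites), len(occ.records))
# 26 260    <- 26 sites, each one center + nine 1.2-km lattice points

pres = gd.extract_env(occ, stack)
cells = stack.cell_table()
res = mx.tune(pres, cells, [n for n in stack.layer_names
                            if n != "elev"][:5], cells, n_knots=5)
print(len(res.table), res.selected["combo"], float(res.selected["rm"]))
# 48 LQHPT 0.5   <- 6 feature combos x 8 multipliers, best by deltaAICc
```

The `48` is the tuning-grid cardinality (every feature-combo ×
regularization-multiplier cell is fitted and ranked by deltaAICc); the
selected row is the configuration used for the suitability maps.

Concordance between phenotype-defined ecotypes and SDM niches, on the
reference 26-population membership table bundled with the package:

```python
from nichepheno import concordance as cc
mem = cc.field_study_membership()
ct = cc.concordance_table(mem.set_index("population")["ecotype"],
                          mem.set_index("population")["niche"])
print(ct.per_ecotype["within"].tolist(), ct.overall_count,
      ct.overall_pct_mean)
# [8, 3, 6] 17 64.5
```

Per ecotype, 8 of 12, 3 of 5 and 6 of 9 populations lie in their
ecotype's modal niche (66.7 %, 60.0 %, 66.7 %); 17 of 26 populations are
correctly classified overall.  `64.5` is the unweighted mean of the
per-ecotype percentages; the exact ratio (65.4 %) is reported alongside.

The full workflow also runs from the shell:

```bash
nichepheno all --seed 1 --outdir out/        # simulate ... report
nichepheno sdm --config my_config.yaml       # one stage, from artifacts
```

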
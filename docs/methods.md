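# Methods

This note documents the models implemented in `nichepheno`, the choices
made where the design was open, and what the synthetic study does and
does not establish.

## Synthetic study design

The generator emulates a gradient-sampling field survey.  Defaults:

- **Grid** 120 × 120 cells at 0.01° (tests and the acceptance suite use
  60 × 60 with 10–12 layers; these sizes keep a full fit in seconds
  while leaving every band and gradient populated).  Four vertical
  gradient strips separated by 4 no-data columns hold monotone elevation
  ramps (≈370–3580 m, alternating direction) with a slight lateral tilt
  so cells within a band differ.
- **Bands** 400–1800, 1800–2400, 2400–3500 m.a.s.l. (closed left, open
  right).  One site per population: 4 gradients × 3 bands × 2
  populations + 2 extra (to the first two clusters) = 26 sites, kept
  ≥ 3 cells apart and ≥ 2 cells from strip borders so the 3 × 3
  occurrence lattice (1.2 km spacing, ≈ 1.1 cells) stays on data cells.
- **Layers** (default 34: elevation + 23 bioclim-like + 8 soil + 2
  vegetation): each non-elevation layer is a smooth function of scaled
  elevation (linear, quadratic, or saturating, cycled) plus a Gaussian
  random field (white noise smoothed with a σ = 3-cell filter, scaled to
  0.3 × the signal SD).  Configured correlated pairs are rebuilt by
  exact projection, so the realized Pearson r equals the target.
- **True suitability**: inverse-logit of a linear/quadratic form in
  named scaled layers, min-max rescaled.  The default truth uses three
  drivers with weights (+6 linear, −12 quadratic centred at 0.5, −4
  linear): strong enough that the habitat structure dominates the
  field noise — with weak weights the three elevation-driven covariates
  largely cancel and no estimator could recover the surface from 260
  points.
- **Traits**: `y = α_t + δ_t·pattern[ecotype] + sex_t + amp·sin(2πz_k) +
  ε`, ε ~ N(0, 1).  True ecotype = elevation band.  Eight signal traits
  (codes BW, BL, WS, CL, CW, EW, WW, KL; baselines at realistic
  adult-bird magnitudes) carry shifts of 1.2–2.0 SD in cycled patterns
  plus a 0.4-SD environmental smooth; eleven null traits carry neither.
  Effect sizes are in residual-SD units (taken as one trait unit at zero
  noise, so zero-noise runs reproduce the injected shifts exactly).
  Within-population variances are not published for the real study;
  the 1-SD default is set from the order of magnitude of reported
  standard errors and is configurable.

What the generator does *not* emulate: spatial autocorrelation of
residual trait variation, measurement error structure, unbalanced
sampling (the real survey lost 7 birds of 520), admixture between
populations, and real geography.  Passing recovery tests therefore show
the estimators work when their assumptions hold, not that the field
estimates themselves are correct.

## Maximum-entropy SDM

Features are built from background min/max normalizers: L (scaled
layer), Q (its square), P (pairwise products), T (step indicators), H
(forward and reverse hinges), knots equally spaced inside the background
range (default 10; 5–8 at desk scale).  Categorical features are not
implemented (no categorical layers in scope).

Fitting maximizes `mean_pres(λ·f) − ln Σ_bg exp(λ·f) − Σ β_j|λ_j|` by
cyclic coordinate descent: a soft-thresholded Newton step per feature,
backtracked (step halving, up to 20×) until the objective does not
decrease, so the objective is non-decreasing by construction;
convergence when a full cycle improves by < 1e-7 (cap 500 cycles;
non-convergence flags the model rather than raising).  The penalty scale
`β_j = RM·max(s_j, 0.05)/√m` (presence SD, floored) is a single-formula
simplification of the class-specific penalty tables of the reference
MaxEnt implementation; hooks for per-class tables were not needed at
this scale.  Entropy is computed as `H = lnZ − E_p[λ·f]`, which is exact
for the uniform model, making the logistic identity (uniform → 0.5)
hold to the bit.  Logistic output is the default (as in the modelled
workflow); cloglog is available behind a flag.

AICc standardizes the raw distribution over **all valid cells** (the
ENMeval convention), not background only; this shifts logLik by a
constant and is stated because model ranking depends on it.  Duplicate
occurrence cells are kept — the 10-points-per-site design intentionally
re-samples local environment; thinning is available but off.

Percent contribution credits each accepted coordinate-descent update's
objective increase to the updated feature's source variable (negatives
floored, normalized to 100).  Jackknife gains refit with each variable
alone / left out.  Variable selection iterates fit → drop
contribution < 4 % → drop the lower-contribution member of pairs with
|r| > 0.6 → refit until stable.  Spatial blocks (2 × 2 lon/lat median
splits) are provided for held-out evaluation.

## Niche clustering

Overlap statistics normalize each suitability map to sum to one over the
shared data cells.  `I ≥ D` is not asserted (not a theorem); symmetry,
bounds, and self-overlap = 1 are.  For clustering, the default distance
is the Euclidean distance between rows of the I-matrix (two populations
are similar when they relate to all others alike); a direct `1 − I` mode
exists because the source workflow is ambiguous between the two
readings.  Ward follows the squared-distance (ward.D2) convention.  The
agglomerative coefficient is the mean over leaves of one minus the
ratio of first-merge to final-merge height.  Trees are cut by group
count (default 3) — published cut heights are data-scale specific —
and labels are numbered in dendrogram left-to-right order.

## Trait selection and ecotype clustering

Stepwise discriminant analysis enters the candidate minimizing partial
Wilks' `Λ(t|S) = Λ(S∪t)/Λ(S)` when `F = ((n−g−s)/(g−1))(1−Λ)/Λ` has
`p ≤ SLE`, then removes entered traits with removal `p > SLS`
(defaults SLE = SLS = 0.15, the common stepwise default; the source
study states none).  Ties break on larger partial R², then column
order.  Selection runs per sex; ecotype clustering uses hen means by
default (the larger sample).  Note the entry scan takes the minimum p
over all remaining candidates, so with ~11 null candidates the
family-wise chance of at least one spurious entry at SLE = 0.05 is
≈ 1 − 0.95¹¹ ≈ 43 % per run — an intrinsic property of stepwise entry
that users should weigh when interpreting small selected sets.

Populations are clustered on standardized population means of the
selected traits (the natural population-level reduction; the aggregation
is not specified in the modelled workflow).  The silhouette scan cuts
the Ward tree at each k and picks the argmax of the mean width.
LS means come from per-sex one-factor OLS (equal to raw group means in
balanced designs), with pairwise t-tests and compact letter display
(letters = maximal cliques of the non-significance graph).

## Concordance

"Correctly classified" = membership in the ecotype's modal class (ties
to the lower class index, flagged).  Two overall percentages are
emitted: the exact ratio `100·Σwithin/n`, and the unweighted mean of the
per-ecotype percentages rounded to one decimal — the latter matches the
convention of comparable published tables (where 8/12, 3/5, 6/9 is
printed as 64.5 % overall rather than 17/26 = 65.4 %).  Elevation bands
are closed-left/open-right for deterministic boundaries.

## Penalized Gaussian GAM

Smooths use a knot-kernel basis: `B = K(x, knots)` with a Matérn
ν = 3/2 kernel (range = covariate span/2 by default; the reference
workflow specifies only a Gaussian-process basis), penalty
`S = K(knots, knots)`, knots at quantiles (default dimension 10; 6–8 in
the pipeline).  A cubic P-spline basis (B-splines + second-difference
penalty) is the alternative.  Each smooth gets a sum-to-zero constraint
over observed values via a null-space reparameterization, absorbing one
degree of freedom.  Aliased factor columns (e.g., ecotype ≡ niche) are
dropped by pivoted QR with a warning.

Smoothing parameters maximize the Gaussian restricted likelihood with
the scale profiled out (`σ̂² = (RSS + pen)/(n − M_p)`), optimized by a
coordinate-wise grid on log λ ∈ [−6, 12] (19 points, two passes) plus a
Nelder–Mead polish.  `edf_k = tr(F_kk)` with `F = (XᵀX + S_λ)⁻¹XᵀX`;
`AIC = −2·logLik_ML + 2(edf + 1)` (the +1 is the scale parameter —
stated because cross-model comparisons depend on the convention);
adjusted R² and deviance explained as in the standard GAM summaries.

Smooth significance is a Wald block test with the penalized (Bayesian)
covariance and reference df = rounded edf — a documented approximation
to the reference implementation's test; its contract here is the
simulated type-I rate ≤ 0.10 at α = 0.05 (measured ≈ 0.03–0.05) and
power p < 0.001 for a strong sinusoid.  Partial-dependence curves are
the centred smooth on an equally spaced grid spanning the observed
range, ± 1.96·SE.

## Pipeline

Stages (simulate, sdm, niches, ecotypes, concord, gam, report) read and
write artifacts in one output directory with SHA-256 manifests; stage
seeds derive from the root seed via `SeedSequence([root, stage_index])`.
The per-population suitability maps are fitted with LQ features and
RM = 1 on the selected variables (10 points per population support only
low feature complexity).  The default tuning grid is the full 6 × 8;
tests and examples shrink the grid and the landscape, not the method.

## Known limitations

- The MaxEnt penalty is a single-formula approximation; coefficients
  differ in detail from implementations with class-specific penalties.
- Wald smooth p-values are approximate (no unpenalized-rank correction).
- The stepwise entry rule carries the multiplicity property noted above.
- No projected CRS support; kilometre offsets use cos-latitude scaling.
- No spatial residual correlation in the GAMs; one model per trait.
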
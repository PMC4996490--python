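# Methods

This note documents the statistical model, the synthetic survey generator,
the numerical choices, and the known limitations of the `eaglersf`
pipeline.

## 1. The estimation pipeline

**Detection adjustment.** Aerial observers detect an eagle group with a
stratum-specific mean probability P̄ₜ (stratum = observation type
{perched at 107 m AGL, perched at 150 m AGL, flying} × observer position
{back-left, combined right, front-right}).  Every detected group of size
*g* contributes *g*/P̄ₜ to its sampling unit — the Horvitz–Thompson
correction, unbiased for the latent total when P̄ₜ is correct.  Groups are
inflated as whole groups, not per individual.  The nine published
probabilities and SEs ship with the package (`DetectionTable.standard()`)
and are consumed as data; estimating them is out of scope.  By default
right-side observations use the combined right-side probability; a
two-observer configuration switches to the front-right column.

**Pseudocounts.** Inflated contributions are summed per unit across survey
years and rounded half away from zero to integer pseudocounts (the rule is
explicit in `round_half_away` and swappable).  Rounding is applied once
per sampled unit instance.

**The RSF.** Pseudocounts follow an offset NB2 regression,
ln E[count_i] = ln(n.years_i) + Xβ, variance μ + μ²/θ.  The offset
standardises coefficients to one survey-year of effort.  Quadratic terms
are available for elevation, slope, NDVI and solar radiation; a quadratic
may only appear with its linear parent.  The categorical aspect expands to
S/E/W indicators with N as the reference level (the reference is a
documented package choice; flat cells in synthetic aspect fields are
assigned a quadrant by the field generator, so no "flat" class exists).

**Selection.** Before fitting, covariate pairs with |Pearson r| > 0.6 are
flagged and only one member may enter the full model; which member is the
caller's choice (biological relevance is not computable), with defaults
dropping slope, NDVI and the rare water/ice/snow class.  Correlated
candidates can be adjudicated by univariate AIC with the same offset NB
model.  The final model comes from backwards single-term BIC removal: at
each step the deletion that lowers BIC most is applied; removal stops when
no deletion lowers BIC.  Aspect leaves as a block; linear terms are locked
while their quadratic remains.  The trace records each step's BIC and the
maximum relative change in surviving coefficients — the multicollinearity
stability monitor.

**Diagnostics.** Goodness of fit uses the residual deviance (sum of
squared NB2 deviance residuals) against chi-square with n − (p+1) degrees
of freedom.  Spatial autocorrelation uses Moran's I on deviance residuals
with binary weights w_ij = 1 for centre distances in (0, 200] km
(row-standardised weights optional); I > 0.20 is flagged.

**Inference.** Confidence intervals come from a transect bootstrap:
whole transects are resampled with replacement (original count), all unit
instances on a selected transect enter with its multiplicity, one
detection probability per stratum is redrawn from N(P̄ₜ, SE) truncated to
(0.01, 1], pseudocounts are recomputed and the *fixed* final model is
refitted.  The central 90% of each coefficient's draws is the interval
(percentile method, default 1,000 iterations).  Model structure is not
reselected inside the bootstrap, units are not re-drawn, and the
truncation floor (configurable) prevents explosive 1/p inflation.

**Validation.** Units are ranked by prediction into 10 equal-count bins
(bin 10 = top decile).  Bin utilization is U(xᵢ) = w(xᵢ)/Σ w(x_k) with
w(xᵢ) the bin's median prediction; expected held-out-year counts are
N_ij = N_.j · U(xᵢ) with N_.j the year's detection-adjusted total.
Observed (adjusted, unrounded) bin sums are regressed on expected, pooled
over years; the model passes when the 90% CI of the intercept contains 0
and that of the slope contains 1.  Spearman rank correlations are computed
per year.  By default both axes are proportions of the year total, which
makes pooling years scale-free (expected proportions equal U); a raw-count
mode is available.

**Mapping.** Predictions on a 2 × 10-km grid use offset 0 (one
survey-year; only relative intensity matters).  Cells are classified into
ten equal-area classes by the prediction percentiles, tied values staying
together (stable sort, first-of-run class).  Scaling the map so cells sum
to an external abundance total (e.g. 29,757 birds) converts relative
intensity to expected numbers; region totals sum the cells whose centre
points fall inside a region polygon.  Scaling preserves ranks and decile
classes exactly.

## 2. The synthetic survey generator

The generator defines the study conditions every statistical claim is
tested under.  Geometry is a planar equal-area km grid (x east, y north);
no geographic CRS mathematics is used or needed.

* **Covariate fields.** Continuous covariates are Gaussian random fields
  (white noise smoothed to a stated correlation range, rescaled to a mean
  and SD on the natural scale of the real layers — elevation mean 1,800 m,
  SD 500 m; solar radiation mean 4,000 Wh·m⁻²·day⁻¹, SD 400; wind class
  1–7; etc.).  Land-cover classes are smooth fields thresholded at a
  quantile so the class covers a stated landscape share (forest 20%,
  developed 3%, open water 0.4%, …).  Road distances are smooth fields
  read at the unit centre; aspect is a categorical quadrant field.
* **Transects.** Systematic east-west transects of 100 km with a single
  uniform random start: rows every 60 km north-south and a 60-km gap
  between successive transects within a row (≈ 0.010 km of transect per
  km², matching a ~17,500-km system over a ~1.9M-km² frame).  Transects
  are clipped at the extent boundary.
* **Latent counts.** Per 2 × 10-km transect segment and year, group counts
  are NB2 with mean exp(Xβ) (θ → ∞ gives exact Poisson), generated by a
  gamma–Poisson mixture on the segment's own summarised covariates; group
  sizes are 1 + Poisson(0.15); partial end segments scale the mean by
  length.  Default coefficients follow the magnitudes of the published
  final model, with the intercept set to −16.6 so the expected
  detection-adjusted total over ~1,850 units and ~4.8 effort-years matches
  the survey's observed scale (~0.13 adjusted eagles per unit-year).
* **Detection.** Each group is flying with probability 0.3, otherwise
  perched with the AGL stratum set by the segment's forest proportion
  (threshold 0.25, mirroring higher flight over forested/rugged terrain);
  sides are equiprobable; detection is Bernoulli at the stratum
  probability.  Groups are placed uniformly within their segment.
* **Effort.** Each transect-year is flown with probability 0.96
  (whole-transect dropout), giving mean effort 4.8 of 5 years as observed;
  units flown fewer than 2 years are excluded from modelling.

What the generator does **not** emulate: real GIS layers and their
artefacts, alternate-transect substitution (dropout is modelled directly),
double-observer mark-recapture (probabilities are inputs), exclusion
zones, and movement of individual eagles between years.  Passing tests
therefore demonstrate the statistical machinery under the design's
sampling structure, not robustness to real-data pathologies.

## 3. Numerical choices

* **NB2 fitting** alternates an IRLS GLM step at fixed dispersion with a
  bounded one-dimensional profile-ML update of θ (log-θ in [−7, 16]),
  stopping when the log-likelihood improves by less than 10⁻⁸ (alternating
  ML is monotone, so non-improvement is convergence; this is robust to
  likelihood jitter on the flat dispersion profile of equidispersed data).
  Coefficient SEs are the GLM SEs at the converged θ.  The fit agrees with
  joint-ML NB2 estimation to ~10⁻⁴ on coefficients and is cross-checked
  against it in the tests.
* **BIC** is −2ℓ + (p+2)·ln n, with p+1 regression coefficients and the
  dispersion counted as a parameter; n is the number of modelled units.
  Removal ties within 10⁻⁶ are broken by deleting the term with the
  smallest |coefficient/SE|, making traces deterministic.
* **Moran's I** uses an inclusive radius, binary weights by default, and
  requires at least one neighbour pair; the antisymmetric two-point
  configuration gives exactly −1.
* **Degenerate inputs** raise informative errors: all-zero responses,
  missing detection strata, quadratics without parents, fewer than 10
  units for binning, zero-variance expected values in the validation
  regression, constant prediction maps (one class, with a warning).
* **Reproducibility.** Every stochastic routine takes an explicit seed or
  Generator; identical seeds give byte-identical observation tables.

## 4. Known limitations

* **The deviance goodness-of-fit test is not calibrated for NB2.**  With
  ML-estimated dispersion, the chi-square reference is wrong in both
  directions: under genuine NB dispersion the unit deviances have
  expectation above 1 (deviance/df ≈ 1.1 at moderate means), so the test
  over-rejects; in the Poisson-like and low-mean regimes the estimated θ
  absorbs chance overdispersion and the test is conservative (large
  p-values, as in the worked example).  The statistic and df follow the
  standard convention and are verified against a term-by-term oracle; the
  p-value should be read as a rough screen, not a calibrated error rate.
* **Model-based SEs understate intercept uncertainty under the design.**
  With ~2,000 with-replacement 10-km units on ~16,500 km of transects,
  unit rectangles overlap and the same eagles are counted in multiple unit
  instances.  The induced positive correlation inflates the sampling
  variance of the intercept well beyond its reported SE (slope contrasts
  are much less affected).  This is precisely why inference uses the
  transect bootstrap, whose intervals have close-to-nominal coverage in
  simulation.
* **Median-based utilization bins assume limited within-bin skew.**  When
  predictions are highly dispersed (SD of the linear predictor ≳ 1), the
  top bin's median understates its share of total intensity and the
  observed-vs-expected slope biases above 1.  At the intensity spread of
  the emulated survey (top-bin utilization ≈ 0.2) the validation is well
  behaved.
* **Rounding** adjusted sums to pseudocounts adds a small (<1%) bias at
  the observed inflation factors; it is kept because the pseudocount is
  the defined response of the method.
* Detection probabilities are treated as exogenous and shared across the
  study area; their uncertainty enters only through the bootstrap's
  per-stratum redraws.
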
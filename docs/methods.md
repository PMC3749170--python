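# Methods

## The model

Reproductive investment in egg-laying amniotes scales with adult body
mass BM (kg) as a power law,

    Y = c · BM^b,

where Y is one of three traits — egg mass (EM, kg), clutch mass
(CM = EM × CS, kg, with CS the clutch size) or annual clutch mass
(ACM = CM × CY, kg/yr, with CY the number of clutches per year) — c is
the normalization constant (the trait level at 1 kg body mass) and b the
dimensionless exponent. On log10–log10 axes the law is a straight line
with intercept log10 c and slope b; all fitting happens on that scale,
by ordinary least squares, separately per taxonomic group (birds,
crocodiles, tortoises). Logarithms are base 10 throughout.

The package does not use phylogenetically corrected regression: the
fitting targets mean coefficient values, for which OLS estimates are
unbiased regardless of phylogenetic covariance, and no adequately
resolved species-level tree exists for the calibration groups. Reduced
major axis regression is likewise out of scope.

## Homogeneity testing and model merging

Whether groups need separate models is decided by ANCOVA-style
nested-model F-tests on the pooled log-log data:

* slope homogeneity: `log10 Y ~ log10 BM + group + log10 BM:group`
  against the additive model (the interaction term);
* intercept homogeneity given a common slope: the additive model
  against `log10 Y ~ log10 BM` (the group term).

When an overall test with three or more groups is significant, pairwise
two-group ANCOVAs identify which groups differ. The merging decision
tree is:

1. **Slopes homogeneous, intercepts differ** — every group keeps its own
   model but with a *common slope*, the unweighted arithmetic mean of
   the groupwise OLS slopes (an average over taxa, not species); only
   each group's normalization constant is re-estimated, as the mean of
   `log10 Y − b_common · log10 BM`.
2. **Slopes and intercepts both homogeneous** — the groups collapse into
   one model with the common slope and the average of the groups'
   fixed-slope normalization constants. The pooled records back the
   merged model's residual statistics.
3. **A group whose slope differs from every other group** keeps its
   free-slope OLS fit unchanged.

Two conventions deserve note. First, "average intercept" in branch 2 is
the average of the *fixed-slope refit* intercepts, not of the free-OLS
intercepts; this keeps the procedure sequential (slope first, then
intercepts at that slope) and makes all models that survive a slope
merge share the slope exactly. Second, ambiguous patterns such as
{A≈B, B≈C, A≉C} are resolved greedily: the pair of clusters with the
largest criterion p-value merges first, and remaining candidates are
re-tested against the pooled cluster; realistic three-group data rarely
hits this case.

The significance level defaults to α = 0.05. No multiple-testing
correction is applied to the pairwise ANCOVAs; the raw p-values are
reported so users can apply one.

## Prediction intervals and classification

Prediction intervals are for a *single new observation* — the relevant
question when asking whether one fossil taxon could have been drawn from
an extant group's distribution — computed in log10 space as

    ŷ(x₀) ± t(1−α/2, df) · √(s² · (1 + 1/n + (x₀ − x̄)² / Sxx))

and back-transformed with a plain 10^. No smearing/bias correction is
applied on back-transform. Degrees of freedom are n − 2 for free-slope
fits, n − 1 for fixed-slope refits, and n − 2 (pooled n) for merged
models. A fossil trait value is classified below/within/above each
model's band at its body mass, and the "nearest" model minimises the
vertical (trait-axis) log10 distance to the regression line;
perpendicular distance is not used.

## Application to fossil taxa

Fossil egg mass, when not directly recorded, follows from egg
dimensions: volume V = k·L·D² (cm³) with k = 0.51 for asymmetrical
bird-like eggs (theropods) and k = 0.524 for ellipsoid/globular
crocodile-like eggs (sauropodomorphs, hadrosaurs), converted to mass at
a whole-egg density of 1.13 g/cm³ for all clades.

Given a model set, per taxon and per reported body mass (minimum, mean,
maximum each produce their own row):

    CS_model = CM_model(BM) / EM        model-based clutch size
    AEN      = ACM_model(BM) / EM       annual egg number
    CY       = AEN / CS_fossil          clutches per year

The baseline assumption is one clutch per year when forming a fossil
ACM from a fossil clutch mass (every extant calibration species lays at
least one). CY uncertainty brackets pair the single AEN at a body mass
with the fossil clutch-size extremes, [AEN/CS_max, AEN/CS_min]; body
mass extremes appear as separate rows rather than entering the bracket.
Model-based clutch sizes and egg numbers are continuous and may fall
below one egg; they are reported as-is. Report tables round half-up at
one decimal by default; stored values keep full precision.

## Recovered reference models

`paleoallom.datasets` bundles the nine-taxon dinosaur table (body-mass
ranges, egg masses, fossil clutch-size ranges) and recovers the extant
clutch-mass and annual-clutch-mass power laws exactly from pairs of
published per-taxon estimates: two reported predictions at two body
masses determine a power law uniquely on log-log axes. The recovered
ACM slopes for the bird and reptile (crocodile+tortoise) models agree
to four decimals (≈0.7245), consistent with a common-slope merge in the
source analysis. These recovered fits carry no residual statistics, so
they support the ratio estimators but not prediction intervals.

## Synthetic data

The generator emulates the statistical structure the chain assumes:
log10 BM uniform over a group's range, and
log10 Y = log10 c + b·log10 BM + N(0, σ). Residual σ defaults to 0.2
(0.10–0.18 per component in the joint generator), in the range typical
of reproductive allometries spanning several mass decades. Default
group sizes (217 birds, 22 crocodiles, 20 tortoises) and mass ranges
(0.2–100, 20–1000, 1–300 kg) mirror a realistic calibration table. The
default laws give birds a distinct egg-mass slope, one common
clutch-mass slope with three distinct constants, and bird/reptile
annual-clutch-mass models sharing slope 0.725 — so a full refit on
generated data reproduces the 3 EM / 3 CM / 2 ACM merged structure.

Per-trait generation decomposes the trait into (EM, CS, CY) components
so the *specified* trait lies exactly on its law; companion components
are drawn from plausible ranges and are only approximately allometric.
Two guards keep records valid: clutch sizes are floored at one egg, and
for egg-mass laws the rare extreme draw exceeding body mass is truncated
at 0.9·BM (an egg cannot outweigh its layer). The generator does not
emulate phylogenetic autocorrelation, heteroscedastic scatter, body-mass
measurement error, or literature-compilation biases — passing tests
demonstrate correctness of the statistical machinery under the assumed
model, not robustness of real-data conclusions to those violations.

A single integer seed drives everything via
`numpy.random.SeedSequence(seed).spawn`, one child stream per group (or
per fossil taxon), so adding a group never perturbs earlier draws and
equal seeds give byte-identical tables.

## Numerical choices and degenerate inputs

* Fits require ≥ 3 records per group and non-zero variance in log10 BM;
  violations raise typed errors naming the group.
* Duplicate literature rows for one species are averaged arithmetically
  per trait at read time; masses declared in grams convert to kg on
  ingest.
* Missing min/max columns in fossil tables collapse onto the mean
  (degenerate ranges are legal everywhere and collapse brackets to
  points).
* Merged-model labels join member names ("crocodile+tortoise") unless a
  rename map is supplied; the pipeline names that merge "reptile".
* Report rounding is decimal half-up, applied only at formatting.

## Problem sizes

The test suite's Monte-Carlo checks use 1,000 replicates for test size
and confidence-interval coverage (two groups × 100 species, or 200
species, per replicate), and 50 calibration replicates × 200 fresh
observations (10,000 draws) for prediction-interval coverage — sizes at
which Monte-Carlo standard errors (≈0.7 percentage points on a 5% rate)
are small against the tested tolerances. The fossil-application checks
are deterministic and instantaneous.

## Known limitations

* The ANCOVA machinery assumes homoscedastic normal residuals in log10
  space; heavy-tailed scatter will distort both the tests and the
  prediction intervals.
* Extrapolation: fossil body masses lie far outside the calibration
  ranges; the leverage term widens the bands accordingly, but the power
  law itself is assumed to hold across the extrapolation.
* The two-stage merge inflates the probability that *some* distinction
  survives under a true common law to ≈ 1 − (1 − α)²; each individual
  test holds its nominal size.
* Egg-producer identity for oospecies is uncertain; body-mass ranges
  stand in for unknown individual masses, and the dinosaur-only
  egg-mass regression depends visibly on which mass column is used.
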
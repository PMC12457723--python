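# Methods

## Shoot model and age conventions

A "shoot" is the longest unbroken primary axis of one individual plus
its laterals.  Segment age counts from the tip: age 0 is the
current-season, incompletely formed apical segment; age 1 (S1) is the
newest fully formed segment; ages are contiguous 0..A.  Dichotomous
branching means the count of youngest bladders (b0, one per current
tip) is at least the count of second-youngest bladders (b1) on an
intact shoot; broken shoots are flagged and excluded from tip-based
statistics by default, because their bladder counts no longer reflect
annual tip production.

Receptacle masses are pooled by (site, segment age) — the canonical
granularity of the field protocol, which dries and weighs receptacles
pooled across shoots per age — so per-receptacle mass lists are
optional and a segment's `receptacle_masses` typically holds one pooled
mean.  *R* is taken as the whole-shoot receptacle mass.

## Allocation statistics

For annual vegetative growth, annV = (site-mean S1 dry mass) x n with
n = (b0 + b1)/2: b1 undercounts and b0 overcounts the tips formed in
the last year, so their mean is the compromise estimate, and annV
computed with b1 / mean / b0 is ordered accordingly (a property the
tests check).  The site-mean S1 mass is used rather than each shoot's
own S1 because the sampling design measures apical growth on a larger
separate pool of individuals (20-30 apical segments per site); a
per-shoot override exists.

turnover = annV/V, RE = R/V, annRA = R/(R + annV), and
annRA = RE/(RE + turnover) holds exactly per shoot.  Carbon units:
annRA_C = R c_rep / (R c_rep + annV c_veg) with site-level scalar
carbon fractions (vegetative C measured on S1, receptacle C the mean
over receptacles from segment ages 2, 5 and 8).  Receptacles are
carbon-poorer than vegetative tissue, so annRA_C < annRA.

Site summaries report mean and SE = sd/sqrt(n) per metric across
shoots, the reporting convention of the field literature.  Areal
fluxes: rep_C = standing biomass x RE x c_rep and veg_C = standing
biomass x turnover x c_veg.  The SE propagation rule for areal fluxes
is not fixed by the literature; here each shoot's RE and turnover is
converted to an areal flux using the site-mean biomass and the mean/SE
is taken across shoots, consistent with shoot-level replication.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:

* **Tips** follow a branching process: each tip splits dichotomously
  with annual probability p; b0 and b1 are the tip counts after the
  last and second-to-last year.
* **Receptacle counts** per segment are negative binomial with
  log-mean b0 + b1 age + b2 age^2 (b2 < 0) plus a shoot-level Gaussian
  intercept (optionally a random slope); ages below the first
  reproductive age (2 at the northernmost profiles, 1 further south)
  are structural zeros.
* **Receptacle mean mass** declines linearly with age,
  max(0.001 g, a + b age + noise); the 1 mg floor keeps masses
  positive.
* **Segment masses** are lognormal with a multiplicative age profile;
  the default profile gives the incomplete apical segment half the
  mass of a formed segment and is constant otherwise.  The
  fast-turnover temperate profile uses a front-loaded profile
  (older segments lighter), matching young, rapidly renewing shoots.
* **V** is the cohort sum of segment masses weighted by tips alive in
  each formation year; **R** sums counts x pooled mean masses.

### Profile calibration

Four site profiles span the observed ranges (RE 0.11-0.73, turnover
0.22-0.67 yr^-1).  Calibration is by moment matching on three
conditions per profile:

1. branching probability p solved so the expected per-shoot turnover
   E[s1_mean n / V] equals the site anchor;
2. negative-binomial size k solved so the between-shoot sd of RE
   matches the published site SE scaled to the field replication
   (SE x sqrt(12)); where segment-mass and branching noise alone
   exceed that spread, k clamps at its near-Poisson maximum and the
   residual gap is accepted — between-shoot spread has a morphological
   floor;
3. count-model intercept solved in closed form (E[R] scales as
   exp(b0), and R is independent of V) so E[R/V] equals the RE anchor.

Expectations of ratios such as E[1/V] are evaluated by a large
fixed-seed vectorized simulation (60 000 replicates, seed independent
of user seeds): V is a weighted sum over a branching process whose
left tail defeats lognormal/delta-method corrections, and a plain
ratio of expectations would be biased low by Jensen's inequality.
`expected_site_means` reports the generator-implied expected per-shoot
means; note the expected mean annRA is the mean of per-shoot ratios,
which is *not* RE/(RE + turnover) of the anchors — the field data show
the same structure.

Published quantities that require the raw field measurements (per-site
annRA percentages, mean receptacle masses, areal carbon fluxes) are
carried as documentation on the anchor table, not recomputed.

### What the generator does not emulate

Lateral-axis architecture is collapsed into cohort weights; receptacle
counts are attributed to the measured axis; segment masses within a
cohort share the primary axis' draw; no epiphytes, herbivory losses,
breakage, measurement error on bladder counts, or within-season
phenology.  Tests passing on synthetic data therefore demonstrate
estimator correctness under the assumed statistical structure, not
robustness to field artifacts.

## Within-shoot models

The count-age model is a quadratic negative-binomial regression (log
link) fit by maximum likelihood, either pooled or with fixed per-shoot
offsets.  A full random-intercept-and-slope mixed model is
deliberately avoided: at 10-14 shoots per site random-slope NB fits
are fragile, and the scientific targets are the sign of the quadratic
term and the age of peak receptacle production, -b1/(2 b2).  Fits are
flagged (never raised) on non-convergence or degenerate all-zero
counts.  Parameter-recovery tests generate with the first reproductive
age at 0 so the generating model matches the fitted model; with
structural zeros at ages 0-1 the fitted peak shifts upward by roughly
a year, a model-mismatch artifact rather than an estimator defect.
Segments older than 12 years are excluded from the count table (few
shoots reach that age, so older cells would be dominated by one or two
individuals).

Receptacle size vs age is ordinary least squares on the pooled per-age
mean masses (at least 3 ages), with a two-sided slope t-test.  The
50%-cumulative age is the smallest age, counting from the tip, whose
cumulative receptacle count reaches half the total; ties resolve to
the first age reaching the threshold (>=), making the statistic
deterministic and invariant to rescaling all counts.

## Phenology conventions

Reproduction peaks reported as months are coded as the day-of-year of
the 15th on a 366-day calendar: the published anchor values (July 197,
late August 228) only arise on a leap calendar, while February 46 and
November -46 are calendar-invariant, so the leap calendar is adopted
as the canonical convention.  Under the default autumn-negative
policy, months October-December map to day-of-year minus 366, which
keeps the latitude-timing relation a single monotone line across the
year boundary; the cutoff at October reproduces the published
treatment of the southern-edge November peak and is configurable.

## Meta-regression

Literature records are collapsed to one point per region:
sub-population rows sharing a region tag are averaged; sources
reporting only RE (= R/V, not convertible to annRA without annV) are
excluded from the annRA analysis; regions left with no usable response
are dropped with a logged reason.  The packaged reference table
carries the published regional means.  Nova Scotia is a special case:
the original nine sub-populations were grouped into three regions, but
the three regional means were never published, so the packaged table
carries the single published regional value and the nine-point layout
is the canonical desk-scale regression; supplying the three regional
means as extra tagged rows reproduces the eleven-point layout (the
test suite exercises this with synthetic stand-in values).

The four headline fits (annRA and peak Julian day vs latitude and
SST) are separate simple OLS regressions: latitude and SST are far too
collinear across the North Atlantic for a joint model.  Fits report
slope, intercept, R^2, adjusted R^2 = 1-(1-R^2)(n-1)/(n-2), the
two-sided slope t-test, and a Shapiro-Wilk residual-normality p-value;
a conservative alpha of 0.01 is the recommended reading threshold but
nothing is enforced, and no multiple-testing correction is applied.
SST is an input column throughout (the packaged table leaves it blank,
so SST regressions are reported absent there); retrieval from an
oceanographic layer service is out of scope.

Two geographic notes: published sources disagree on which of the two
Disko Bay sites sits at 69°24' vs 69°02'; the packaged table follows
the study-site description (Qeqertarsuaq as the northernmost, 69°24').
Latitudes are decimal degrees converted from printed degree-minute
coordinates.

## Numerical choices and problem sizes

* Calibration expectation estimator: 60 000 replicates, fixed seed
  1234567; branching probability solved to 1e-4, NB size in log space
  to 1e-3.  Calibrated profiles are cached per process.
* NB likelihood maximization: BFGS from Poisson-GLM start values,
  statsmodels NB2 parameterization (reported k = 1/alpha).
* Recovery test sizes: 500 shoots per profile for allocation
  estimators; 100 replicates of 200 shoots for count-model shape; 100
  replicates for size-age CI coverage.  Per-test seeds are fixed;
  per-profile seeds derive from a stable hash of the profile name.
* CSV round-trips write floats at %.17g and read with pandas
  round-trip precision, so datasets survive write/read bit-exactly.

## Known limitations

* The generator's R sits on the measured axis; studies that weigh
  receptacles per lateral branch need the per-receptacle mass lists.
* The turnover range achievable by calibration is bounded by the age
  structure and segment-mass profile (the solver reports the
  achievable interval when a target falls outside it).
* Site summaries assume shoots are independent draws; within-site
  spatial structure is not modelled.
* The SE of a site mean computed with a dataset-internal S1 mean
  underestimates the estimator's true sampling variability, because
  the shared S1 factor correlates all shoots' annV; supplying the
  independently measured site S1 mean (as the field design does)
  avoids this.
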
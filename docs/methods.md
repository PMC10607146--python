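# Methods

This note documents the models, conventions and design choices behind
`vectorshift`, and what the synthetic validation does and does not show
about real data.

## Occurrence processing

Records are cleaned in the order deduplicate → uncertainty filter →
spatial rarefaction. Duplicates are defined by the (lon, lat, population)
key rounded to 4 decimals (~11 m); the uncertainty filter removes records
whose coordinate uncertainty *exceeds* the cutoff (default 5 km, strict
inequality) and **retains records with missing uncertainty**, because an
"uncertainty over X" rule cannot apply to absent metadata — the retained
count is logged for auditing. Rarefaction is greedy minimum-distance
thinning: records are visited in a seed-shuffled order and kept iff at
least the radius (default 5 km, haversine on a sphere of radius
6371.0 km) from every record kept so far. The exact retained set depends
on the visit order; the seeded shuffle makes runs reproducible while
avoiding systematic bias from input ordering. The post-condition (no two
retained records closer than the radius) is order-independent and is
asserted directly in tests. Ellipsoidal distance corrections (< 0.5% at
this scale) are deliberately omitted. Population splitting is
boundary-inclusive point-in-polygon against user-supplied native-region
polygons; pre-labelled records keep their labels. Rarefaction is applied
per population by default (native and introduced thinned separately), so
a dense introduced cluster cannot displace sparse native records.

## Bioclimatic variables

`compute_bioclim` follows the WorldClim/biovars conventions: monthly mean
temperature is (tmin + tmax)/2 unless an explicit tmean is supplied (both
are supported because gridded products disagree on which is primary);
bio04 and bio15 use the sample (n−1) standard deviation; bio15 adds 1 mm
to the mean precipitation in the denominator; quarters are the 12 cyclic
consecutive 3-month windows (Dec–Jan–Feb allowed) with ties broken by the
earliest window index; a zero annual temperature range yields NaN
isothermality. Equivalence with an independent per-cell scalar-loop
oracle is tested to 1e−9 on random grids, along with the algebraic
identities (bio07 = bio05 − bio06, bio12 = Σ prec, quarter orderings) and
cyclic-month invariance of the non-quarter variables.

## Predictor selection

Importance is permutation-based: for a fitted suitability model,
importance(p) = 1 − Pearson r between predictions on the data and
predictions with column p permuted, averaged over shuffles and over
ensemble members, capped into [0, 1] (a negative correlation counts as
full importance). Collinearity pruning repeatedly finds the predictor
pair with the largest |r| above the threshold (default 0.7) and drops its
lower-importance member (ties drop the lexicographically later name).
Highest-|r|-first ordering makes the loop deterministic and removes the
worst collinearity first; correlations are computed on presence +
background cells to mirror the modelling domain.

## Ensemble SDMs

Pseudo-absences equal the presence count when presences exceed 1000,
otherwise 1000, drawn uniformly over the domain mask excluding presence
cells, in 3 independent replicates. Evaluation is repeated stratified
70/30 cross-validation; AUC uses the Mann–Whitney rank formula (ties
counted ½) and TSS is the maximum of sensitivity + specificity − 1 over
observed score thresholds (positive at score ≥ t; ties take the smallest
threshold). Evaluations are averaged per algorithm over replicates ×
repeats before the inclusion rule (mean AUC > 0.8 **or** mean TSS > 0.6);
qualifying algorithms are refitted on each full replicate table and
weighted by mean TSS (normalized to sum 1, split evenly over replicates).
Binarization uses the smallest observed score maximizing
sensitivity + specificity.

The algorithm registry maps the classical SDM families onto scikit-learn
estimators behind a uniform predict-in-[0,1] contract. GLM and FDA use
degree-2 polynomial features (logistic regression and linear discriminant
respectively) so they can express the unimodal responses typical of
climatic niches; MARS is a logistic model on hinge-basis features with
five quantile knots per predictor; MAXENT is a penalized logistic
regression on linear + quadratic + product features (maxnet-style); ANN,
CTA, GBM and RF are the standard MLP, decision-tree, gradient-boosting
and random-forest classifiers. SRE — the surface range envelope — is
implemented natively: score 1 iff every predictor lies within the
presence quantile envelope [q, 1−q] (default q = 0.025).

The null-model test replaces the training presences with uniformly random
domain cells (count = 70% of the real presences), fits against the real
pseudo-absences and evaluates on held-out real presences; the p-value is
the (r+1)/(n+1) rank of the real AUC among n null AUCs. The test is
honest only when the modelling domain dwarfs the presence set (as in a
global-scale study): on a small domain the exclusion of presence cells
from pseudo-absences itself carries signal that null models can exploit.
The validation fixtures therefore use a 100×100-cell landscape with
~600 presences, and the null test runs with n_null = 19 and a GLM, the
fastest member, keeping the full synthetic pipeline to a few minutes of
one CPU.

## COUE niche dynamics

The environmental space is the first two principal components of the
standardized predictor values over the pooled background (unweighted PCA;
availability weighting is out of scope). Occupancy surfaces are Gaussian
product-kernel densities of occurrence scores evaluated at the centers of
an R×R grid (default R = 100) spanning the pooled background bounding
box, with per-axis Silverman (normal-reference) bandwidths from the
occurrence scores — the bandwidth is configurable because no single rule
is canonical for this analysis. Densities are normalized to sum to 1;
occupancy z is the density scaled by its maximum where the background has
support. Because a Gaussian kernel never reaches exact zero, cells with
z below 1e−6 of the maximum are set to zero — equivalent to truncating
the kernel at ≈ 5.3 bandwidths; E/S/U are insensitive to this constant
over several orders of magnitude because the zeroed cells carry
negligible mass.

E is the introduced density mass in cells with zero native occupancy
(fraction of total introduced mass), S = 1 − E exactly, and U the native
mass outside the introduced occupancy (fraction of native mass). By
default the sums are restricted to analog environments — cells available
in both populations' backgrounds — with no additional marginal-climate
quantile trimming. The shift indices use the introduced-normalized
breadths: IB = S + E = 1, NB = S + U, BR = 1/(S + U), SI = 2S/(1 + S + U).
U is a native-niche fraction inserted into the same arithmetic as the
introduced-niche fractions; this mixed-unit convention is what makes the
indices reproduce from published (E, S, U) triples and is adopted
deliberately. Conservatism is rejected only when SI < 0.5 and BR > 1.

The equivalency test pools and re-splits occurrences (null: niches are
interchangeable; one-sided p for lower-than-random overlap). The
similarity test translates one population's occurrence scores so their
centroid lands at a uniformly random point in its background envelope
(null: overlap explainable by background availability; one-sided p for
higher-than-random overlap). Both use the (r+1)/(n+1) rank convention.

## Virtual species and what validation shows

The landscape generator produces layers that are linear index gradients
(direction rotating across layers) plus moving-average-smoothed Gaussian
white noise — a simple, dependency-free source of spatial autocorrelation,
not a full Gaussian random field, and not an emulation of real climate
covariance. The monthly climate generator uses
tmean_m = mean − A·cos(2πm/12) (January exactly the coldest month, annual
range of monthly means exactly 2A), a fixed diurnal half-range (default
5 °C), and distributes a configurable annual precipitation total
(default 1200 mm) over the 12 monthly weights. True suitability is a
Gaussian response s = prevalence_scale · exp(−½ Σ ((e − μ)/σ)²);
occurrences are drawn multinomially ∝ s and jittered uniformly within
their cell. Defaults (100×100 grid at 2.5 arc-minute cells, 4 layers,
noise sd 0.5, 2000 records per population) are sized so the estimation
problem is comparable to a rarefied continental dataset while keeping the
full pipeline in minutes.

`true_coue` binarizes each population's true suitability at a cutoff
(default 0.05 × its maximum; the choice is exposed because no canonical
definition of a "true" occupied niche exists) and counts cells. This
cell-count truth and the density-mass estimate agree closely for
identical or nested niches — the zero-shift recovery tests require
estimated E < 0.05, U < 0.10, SI > 0.9 across seeds — but diverge for
strongly shifted niches, where density mass concentrates near the niche
centres and E under-reports the cell-level expansion. Overlap (Schoener's
D) and the permutation tests detect such shifts earlier; the monotonicity
test (estimated E non-decreasing over increasing niche separations)
covers that regime. Passing these tests shows the estimators are
internally consistent and recover known geometry under Gaussian niches on
smooth landscapes; it does not show robustness to real-data pathologies
(sampling bias beyond what rarefaction removes, non-Gaussian or
multimodal niches, dispersal limitation, spatially structured errors).

## Range dynamics

Binary range overlay classifies cells as expansion (introduced only),
stability (both), unfilling (native only) or absent; areas use the
spherical-zone formula R²·Δλ·(sin φ_top − sin φ_bottom) with
R = 6371 km, so indices are computed on km², not cell counts, and
latitude cannot bias them. RE + RS + RU equals the union area exactly.
Invasion durations for the rate comparison are explicit parameters: the
published figure for the two *Aedes* vectors uses a tenfold duration
ratio, and the ratio is left to the caller rather than hard-coded.

## Known limitations

- The environmental-space grid covers the pooled background bounding box;
  occurrences projected outside (impossible when backgrounds contain all
  cells) would be clipped to edge cells.
- The similarity-test null shifts the whole occurrence cloud rigidly;
  shape changes under the null are not modelled (matching common
  practice).
- The SDM registry approximates MARS/FDA/MAXENT with basis-expanded
  linear models rather than the original implementations; rankings among
  algorithms on real data may differ.
- Published E/S/U and range areas for the real mosquito datasets require
  the original ~25k–38k records and 1990–2020 global rasters and are not
  recomputable here; the acceptance script instead verifies every index
  formula against the published decomposition components.
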
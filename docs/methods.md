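# Methods

This note documents the models, estimators and numerical choices behind
`cpforage`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Data model and preprocessing

The unit of analysis is the **tracking day**: one bird's fixes on one
calendar date, expected on a regular grid (default 5 min) between local
sunrise and sunset. Sun times come from the low-order NOAA solar-position
series (accuracy ≈ 2 min, far below the fix interval). A **year-bird**
(bird × year) is the statistical individual: crop rotation changes a
bird's environment between years, so repeated years are treated as
distinct grouping units. Dates are mapped to six biological periods
(nest building 10 Mar–20 Apr, incubation 27 Apr–14 May, chick rearing
21 May–16 Jun, post fledging 10 Jul–8 Aug, post breeding 5 Oct–3 Nov,
wintering 6 Nov–6 Dec); dates in calendar gaps are excluded.

**Missing-data rule.** A "missing location" is a slot of the theoretical
sunrise–sunset grid with no fix, which also covers device-suspension
gaps. Days with strictly more than 5 % missing slots are discarded; the
test uses observed/expected counts *before* any interpolation (9/180
missing is kept, 10/180 rejected). The filter is monotone in
missingness by construction.

**Gap interpolation (CTCRW).** Remaining gaps are filled by fixed-interval
smoothing under the integrated Ornstein–Uhlenbeck velocity model: velocity
follows dv = −β v dt + σ dW per planar axis, position integrates velocity,
and fixes are observed with fixed measurement error (σ_obs = 10 m,
configurable — typical GPS, deliberately not estimated because β, σ and
σ_obs are weakly separable at a 5-min cadence). (β, σ) are fitted per
year-bird by maximizing the Kalman-filter likelihood pooled over that
bird's days (per-day fits are unstable when gaps are rare); the fit uses
at most 2000 fixes per bird, which bounds cost without affecting the
smoother. The Rauch–Tung–Striebel smoother predicts positions at missing
slots; observed fixes are never altered, and interpolated fixes are
flagged. If the fit or smoother fails, the day falls back to
piecewise-linear interpolation with a logged warning.

Coordinates are planar metric (x east, y north, Euclidean meters).
Geographic input is projected by a local spherical azimuthal-equidistant
projection about the study centroid: exactly invertible, with distance
distortion O((d/R)²) — sub-meter over the few-km daily ranges this
package targets. The habitat raster is a single-band integer grid stored
as an ESRI ASCII text file with a JSON class-label sidecar; habitat at a
fix is the class of the containing cell (point-in-cell, no buffering).

## Behavioral segmentation

A single population-level 3-state HMM is fitted to all days pooled
(the chain restarts from the initial distribution at each day boundary).
Observations per step: **smoothed speed** — a centered rolling median
(window 3, shrinking at the edges) of raw speeds, robust to single-fix
GPS jitter — with a gamma emission, and **turning angle** with a von Mises
emission; the two are conditionally independent given the state, and the
first angle of each day is undefined and masked. Speeds are floored at
0.1 m/min (below GPS noise) so the gamma density is defined at rest.

Fitting maximizes the forward-algorithm log-likelihood directly by
multistart L-BFGS on an unconstrained reparameterization (log scales for
positive parameters, row-wise multinomial logits for the transition
matrix and initial distribution) with **exact analytic gradients** from
the Fisher identities: posterior-weighted emission scores for emission
parameters and pairwise-transition posteriors for the chain parameters.
Each start runs a short exploration; the best start is polished to a
gradient tolerance of 1e-8. The forward pass is vectorized across days
(padded to the longest day) with per-step renormalization. States are
relabelled after fitting by ascending gamma mean and interpreted as
stationary / short-distance (walk) / long-distance (flight).

Decoding is by Viterbi (per-fix posteriors from forward–backward are also
reported); the step state is assigned to its departure fix, the last fix
inheriting the final step's state. Model checking uses one-step-ahead
forecast pseudo-residuals (normal quantile of the predictive CDF per data
stream), approximately standard normal under a correct model. A
**foraging occasion** is a fix decoded stationary-or-walk whose habitat
is agricultural (grassland, cereal, maize, other agricultural).

Note that rolling-median smoothing deliberately trades emission fidelity
for robustness: short flight bouts are partially blended into adjacent
slow states, so emission means fitted to *tracks* sit a little below the
generative step speeds, and a few percent of flight steps decode as
foraging states. This is a property of the observation pipeline, not of
the fitting code — on data sampled directly from the HMM the emission
means are recovered within a few percent.

## Daily occurrence distributions

The **biased random bridge** UD places advective Brownian-bridge kernels
along each consecutive-fix segment: at interior time t of a step of
duration Δt the kernel is a circular Gaussian centered on the linear
interpolation point with per-axis variance h_min² + 4·D·t(Δt−t)/Δt,
integrated over t with a 10-node midpoint rule and weighted by the step's
duration. Steps shorter than l_min = 5 m become stationary kernels of
variance h_min²; gaps longer than t_max = 30 min contribute nothing.
Defaults: grid cell 20 m, h_min = 20 m, all configurable. Grids snap to
the global 20-m lattice so cells of different days are comparable by
integer index.

The diffusion coefficient **D** is estimated per year-bird by maximum
likelihood on alternate-fix prediction: each odd-indexed position is
predicted from its neighbours under the same bridge model; D is floored
at 0.1 m²/min for degenerate all-stationary tracks. D uses the kernel's
own convention (a free trajectory has per-axis variance 4·D·t), keeping
estimator and kernel consistent.

The 95 % **isopleth** is the smallest set of highest-density cells whose
cumulative mass reaches 0.95 (ties at the threshold density all
included). Descriptors: area = cell count × cell area; **overlap** is
directional — the mean over the bird's other same-period days of
100·area(i∩j)/area(i) — matching the "of each day over the others"
phrasing (a symmetric variant is a one-line change on the cell sets);
the **centroid** is the mass-weighted mean of the full UD (not the 95 %
region); the **farthest limit** is the maximum distance from the nest to
a boundary vertex of the isopleth region — for a union of axis-aligned
cells this maximum is always attained at a member-cell corner, so it is
computed exactly without polygon construction (the boundary polygon is
still available via shapely for export).

## Mixed models and inference

All descriptor, use and duration comparisons are random-intercept models
with the biological period as the only fixed effect and year-bird as the
grouping factor, fitted by maximum likelihood (never REML — comparisons
are across fixed-effects structures, and ML keeps the gaussian case
consistent with the GLMM families):

* area, nest–centroid and nest–farthest distances: gamma error, log link;
* overlap (spatial fidelity, %): gaussian LMM;
* daily use of each habitat (used/not per day): binomial, logit link —
  except a habitat used on >99 % of days, where raw per-period
  proportions are reported instead of a degenerate model;
* daily foraging duration conditional on use (count of foraging fixes ×
  5 min): gamma, log link.

For gamma and binomial families the random intercept is integrated by
**adaptive Gauss–Hermite quadrature** (15 nodes, centered at each group's
posterior mode found by vectorized per-group Newton steps); the gaussian
case uses the closed-form marginal likelihood with Sherman–Morrison
per-group inversions. The gamma family is parameterized by shape = 1/φ
with φ estimated jointly by ML. Observation weights multiply log-density
contributions. Coefficient covariance is the inverse numerical Hessian of
the marginal log-likelihood; when a variance component sits on the zero
boundary the pseudo-inverse supplies the coefficient block. Binomial
separation (diverging coefficients or standard errors) triggers a
ridge-stabilized refit (penalty 1e-4) with a logged warning.

Inference artifacts per model: **Wald χ²** on the five period contrasts;
**Tukey-adjusted pairwise contrasts** of the link-scale marginal means —
the adjusted p of each contrast is the equicoordinate tail probability
P(max|Z| ≥ |z|) of the 15 correlated contrast statistics under
multivariate normality, evaluated by seeded quasi-Monte-Carlo (2¹⁷ Sobol
points; MVN rather than studentized range because the contrasts are
correlated and the degrees of freedom asymptotic), clipped to never fall
below the unadjusted p; **compact letters** by insert-and-absorb, ordered
by ascending marginal mean; and **pseudo-R²** by the latent-scale
variance decomposition R²m = σ²_f/(σ²_f+σ²_b+σ²_d),
R²c = (σ²_f+σ²_b)/(same), with σ²_d the residual variance (gaussian),
π²/3 (binomial logit) or ln(1+φ) (gamma log, the lognormal
approximation — the conventional choice for a log-link gamma).

## Habitat selection functions

One HSF per biological period. Used points are *recorded* foraging fixes
only — interpolated positions are model imputations, not observations of
a habitat choice, so they enter the UDs and duration counts but not the
selection design. For each used (foraging) fix, ten
availability points are drawn area-uniformly (r = R√u) in the circle
centered on the nest with radius equal to that day's farthest-limit
distance; points landing on non-agricultural cells are **redrawn**
(capped at 1000 attempts; a "discard" alternative would change the
used:available ratio across days, so redraw is the default), because the
selection model is defined over the four agricultural habitats only.
The model is a weighted binomial-logit mixed model (response 1 for used,
0 for available; weights 1 and 1000 — the large available-point weight
makes the logistic likelihood approximate an inhomogeneous point-process
likelihood), with habitat as the only fixed effect, grassland as the
reference, and one intercept per tracking-day stratum held at a **fixed
large variance** (1e4 on the logit scale, configurable) so each day
carries its own availability baseline without a variance component to
estimate. Day strata nest within year-birds and subsume bird baselines,
so no separate bird intercept is added. With the variance fixed and
large, the marginal likelihood is integrated by Laplace (exact in the
flat-prior limit); the estimates are stable in the weight (1000 vs 5000
changes log-RSS by <1 %). Exponentiated coefficients are **relative
selection strengths** with Wald 95 % CIs.

**Cross-validation**: folds are whole tracking days (k = 5 by default);
held-out used+available rows are scored by the fixed-effect linear
predictor, rank-binned into 10 equal-size bins (ties broken at random —
the predictor takes one value per habitat, so ties are structural), and
the Spearman correlation of bin rank with the bin's used-point proportion
is recorded per fold. Bins are reduced with a warning when a fold is
small.

## Synthetic study generator

The generator emulates the tracking design the analyses expect:
~20 birds of which 11 are tracked in two years (31 year-birds),
participation and days-per-period calibrated to give roughly 530 tracking
days, 5-min sunrise–sunset schedules at 47.9° N, nests placed in
non-agricultural (built) cells near the landscape centre, and
per-fix dropout (default p = 0.03, producing both keepable and
discardable days under the 5 % rule).

**Landscape**: seeded-region growth — n random seeds partition the grid
into contiguous Voronoi parcels (default ≈1.3 ha, typical of bocage
farmland); whole parcels are allotted to classes, largest first, to the
class with the greatest remaining deficit, so realized shares match the
target composition (default ≈ grassland 31 / cereal 27 / maize 28 /
other 7.5 / non-agricultural 6.5 %) within ±3 points, else the generator
refuses.

**Movement**: a hidden state chain (stationary/walk/flight, mean speeds
3.1 / 14.2 / 78.8 m/min) drives gamma step lengths and von Mises turns;
the heading is pulled toward the nest with gain min(1, a·d) at distance
d (linear-in-distance drift — keeps tracks central-place with no
reflecting boundary). **Habitat preference** acts where a foraging bout
is initiated: the endpoint of the flight step entering the bout is
accepted with probability ∝ exp(selection log-weight of its habitat)
(grassland fixed at 0), redrawing on rejection; within the bout, steps
keep to the bout's habitat (field fidelity). Because flight steps
(~400 m) are long relative to parcels, the proposal composition tracks
local availability, and because bout length is independent of habitat,
the induced point-level selection ratio of foraging fixes equals the
acceptance-weight ratio — the quantity an HSF estimates. An earlier
design that weighted *every* foraging step was rejected: in a serially
dependent chain the short-step proposals mirror the current habitat and
the realized ratio ends up far from the acceptance weights (measured
≈1.3–1.4 for a weight of 2).

What the generator does **not** emulate: GPS position error (tracks are
exact; the CTCRW's 10-m error model is therefore conservative), weather
and wind drift, conspecific attraction, crop growth within a period,
battery duty cycles beyond Bernoulli dropout, and habitat-dependent
behavior transition rates. Passing recovery tests therefore demonstrate
estimator correctness under the stated generative assumptions, not
robustness to all field conditions.

## Verification scales and numerical choices

The test suite and `scripts/acceptance.py` use these problem sizes,
chosen to make each check statistically meaningful on a single CPU:
exhaustive HMM oracles at K ≤ 3, T ≤ 8; emission recovery at 2×10⁴
simulated steps (25 starts); Wald/Tukey calibration on 200 simulated null
datasets of 40 groups × 12 observations — sized so that the asymptotic
z-based contrast inference being checked actually applies (at 12 groups ×
6 observations the family-wise error of the same machinery is ≈0.085,
an honest small-sample property of Wald contrasts without degrees-of-
freedom corrections, which this package does not implement);
end-to-end selection recovery on a
31-year-bird study with 15 days per bird per period and a constant
selection-weight set (cereal −1.2, maize +0.1, other −2.0 on the log
scale) — recovery is assessed on the pooled design because per-period
estimates at 15 days carry bout-level clustering noise of ±0.2 and more
on the log scale for rare habitats; null CI coverage on 200 reduced
replicates (3 birds × 3 days, ground-truth behavioral states), assessed
at the level of independent selection decisions — one used point per
foraging bout. The per-fix weighted likelihood treats every 5-min fix as
an independent choice, but the fixes of one bout replicate a single
habitat decision; feeding all of them in understates the standard errors
by roughly the square root of the bout length (we measure ~25 % CI
coverage of a true null at the fix level versus the nominal 95 % at the
bout level). Real studies using fix-level HSFs inherit the same
pseudo-replication, which is worth remembering when reading their
confidence intervals; point estimates are unaffected. The
pipeline HMM is fitted on a subsample of days capped at 2–3×10⁴ steps
and then decodes all days; estimates are population-level, so the
subsample loses little.

Degenerate inputs: zero-speed steps are floored (above); all-stationary
tracks floor D; a day with fewer than 3 fixes cannot form steps and is
excluded from segmentation; a period with a single observation is
permitted in the mixed models (its variance contribution is what it is);
empty habitat classes are dropped from an HSF design with a warning.

## Known limitations

* End-to-end recovery of selection strength is sharp for common habitats
  (log-RSS errors < 0.08 for cereal and maize in a 31-year-bird study)
  but only marginal for a rare, strongly avoided category: for 'other
  agricultural' (7.5 % of the landscape, true log-weight −2) the pooled
  error sits around +0.1–0.16 depending on the landscape realization —
  the sum of a small decoding contamination and the local-proposal
  mixing attenuation described above, plus realization noise from the
  few hundred parcels such a category occupies in a single landscape.
* The HSF omits continuous covariates (distance to nest, field size); the
  spatial decay of use around the nest is absorbed by the day strata only
  at the day level, so habitat–distance correlations within a day's
  circle leak into the RSS. In the synthetic recovery this contributes
  visible per-period noise for rare habitats.
* Pseudo-R² for the gamma family uses the lognormal approximation; other
  conventions (delta method, trigamma) shift R² by a few percent.
* The overlap descriptor is directional; symmetrized overlap differs when
  daily areas differ systematically.
* One population-level HMM assumes emission parameters shared across
  birds and periods; individual heterogeneity in speeds would bias state
  assignment for atypical birds.
* The CTCRW assumes isotropic, stationary movement within a day; it is
  used only to fill ≤5 % of slots, where this is immaterial.
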
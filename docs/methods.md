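# Methods

This note documents the models, numerical choices and limitations of
`gearmorph`, in the order the pipeline runs.

## Vulnerability scoring

Trawl outcomes are scored E_B = 50, E_F = 100, C_N = 200, C_C = 300,
and a cod-end capture adds `600 − t` (seconds, trial duration fixed at
600 s; a capture exactly at 600 s adds nothing). The three-trial index
V therefore lies in [150, 2700] and is monotone in outcome severity and
in earliness of capture. Trap captures earn 3/2/1 points in trials
1/2/3 (earlier capture weighted more to discount learning), so the trap
score lies in [0, 6].

Group assignment takes the ⌈fraction·n⌉ highest and lowest scores per
stratum (default fraction 0.25; trawl cohorts stratified by holding
tank, trap cohorts pooled — both configurable). Score ties that span a
quartile boundary are broken by fish-id order, optionally after a
seeded shuffle, so membership is deterministic and reproducible; the
break is reported in the log. Fish with missing trials are excluded
with a warning rather than pro-rated. A stratum whose scores are all
identical has no meaningful quartiles and raises an error.

## Generalized Procrustes analysis

Configurations are centred, scaled to unit centroid size and rotated
onto the running consensus by 2×2 SVD with a determinant correction
that forbids reflections (lateral photographs share an orientation).
The consensus is re-estimated until its change falls below `tol`
(default 1e-10, `max_iter` 100). Degenerate (zero-size) configurations
are excluded with a warning.

Semi-landmark sliding moves each semi-landmark along the chord between
its `before`/`after` neighbours (tangent approximation, no curve
resampling). Two criteria are offered: thin-plate-spline bending energy
(default, solving the usual linearised system per specimen against the
consensus) and summed squared Procrustes distance (projection of the
residual onto the tangent). Two numerical safeguards, chosen here
because unconstrained bending-energy slides oscillated on noisy
synthetic outlines:

* each slide step is clamped to half the distance to the nearer
  neighbour, so points cannot cross along the curve;
* the outer slide/re-align loop (≤ 5 iterations) measures its objective
  in a fixed metric — the bending-energy matrix anchored on the initial
  consensus — and uses guarded acceptance: an iteration that would
  raise the objective is reverted and the loop stops. The recorded
  `slide_log` is therefore non-increasing by construction, and in
  practice all iterations on synthetic cohorts are genuine decreases.

Downstream statistics use the flattened Procrustes coordinates;
orthogonal tangent-space projection is available (`tangent_project`)
but the linear models operate on the coordinates directly, where the
projection difference is absorbed by the model intercept.

## Permutation shape statistics

Sequential (type-I) sums of squares are computed by Gram–Schmidt
orthogonalisation of the design blocks in model order: each term's SS
is the squared norm of the response projected onto the subspace the
term adds, which makes the decomposition exact (term SS + residual SS =
total SS to machine precision) and flags aliased terms by name.
F statistics use the full-model residual; effect sizes are
R² = SS_term / SS_total.

Significance uses residual randomization (RRPP): for each term, the
reduced model contains the preceding terms, its residuals are permuted
as whole rows, and the term's F is recomputed; full randomization is
available as an alternative. The p-value convention is
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), with 10,000 permutations by
default (tests and examples use 99–999 for speed; the permutation
p-value is unbiased at any count, only its Monte-Carlo error changes).
Allometry is the same machinery with a single (log by default) centroid
size term.

Morphological disparity is the per-group Procrustes variance: the sum
of squared deviations from the group mean shape divided by group size n
(not n − 1). Pairwise |PV_a − PV_b| tests permute residuals from the
*grand* mean and re-centre within the permuted groups. This choice
matters: permuting group-centred residuals (with or without re-fitting
the permuted group means) is strongly conservative on unit-centroid-size
shape data (empirical size ≈ 0.00–0.01 at α = 0.05), because the
unit-size constraint couples each specimen's deviations; the
grand-mean scheme is exact under exchangeability (empirical size 0.05)
while within-group re-centring still removes genuine location
differences between groups.

LDA classification uses a stratified seeded 70/30 split. Residuals from
the per-gear regression of shape on log centroid size are standardized
per column with training-set statistics (zero-variance columns
dropped), optionally projected onto principal components fitted on the
training data only — at most min(n_train − 3, components reaching 95%
cumulative variance) — before fitting the discriminant. The published
analysis did not state how ~182 shape variables were reduced for ~111
fish; PCA pre-reduction is our default and is logged.

## Deformation maps

Group mean shapes are compared with an interpolating thin-plate spline
mapping the reference onto `reference + magnification·(target −
reference)`; default magnification 4 for heat maps and 7 for grids,
matching the published figures. Local change is the log determinant of
the warp's analytic Jacobian on a 100×100 grid over the padded
reference bounding box: positive = expansion (red), negative =
contraction (blue). The original analysis used a proprietary local
deformation estimator whose algorithm is not described; the analytic
TPS Jacobian is a closed-form, testable stand-in producing the same
qualitative expansion/contraction maps, and our values are not asserted
to match any published colour scale. Fold-over cells (non-positive
determinant, common under large magnification of noisy means) are set
to NaN and counted in a warning rather than clipped. SVG output is
byte-deterministic (fixed hash salt, no timestamps).

## Condition models

SMI uses the standardized-major-axis slope sign(r)·sd(ln M)/sd(ln L)
and the arithmetic mean length L0; if all lengths are equal the ratio
term is 1 and SMI is defined as the observed mass. Caudal aspect ratio
is fin height²/area. OLS model selection enumerates every sub-model of
the stated full model that respects marginality (an interaction only
with both mains present), always including the null and full models,
and picks minimal AIC with ties (< 1e-6) broken toward fewer terms;
small-sample AICc is a flag. Note that plain AIC selects the true null
model only ~43% of the time when five 1-df terms are candidates (each
enters when its likelihood-ratio statistic exceeds 2); the unit tests
check agreement with that chi-square-derived rate rather than a fixed
percentage.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not real
zebrafish photographs. A stylized lateral template (19 fixed anatomical
points, 72 semi-landmarks equally spaced on six bowed outline curves,
standard length ~30 mm, body depth ~7 mm) is perturbed per fish, on the
unit-centroid-size scale, by:

* a **depth vector** u_depth (every landmark moved toward the
  anteroposterior axis in proportion to its dorsoventral offset,
  normalised to unit Procrustes norm) scaled by a standard-normal
  "shallowness" trait — positive values give shallower bodies;
* a **sex vector** (ventral abdominal bulge, females +);
* an **allometry vector** (relative head enlargement) scaled by centred
  ln length;
* isotropic landmark noise (default SD 1% of centroid size).

Effect magnitudes are in units of 1% of centroid size per SD of the
driving trait, the order of the ~1% of shape variance the vulnerability
effect explains in the study; the default vulnerability magnitude is 2.
Standard length is lognormal (median 30 mm, ln-SD 0.08); mass follows
M = aL^b with a = 1.5e-5 g/mm³, b = 3 and lognormal error (ln-SD 0.05),
plausible for adult zebrafish. Latent vulnerability is
β·shallowness + (1 − β)·independent noise with β = 0.8, so shallower
fish are more catchable — the direction reported for both gears.

Trawl outcomes come from a proportional-odds model over the severity
ordering with cutpoints (−1.1, 0, 1.1) (roughly equal outcome
frequencies at zero vulnerability) and slope 1.5; cod-end capture times
are uniform on [0, 600] s (no distribution was reported). Trap captures
are per-trial Bernoulli with logit −0.4 + 1.0·vulnerability. All draws
come from one seeded PCG64 generator (`numpy.random.default_rng`), so
cohorts and trials are fully reproducible from the seed.

What a green test does *not* establish: the generator has no
digitisation error model, no photographic distortion, no behavioural
correlation between trials, and its landmark noise is isotropic and
independent across landmarks — so passing recovery tests validates the
statistical machinery, not the biology of any particular cohort.

## Known limitations

* 2-D landmarks only; no missing-landmark estimation (absent landmarks
  are a hard error, as the study digitised complete configurations).
* The deformation maps are a methodological stand-in (see above).
* LDA is evaluated on the single stated 70/30 split; a repeat-seeds
  utility exists in tests but cross-validated accuracy is out of scope.
* Reproducing the published Table-1 F statistics exactly requires the
  deposited raw data and the unstated sliding options; the optional
  integration test asserts the qualitative significance pattern only.
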
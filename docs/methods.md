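# Methods

## Model

Screens are conditionally independent: population i yields k_i positives
out of n_i with k_i | q ~ Binomial(n_i, q), where q is the prevalence of
the species the population belongs to. Across species, q follows one of
two families:

* **beta(α, β)** — the two-parameter workhorse; with α, β < 1 it is
  U-shaped, which is the empirically typical shape for endosymbiont
  prevalences (most species nearly uninfected or nearly fixed).
* **doubly-inflated beta(α, β, γ, φ)** — point mass φγ at q = 0, φ(1 − γ)
  at q = 1, continuous beta mass 1 − φ. This accommodates genuinely
  trimodal prevalence distributions that the plain beta cannot.

The marginal pmf of a screen is the beta-binomial
C(n,k)·B(k+α, n−k+β)/B(α, β) for the beta family; the inflated family adds
φγ·1{k=0} + φ(1−γ)·1{k=n} on top of (1 − φ) times the beta-binomial. The
log-likelihood is the sum of log marginals over populations, **with** the
binomial coefficients: they are constant in the parameters, so estimates
and AIC *differences* are unaffected, but absolute AIC values assume this
convention. With φ = 0 the inflated likelihood reduces exactly to the beta
likelihood, which nests the families for AIC comparison (penalty 2 per
extra parameter).

Functionals, in closed form:

* mean prevalence μ = α/(α+β), or φ(1−γ) + (1−φ)·α/(α+β);
* incidence x_c = 1 − I_c(α, β), or (1−φ)(1 − I_c(α, β)) + φ(1−γ), where
  I_c is the regularized incomplete beta function. The point mass at q = 1
  counts toward incidence at every threshold; the mass at q = 0 never
  does, so x_c → 1 − φγ as c → 0.

Default thresholds are c = 10⁻³ and 10⁻⁴ ("more than one in a
thousand/ten-thousand individuals infected").

## Fitting

Optimization is unconstrained on (log α, log β, logit γ, logit φ):
Nelder–Mead to locate the basin, then BFGS to polish (objective tolerance
1e−8). Multi-start (default 10): one start from the moment estimator when
it is valid, the rest from dispersed N(0, 1.5²) draws on the transformed
scale, seeded. γ and φ are clipped to [1e−10, 1 − 1e−10], so point masses
never evaluate log 0; data with no zero/full screens push φ̂ to this
boundary harmlessly. A table that is all-negative triggers a boundary-fit
warning rather than an error.

Curvature CIs: the observed information (finite-difference Hessian of the
negative log-likelihood at the optimum, on the transformed scale) is
inverted to a covariance; the delta method with a numerical gradient gives
the standard error of μ or x_c, and Wald intervals are truncated to
[0, 1]. An indefinite or singular Hessian yields a flagged missing
interval, never a fabricated one.

## Moment estimators

For a group of S ≥ 2 screens with sample prevalences y_i = k_i/n_i:
μ̂ = mean(y_i) (equal weight per population; Σk/Σn available as an
option), and σ̂² = Var(y_i) − (1/S)·Σ y_i(1−y_i)/(n_i−1), where Var is the
empirical (ddof = 0) between-screen variance and the subtracted term
estimates the average binomial sampling variance (screens with n_i = 1
contribute μ̂(1−μ̂), having no internal replication). Matching beta
moments gives α̂ = μ̂·(μ̂(1−μ̂)/σ̂² − 1) and β̂ likewise. When sampling
noise dominates, σ̂² ≤ 0 (or ≥ μ̂(1−μ̂)) and the estimate is flagged
invalid: no beta parameters or incidence are produced. This is an expected
behaviour of the method on small or homogeneous groups, and downstream
tests automatically exclude invalid groups.

Bootstrap CIs resample populations with replacement (default 1000
resamples, percentile 2.5/97.5). Resamples with invalid moment estimates
are counted and excluded from incidence percentiles; an interval built
from fewer than half the resamples is flagged unreliable. The bootstrap
RNG must be independent of any stream that generated the data.

## Geography and phylogeny

Countries are represented by single midpoint coordinates; the packaged
centroid table is an approximate convenience fixture (country, latitude,
longitude, continent) and any analysis sensitive to midpoint choice should
supply its own. Distances are Meeus's ellipsoidal approximation on WGS84
(a = 6378137 m, f = 1/298.257223563): the great-circle distance on an
intermediate-radius sphere with first-order flattening corrections in the
mean latitude and latitude half-difference. Against a full geodesic it is
accurate to a few tenths of a percent, ample for country midpoints.

Patristic distances (path-length sums between tips) come from a
user-supplied Newick tree with branch lengths; dendropy handles parsing.
No comparative model is fitted — prevalence/incidence estimates do not
follow Brownian motion, so the only phylogenetic question asked is the
distribution-free one.

The Mantel statistic is the Pearson correlation of strictly-lower-triangle
entries of two labelled distance matrices; significance is by joint
row/column permutation of one matrix (default 9999 permutations),
one-tailed greater, with the add-one convention
p = (1 + #{r_perm ≥ r_obs})/(1 + N) so p is never 0. The incidence
variants automatically drop labels whose moment estimate is invalid.
Rank correlations use Spearman ρ with average ranks; latitude enters as
|latitude| (distance from the equator), longitude signed.

## Sample-size bias diagnostics

Two checks for the literature-compilation pathology that already-infected
taxa attract more screening effort: (1) screens binned by sample size
((0,10], (10,20], …, upper-bound edges) and Spearman ρ of bin size vs the
bin's detection rate (share of screens with k ≥ 1); (2) binomial (logistic)
regression of per-individual infection on n_i, slope on the log-odds scale
(statsmodels GLM). Caveat for (1): under a *continuous* prevalence
distribution the detection rate rises mechanically with n even without
any effort bias, because larger screens detect rarer infections; the
diagnostic is calibrated (≈5% rejection) only when detection is saturated.
The test suite therefore uses a point-mass world (q ∈ {0, 1}) as the null;
on real compilations the binomial-regression slope is the sharper of the
two diagnostics.

## Synthetic data

`SimConfig` defaults describe a realistic screen compilation: 300 species;
populations per species uniform on {1, 2, 3} (≈600 populations);
individuals per screen uniform on [1, 22] (mean 11.5, the
individuals-per-population average of large published compilations, and
wide enough to span three sample-size bins and exercise the n = 1 moment
branch); prevalence beta(0.24, 0.63); 22 countries with |latitude| evenly
spaced on [0°, 60°], alternating hemisphere, random longitudes. The
latitude gradient (default off) shifts each species' beta mean on the
logit scale by `latitude_effect` per degree of |latitude| with α+β fixed.

What the generator does **not** emulate: the taxonomic imbalance of real
compilations (one superfamily dominating), heterogeneous per-study
protocols and primer sensitivity, within-country sampling structure, and
spatial autocorrelation beyond the latitude gradient. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to those real-data features. One geometric
consequence of the alternating-hemisphere ladder: a latitudinal gradient
produces a strong |latitude| rank correlation but only a weak geographic
Mantel signal, since equal-|latitude| countries are geographically far
apart.

## Problem sizes and numerical choices

The test suite measures statistical properties at the sizes it states:
parameter recovery over 20 replicate databases of 600 populations,
CI calibration over 200 replicates (curvature: 300 populations; bootstrap:
100 populations of n = 25, 1000 resamples), Mantel type-I error over 200
null matrix pairs (20 labels, 999 permutations), gradient power over 50
replicate worlds. Likelihood evaluation groups duplicate (k, n) cells, so
each fit costs milliseconds and the whole suite runs in well under a
minute. Quadrature oracles use adaptive Gauss–Kronrod integration at
1e−12 tolerances; pmf-vs-oracle agreement is asserted at 1e−8 and
normalization at 1e−10.

## Known limitations

* The likelihood treats populations of one species as independent screens
  of independent draws from pdf(q); repeated populations of the same
  species actually share one q, which the fit ignores (a `--pool-species`
  switch pools counts per species first, trading this for loss of
  within-species resolution).
* Wald/curvature intervals can be optimistic when α̂, β̂ < 1 puts the
  optimum in a heavy-curvature region; bootstrap intervals are the
  fallback.
* Country midpoints compress all within-country geography; Mantel results
  are sensitive to the centroid table used.
* The moment estimator is undefined (flagged invalid) on homogeneous
  groups — by design, not failure.
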
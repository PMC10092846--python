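# Methods

## Nest-volume geometry

An open cup nest is modelled as half a spheroid. From the mean of up to
four diameter replicates and two height replicates per surface, the full
and inner cup volumes are `V = (2/3)·π·(D̄/2)²·H̄`, and the outer
(material) volume is their difference. Records with fewer than the
nominal number of replicates are averaged as-is rather than rejected,
because literature records frequently report single values. Units are
fixed to cm/cm³ at ingest; the table reader converts mm, the geometry
functions never rescale. When a digitised record's inner volume exceeds
its full volume by at most 0.5% the two are clamped to equality
(measurement noise); larger violations raise an error. After the
subtraction the full volume is re-derived as `inner + outer` so the
additivity identity holds bit-exactly in floating point. Rim thickness,
analysed as a response in its own right but rarely reported directly, is
computed as `(D̄ − d̄)/2`.

Handbook dimension tuples are interpreted by convention: unqualified
values refer to the external nest; "a × b" is length and width (two
perpendicular diameters); a third value in such a tuple is the height; a
lone "depth" figure is the external height unless it directly follows an
inner-cup diameter description, in which case it is the inner height.
Free-text parsing is out of scope — these rules apply to already
tokenised values.

## Tree-based estimators

The Brownian-motion covariance `C` of the tips has `C[i,j]` equal to the
root-to-MRCA shared path length; polytomies and zero-length internal
branches are handled naturally by this construction, with no arbitrary
resolution.

**Pagel's λ** multiplies the off-diagonal entries of `C`. At each λ the
root state and rate σ² are profiled out by GLS in closed form (ML,
divisor n) and λ is maximised over [0, 1] by bounded 1-D search with the
endpoints checked explicitly. The domain is capped at 1 rather than the
tree-specific theoretical maximum, matching common usage. On a star tree
the likelihood is constant in λ; the fit is flagged and λ = 0 returned by
convention. The reported 95% interval is the profile-likelihood interval
(χ²₁ cutoff). ML rather than REML is used throughout.

**Ancestral states** are the GLS phylogenetic means of the tips with the
tree re-rooted at each internal node; the required covariances are built
from unrooted path distances, `C_k[i,j] = (d(k,i)+d(k,j)−d(i,j))/2`,
which makes the estimate rooting-independent by construction and equal to
the empirical-BLUP conditional expectation (verified to 1e-8 against
that independent formula in the tests). The estimation variance is
`σ̂²/(1ᵀC_k⁻¹1)` with σ̂² the mean squared phylogenetic contrast
(divisor n−1), the convention behind the usual reconstruction CIs; 95%
bounds are ±1.96 sd. A zero-length pendant pair makes the re-rooted
covariance singular and raises an error naming the node.

**Evolutionary correlation** comes from the GLS cross-covariance
`R = (X−1â)ᵀC⁻¹(X−1â)/(n−1)` with `â` the GLS phylogenetic means;
`r = R_xy/√(R_xx R_yy)`. No derivation is standard for a p-value on this
quantity; the package applies a t statistic `r√((n−2)/(1−r²))` with n−2
df, a deliberate design choice that should be read as approximate.

Any per-tree estimator can be aggregated over a sample of topologies
(`over_trees`), after pruning all trees to their common tip set;
summaries are the per-tree values with mean/min/max. Pruning tips absent
from the trait table before analysis leaves estimates unchanged.

## The Bayesian phylogenetic mixed model

Record-level Gaussian model: `y = Xβ + Z u_phylo + Z u_species + e` with
`u_phylo ~ N(0, σ²_p A)` (A the BM covariance scaled to unit diagonal),
`u_species ~ N(0, σ²_s I)` capturing non-phylogenetic between-species
effects, and record-level residuals. Because species effects absorb
between-species variance, the residual corresponds to within-species
variability. For one-row-per-species data (the nestling-period model) the
species term is dropped.

Priors follow the standard weakly-informative choice for this model
family: univariate inverse-Wishart(V = 1, ν = 0.02) on each variance
component — implemented through the exact equivalence with
inverse-gamma(ν/2, νV/2) — and N(0, 10¹⁰) on fixed effects. Sampling is
conjugate Gibbs: all location effects jointly from their multivariate
normal full conditional via the mixed-model equations (one Cholesky per
iteration; the cross-product matrix is cached and only the diagonal
blocks are rescaled), then each variance from its inverse-gamma full
conditional with shape (ν + dim)/2 and rate (νV + S)/2. Chains are fully
reproducible from their seed.

Continuous predictors are transformed (log for sizes, masses and
durations; √ for precipitation and absolute latitude; signed-√ for
temperature, since breeding-season means can be negative) and then
mean-centred and scaled to unit SD. Standardization uses the population
SD (divisor n) so that two-point examples are exact; the divisor is
configurable. Reported standardized effects are posterior means of the
coefficients.

**Multi-tree pooling.** Phylogenetic uncertainty is handled by running
the sampler per tree and pooling the retained draws of chain 1, with
`floor((iterations − burn-in)/thin)` draws per tree; the published-style
schedule (2400/400/1000 over 1000 trees, three chains) retains 2 per tree
for a pooled sample of 2000 and is available via `paper_schedule()`.
Additional chains per tree serve only the Gelman–Rubin diagnostic
(reported as the per-parameter maximum over trees); pooling all chains
would triple the sample without adding independent trees. The desk-scale
default is 100 trees × (5000 iterations, 1000 burn-in, thin 20, 2
chains).

**Summaries and diagnostics.** pMCMC is `2·min(P(>0), P(<0))`, floored at
2/N to avoid reporting exact zeros from finite samples. HPD intervals are
shortest-window. Conditional R² is the posterior mean of
`(V_fix + σ²_p + σ²_s)/(V_fix + σ²_p + σ²_s + σ²_e)` with `V_fix` the
variance of the fixed-effect predictor over records. PSRF uses the
classic `√(((n−1)/n·W + B/n)/W)`; ESS is `N/(1 + 2Σρ_k)` truncated at the
first non-positive autocorrelation. The lag-1 autocorrelation is reported
against a 0.1 target; note it is meaningful at the thinned scale — a
thin-1 desk chain will legitimately show high lag-1 values while its ESS
is still large.

Repeatability (the between-species share of phenotypic variance in
replicated measurements) is a one-way random-effects variance-components
fit using the ANOVA estimator with the unbalanced-design coefficient
`n₀` and clipping at zero — deterministic, exact for balanced designs,
and well-behaved at the degenerate R = 1 and R = 0 corners. VIF is
`1/(1−R²_j)` from regressing each predictor on the others with intercept;
perfect collinearity raises, naming the predictor.

## Geospatial classification

Range polygons are filtered to breeding-or-resident (seasonal codes 1–2),
native (origin 1–2) and extant (presence 1); species losing all polygons
are flagged and excluded downstream. Occupancy on the 0.5° grid (0.25°
available for finer maps) uses the any-positive-area rule, consistent
with the fraction-greater-than-zero island rule; a minimum-cover fraction
is available for sensitivity checks. The range midpoint is the unweighted
mean of occupied-cell centers ("midpoint" has no canonical construction;
the cell-centroid choice matches the gridded workflow, and a
polygon-centroid alternative would differ mainly for very asymmetric
ranges). A midpoint exactly on the equator counts as northern
(deterministic tie-break). Climate zones split at |lat| = 23.5°, and the
breeding-season windows are March–June (northern temperate),
September–December (southern temperate) and the full year (tropical).
Climate values are the month-window mean per occupied cell, then the
unweighted mean over cells, excluding cells without data — no
latitudinal area weighting, mirroring the cell-mean averaging of the
gridded protocol (an area-weighted option exists, off by default).
Insularity keeps marine islands with 1 km² < area < 2,000,000 km²
(upper bound 2,000 km² in the small-island variant — the ambiguous
alternative threshold is implemented as the upper bound); a cell is
insular if the filtered island layer covers any positive fraction of it,
and a species is insular when its insular-cell share strictly exceeds
90%. Polygons running past ±180° are split at the antimeridian before
gridding.

## Synthetic data

The generator is the testing backbone: every output is a pure function of
(scenario, seed).

* **Trees** are pure-birth (Yule), simulated directly with exponential
  waiting times and a final hold time after the last split, so trees are
  exactly ultrametric and every pendant branch is strictly positive
  (off-the-shelf birth–death simulators that stop at the n-th birth event
  produce zero-length pendant pairs, which are singular for GLS).
* **Traits**: per-species phylogenetic effects with covariance
  σ²_p·A(λ) (λ applied to off-diagonals of the unit-diagonal relatedness
  matrix), iid species effects, standard-normal continuous predictors,
  Bernoulli binaries, record-level residuals, and a literature-vs-museum
  source offset (museum specimens systematically smaller). Default effect
  sizes mirror the headline standardized effects of the global nest-size
  analysis (body mass 0.750, temperature −0.145, insularity 0.209) so
  synthetic runs are magnitude-realistic; the records-per-species
  distribution is 1 + Poisson(0.3) capped at 14, matching the observed
  regime of ~1.3 records/species. The `recovery_scenario` preset
  (200 species × 2 records, β = (1.0, −0.5), variances 0.5/0.2/0.3) is
  the sampler-calibration workhorse.
* **Geography**: rectangular ranges along a latitude axis, some placed
  wholly on islands of stated area; temperature
  `T = 30 − 0.5·|lat| + 8·cos(2π(m−7)/12)·sign(lat)` (°C, northern-summer
  peak, phase-flipped across the equator); uniform precipitation.

What the generator does *not* emulate: real coastlines and precipitation
fields, spatially autocorrelated predictor structure, taxonomic
name-matching problems, and sampling biases of museum collections beyond
the scalar source offset. Passing tests therefore demonstrate estimator
correctness under the assumed model, not robustness to violations of it.

## Verification scales and numerical choices

The acceptance checks (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) use problem sizes chosen as the package's
desk-scale defaults: λ recovery at 200 tips × 100 replicates per
generating value; BPMM recovery on the 200 × 2 scenario over 20 seeded
replicates with single-tree chains of 3000 iterations (500 burn-in);
null-effect pMCMC calibration on 100 species × 2 records over 50
replicates; ancestral-state oracle on 100 random 5-tip trees. Cholesky
factorisations carry a 1e-10 jitter on the relatedness matrix; variance
draws are floored at 1e-12; the λ search uses xatol 1e-8.

## Known limitations

* Non-Gaussian responses, multi-response models and model selection (DIC)
  are out of scope, as are OU/EB trait models and tree inference.
* The p-value for the evolutionary correlation is an approximation (see
  above); treat it as indicative.
* Real BirdLife/WorldClim/GSHHG inputs are supported only through their
  file interfaces (GeoJSON polygons, gridded arrays); acquiring them is
  the user's responsibility.
* PSRF is computed across chains within each tree; disagreement *between*
  trees is genuine phylogenetic uncertainty and is deliberately retained
  in the pooled posterior rather than flagged as non-convergence.
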
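# Methods

## The statistical model

All comparative fits work on log₁₀-transformed traits. For species traits
`y` (response) and `x` (predictor) measured at the tips of a rooted
phylogeny with branch lengths, the allometric model is

    y = β₀ + β₁ x + ε,     ε ~ N(0, σ² V(λ)),

where `V(λ)` is the phylogenetic covariance: `V_ij` (i≠j) is Pagel's λ
times the root-to-MRCA path length shared by tips i and j, and `V_ii` is
tip i's root-to-tip depth, never rescaled. λ=0 recovers independent
species (ordinary least squares); λ=1 is pure Brownian motion. `σ²` is a
rate per unit branch length, so a tip's marginal residual variance is
`σ²·depth`.

Coefficients are generalized least squares, `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y`,
computed via Cholesky factorization. λ is estimated by maximizing the
profile likelihood (β and σ² profiled out analytically) with bounded
scalar optimization on [0,1] (tolerance 1e-6), with both endpoints checked
explicitly because the profile often maximizes at a boundary. ML is the
default; REML is a switch. The search domain is fixed to [0,1] — the
transformation is only guaranteed positive semi-definite there.

Reported summaries: `σ̂² = rᵀV⁻¹r/(n−2)`; `r² = 1 − RSS/TSS` with both
sums taken in the `V⁻¹` metric and TSS about the GLS-estimated
phylogenetic mean. The GLS r² has no unique definition; this one reduces
to the ordinary r² at λ=0 and keeps fits comparable across λ.

Batch fits accept "denominator minus response" predictors (e.g. brain
minus olfactory bulb) constructed on the raw volume scale before the log
transform, the convention used when the response is anatomically part of
the predictor.

## Prediction intervals and outliers

For a new observation at `x₀` with own phylogenetic variance `v₀₀` and
covariance vector `v₀` against the fitted sample, the best linear unbiased
prediction and its variance are

    ŷ₀ = x₀ᵀβ̂ + v₀ᵀV⁻¹(y − Xβ̂)
    Var  = σ̂² [ (v₀₀ − v₀ᵀV⁻¹v₀) + dᵀ(XᵀV⁻¹X)⁻¹d ],  d = x₀ − XᵀV⁻¹v₀,

with t-quantiles on n−2 degrees of freedom (the mitral-cell dataset scale,
n≈36, makes the normal approximation noticeably anticonservative).

Two conventions:

* **global band (default)** — `v₀ = 0`, `v₀₀ = tree height`: the single
  band a scatterplot draws for all species at once, modelling a
  hypothetical species unrelated to the sample. This is the convention the
  outlier flags use, since one band must serve every species in a figure.
* **placed tip** — pass the tip's actual (λ-scaled) covariance vector;
  used for leave-one-out checks and mirrored by the Bayesian predictor.

Outlier flags are evaluated exactly at each species' predictor value (no
grid interpolation), with the signed deviation reported in band
half-widths. In simulation the global band covers fresh unrelated tips at
95.2% over 2,000 draws spread across 20 replicate datasets; coverage
conditional on a single fitted dataset scatters roughly 85–100% because
the realized σ̂² and λ̂ enter the band, which is why the package's own
checks measure coverage across replicate fits. Leave-one-out placed-tip
intervals cover ~90% at n=24 — the usual mild undercoverage of plug-in
kriging-type intervals.

## Bayesian posterior prediction for a focal species

The exceptionality question ("is this species' trait larger than its
phylogenetic allometric expectation?") is answered with the focal species
excluded from the regression. A Metropolis–Hastings sampler runs over
(β₀, β₁, log σ², λ) with flat priors on β and log σ² and a uniform prior
on λ ∈ [0,1]; proposals are a joint Gaussian random walk, λ reflected at
the bounds (symmetric), initialized at the PGLS fit with step sizes from
its standard errors and adapted toward 20–45% acceptance during burn-in
only. Each iteration draws one tree uniformly (seeded) from the supplied
candidate set, so phylogenetic uncertainty propagates into the posterior.
Each retained iteration emits one predictive draw for the focal species
from its conditional normal given the non-focal tips:
mean `x₀ᵀβ + v₀ᵀV⁻¹(y−Xβ)`, variance `σ²(v₀₀ − v₀ᵀV⁻¹v₀)`.

Retained draws = ⌊(iterations − burn-in)/thinning⌋; the conventional
settings 100,100/100/100 retain exactly 1,000. "Burn-in 100" is short but
adequate because the chain starts at the PGLS mode. The verdict compares
the observed value with empirical quantiles of the draws; the percentile
uses mid-ranks for ties. With σ² fixed to 0 the model is degenerate and
the implementation returns the fixed-λ GLS regression-line value for every
draw (width 0) by construction.

Priors and proposal tuning are this package's choices; the published
procedure this mirrors specifies only the iteration schedule, so posterior
summaries are comparable but not guaranteed draw-for-draw identical to
other implementations. Calibration is checked instead: the percentile of a
model-true left-out species is uniform (KS test over 100 replicates), and
a +5 residual-SD planted outlier is called "above" the 95% credible
interval in ≥95/100 seeded runs at reduced iteration counts.

## Stereology

* **Optical fractionator**: `N̂ = ΣQ⁻·(1/ssf)·(1/asf)·(1/tsf)`. `tsf`
  defaults to 1 because the mounted-thickness disector height is often
  unreported; it is configurable. Unbiasedness requires uniformly random
  section and grid offsets, which the synthetic sectioning honours.
* **Gundersen–Jensen CE**: `CE = √(ΣQ + VarSURS)/ΣQ` with
  `VarSURS = (3(A−ΣQ) − 4B + C)/240` (smoothness class m=1, the default
  for smooth biological profiles; m=0 with divisor 12 available), where
  A, B, C are the lag-0/1/2 sums of products of per-section tallies. The
  ΣQ term is the Poisson counting "nugget".
* **Cavalieri volume**: `V = Σ(areas) × spacing`, with spacing = mounting
  interval × cut thickness (e.g. every 4th section × 40 μm = 0.16 mm).
  The phrase "multiply by distance between sections and slice thickness"
  in histology write-ups is dimensionally ambiguous; this product
  (interval-in-sections × thickness, i.e. one length) is the only reading
  that yields mm³ and is the standard Cavalieri estimator. It is the
  reading implemented here.

## Two-species comparisons

Pooled-variance (Student) two-sample t-tests, df = n₁+n₂−2, are the
default: at the n=3-per-species scale of whole-brain histology, pooled is
the convention that reproduces published p-values computed from summary
tables; Welch is available. If both SDs are zero with unequal means, the
p-value is reported as the smallest positive float rather than 0.
Proportional comparisons run on per-specimen proportions (region/brain,
olfactory bulb/telencephalon), not ratios of means; count-valued measures
(mitral cells) are excluded from brain-volume proportions since they are
not volumes.

## Synthetic data: what it does and does not emulate

The generators produce data under exactly the model the estimators assume:
birth–death trees (terminal branches extended by one exponential waiting
time so the stopping rule cannot create zero-length cherries and singular
covariances); a Brownian predictor; residuals drawn jointly multivariate
normal with covariance σ²V(λ) — not tip-independent noise — so λ recovery
is a meaningful test; raw-scale (antilog) export so the pipeline's own
log₁₀ step is exercised. Default parameters sit inside the ranges avian
brain-region allometries span (slope 0.9, λ 0.92, σ² 0.05); the
two-species generator defaults to the reported vulture means with an
olfactory-bulb enlargement factor of 4 and ~8% lognormal specimen noise
(the magnitude implied by the reported SDs); specimen sub-region volumes
are capped at 95% of that specimen's brain volume so independent noise
cannot produce anatomically impossible rows.

Passing tests therefore show the estimators are correct *under their own
assumptions*. Real data violate these in ways the generators deliberately
do not emulate: measurement error in both variables, non-Brownian
evolution (selection, rate shifts), topological error beyond the supplied
tree set, and body-size allometry of the predictor itself. The
cell-field generator places cells uniformly in a sphere; real mitral cells
form a layered shell, which changes per-section profiles but not the
fractionator's unbiasedness (which depends only on the random offsets).

## Problem sizes and numerical choices

The package's own checks use: 20 small trees for exact GLS agreement
(1e-8), 200 datasets of 100 tips for slope/λ recovery, 2,000 draws for
band coverage, 100 replicates each for MCMC calibration and planted-
outlier detection at reduced iteration counts (2,100 and 1,100 iterations;
the draw-count bookkeeping is verified once at the full 100,100), 100
seeded fields for fractionator unbiasedness. These sizes keep the full
suite to well under an hour on one core while leaving Monte-Carlo error
comfortably inside the asserted tolerances.

Ties and degenerate inputs: consensus clades need strictly more than the
threshold frequency (exact 50% ties are excluded, making output
deterministic); consensus branch lengths are arithmetic means over
supporting trees (the common default; other consensus utilities differ and
the choice is documented rather than load-bearing); zero-length internal
branches are accepted; a singular V(λ) raises an error naming the
offending λ; trait/tip mismatches are hard errors unless an explicit
intersect flag is passed, which logs the dropped count.

## Known limitations

* Univariate PGLS only; no multivariate response, no
  Ornstein–Uhlenbeck or other correlation structures.
* The MCMC is a plain random-walk sampler; for very large trees a
  gradient-based sampler would mix better per unit time.
* The λ-profile likelihood can be flat on small trees; λ̂ is then poorly
  identified (its sampling SD at n=20 is large) even though the slope
  remains well estimated.
* Published allometric fit values for the real 145-species dataset can
  only be checked with that dataset and its candidate trees supplied by
  the user (`phyloallometry.external.table2_check`); they are not
  asserted by the test suite.
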
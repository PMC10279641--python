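# Methods

## The estimator

The pipe-model view of tree form holds that the amount of leaves a tree
carries is proportional to the stem cross-sectional area at the crown base,
`A_CB`.  Measuring `A_CB` requires climbing to the crown base, so this package
centres on the quasi-pipe (qPipe) surrogate computed from ground measurements
only:

```
A_CB_Est = A_BH · R_CROWN,      R_CROWN = L_C / H_>1.3
```

with `A_BH` the stem area at breast height (fixed at 1.3 m), `L_C = H − h_cb`
the crown length and `H_>1.3 = H − 1.3` the stem length above breast height.
The estimator is exact when the stem between breast height and the treetop is
a paraboloid of revolution with apex at the treetop.  For a general relative
taper profile `A = L^(2/X)` (`X = 1` cone, `2` paraboloid, `3` cubic solid of
revolution) the per-tree relative error is `A_CB_Est/A_CB = l^(1 − 2/X)` at
relative crown length `l`: an overestimate for `X < 2`, an underestimate for
`X > 2`.  `geometry.taper_exponent_from_observation` inverts the profile to
place measured trees against the `X = 1, 2, 3` reference curves.

Breast height is deliberately not configurable: every inclusion filter and
the stem-length scale reference 1.3 m.  Trees whose crown base reaches the
treetop (zero crown) are rejected at record construction, because
`R_CROWN = 0` implies zero leaf amount and breaks the ln-scale regressions.

## Regression pipeline

All allometries are fitted on natural logs of positive quantities.

**Model II (SMA)** establishes slopes.  Per group, slope
`b = sign(r)·sd(y)/sd(x)`, elevation `exp(ȳ − b·x̄)` (the response at a
predictor of 1 m²), slope CI via `b(√(B+1) ± √B)` with
`B = F₁,ₙ₋₂(1−α)·(1−r²)/(n−2)`.  Grouped fits add the likelihood-ratio test
of a common slope — minimise `−Σ nᵢ ln(1−rᵢ²(b))`, where `rᵢ(b)` is the
correlation between the SMA residual and fitted axes in group *i*, and refer
the minimised statistic to χ² with (groups − 1) df — and, when slopes are
homogeneous at the 5% level, Wald comparisons of elevations at the common
slope with Sidak-corrected pairwise p-values.  The common-slope variance used
in those comparisons is the inverse-variance pool of the per-group slope
variances `b²(1−r²)/(n−2)`; the null calibration of the whole construction is
checked by simulation in the test suite.  The `robust` flag replaces the
means/variances/covariance entering these formulas by Huber-weighted moments
(weights `min(1, k·√2/dᵢ)` on the bivariate standardized distance,
`k = 1.345`, iterated to 1e-8, at most 50 iterations); with fewer than five
points it falls back to the standard moments with a warning.

**Model I** supplies predictions.  OLS is closed-form with the exact
t-based prediction interval.  The species random-intercept model
`y = β₀ + β₁x + u_species + ε`, `u ~ N(0, σ_b²)`, is fitted by profiling the
likelihood over the single variance ratio λ = σ_b²/σ²: for fixed λ the GLS
estimates and the profiled σ² are closed-form (block Woodbury identities), so
the whole fit is a bounded scalar optimisation (tolerance 1e-8 on ln λ, λ in
[e⁻²⁵, e¹²], with the λ = 0 boundary checked explicitly).  Variance
components are reported from REML; the AIC is always computed from the full
ML fit so that models with different fixed-effect structures are comparable
(`k` counts fixed effects plus variance components).  Model selection is
minimum AIC over the converged candidates, ties (Δ < 1e-9) going to the model
with fewer parameters; degenerate (perfect-fit) likelihoods raise a
convergence error and the candidate is discarded.  A profile-likelihood CI
(χ²₁ inversion of the ML deviance) is available for σ_b.  The implementation
is cross-checked against statsmodels' general mixed-model fitter in the test
suite; agreement is ~1e-5 on fixed effects and ~1e-3 relative on variance
components.

**Prediction intervals for new trees.**  The mixed-model interval uses the
normal quantile on `σ² + σ_b² + Var(x₀'β̂)` — the interval for a tree of a
new, unobserved species; the printed global interval approximations are taken
as complete, with no extra random-effect inflation.  When an allometry is
fitted locally, the interval is stored either as the exact least-squares form
`ΔPI = t·s·√(1 + 1/n + (u−ū)²/Sxx)` (OLS winner) or as a quadratic
`c₀ + c₁u + c₂u²` least-squares fit to the exact pointwise mixed-model
half-widths over the observed predictor range (200-point grid); across the
middle 90% of that range the quadratic deviates from the exact half-width by
well under 1%.

**Back-transformation bias.**  A ln-scale fit predicts the median of the
response; point predictions are multiplied by `CF = exp(σ̂²/2)` with σ̂ the
ln-scale residual sd.  This reproduces the printed global CFs within rounding
(e.g. σ̂ = 0.3855 → CF 1.077 for the pooled qPipe leaf-area equation).
Interval bounds are placed around the *uncorrected* ln-scale prediction — the
regression's natural scale — while the point estimate carries the CF; a
`cf_in_bounds` toggle recentres the bounds on the corrected prediction for
users who prefer a CF-consistent triple.

**Outliers.**  Grubbs' two-sided test (critical value from the t-quantile
construction) is applied iteratively to fit residuals — remove the most
extreme value while `G = max|v−v̄|/sd` exceeds its critical value, stop below
n = 3 — with α = 0.05 by default (the level is exposed, as the original
analysis did not state one).  Filtering is idempotent and deterministic, ties
broken by first occurrence.

## The shipped registry

`qpipe/data/global_registry.yaml` carries the published global coefficients:
a pooled leaf-area equation for each predictor (pipe: elevation 2370, slope
0.940, CF 1.065; qPipe: 2742, 0.955, 1.077; n = 768) and per-PFT qPipe
leaf-mass equations (EC 854.4/1.078/1.023, DC 571.4/1.172/1.059, EB
293.8/0.973/1.073, DB 180.3/1.017/1.073), each with its 95% interval
approximation.  The DC leaf-mass interval uses the exact least-squares form,
whose coefficients decode as `c₀` = t-quantile (2.004, 55 df), `c₁` =
residual sd, `c₂` = n (57), `c₃` = mean ln-predictor (−5.206) and `c₄` = its
sum of squares (62.89); both interval forms therefore take
`u = ln(predictor area in m²)`.  Leaf-area prediction ignores PFT (a pooled
equation was selected); leaf-mass prediction requires the tree's PFT.
Calibrated predictor ranges are stored as soft bounds of 1e-6–2 m² — the
published per-entry axis extents are not recoverable from the text we work
from, so out-of-range predictions warn rather than fail.  Site-specific
registries use the same YAML schema.

## Stand aggregation

The stand LAI (or leaf biomass per ground area) is `Σ pointᵢ / area` over the
per-tree predictions.  For the 95% bounds, each tree's interval
`exp(μᵢ ± z·σᵢ)` identifies a lognormal on the ln scale; treating trees as
independent (the only option available to a user holding published
coefficients, and a known approximation), the mean, variance and third
central moment of the stand total are the sums of the per-tree lognormal
moments, and the bounds are the 2.5/97.5 percentiles of a *shifted lognormal*
matched to those three moments.  This choice is deliberate: per-side
quadrature of arithmetic half-widths (`√Σδ²`), the most common propagation
rule, misstates the percentiles of a sum of asymmetric lognormals by roughly
20% at the residual scatter implied by the global CF (≈0.39 ln-scale) for a
30-tree stand, and two-moment lognormal matching still errs by ~8% when a few
large trees dominate the total.  Three-moment matching is exact for a single
tree and in the many-equal-trees normal limit, and agrees with a 50,000-draw
Monte-Carlo of the stand total to ≲1% relative half-width in the test suite.
Quadrature (`method="quadrature"`) and a delta-method log-scale variant
(`method="log"`) remain available for comparison.

`compare_methods` evaluates several (label, allometry) pairs on identical
trees — e.g. site-specific pipe vs site-specific qPipe vs global qPipe — and
the report writer emits one delimited row per method.

## Synthetic data

`SimulationConfig` defaults define the generator's study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_trees`, `n_species` | 500, 30 | inventory size; species assigned round-robin to the four PFTs |
| `height_ln_mu/sd` | 2.5, 0.45 | `H = 1.3 + LogNormal` → median ≈ 13.5 m above breast height |
| `dbh_ln_mu/sd`, `size_corr` | −1.9, 0.55, 0.9 | dbh median ≈ 0.15 m, correlated with height through a latent size factor |
| `crown_ratio_a/b` | 5.0, 2.5 | Beta crown ratio, mean ≈ 0.67 |
| `taper_median`, `taper_ln_sd` | 2.0, 0.15 | lognormal taper exponents centred on the paraboloid |
| `la_elevation`, `la_slope` | 3000 m²·m⁻², 1.0 | true leaf-area allometry vs A_CB (slope 1: the pipe-model proportionality) |
| `residual_sd` | 0.385 | ln-scale scatter — the value implied by the published pooled CF 1.077 |
| `species_sd` | 0.3 | ln-scale species intercept sd |
| `base_lma`, `href`, `gamma_lma` | 0.100 kg·m⁻², 15 m, 0.3 | tree LMA = base·(H/href)^γ; γ = 0.3 steepens the leaf-mass slope by ≈ 0.1 over the leaf-area slope, matching the published slope gap |

Heights, diameters and taper exponents are lognormal and crown ratios
Beta-distributed — choices made for positivity and realistic right skew, not
taken from any source, and all overridable.  Each tree's true `A_CB` comes
from its own taper curve, so the qPipe error structure `l^(1−2/X)` is exact
by construction.  One root seed spawns a splittable per-tree stream
(`SeedSequence.spawn`), so the first *n* trees of a larger run reproduce the
*n*-tree run exactly.

What the generator does **not** emulate: measurement error in the predictor
(so SMA slopes on synthetic data exceed the generating Model-I slope by the
usual attenuation-free margin), crown asymmetry, top breakage, epicormic leaf
turnover, spatial structure and competition, and non-lognormal residual
tails.  Passing tests therefore certify the statistical machinery under the
stated error model, not the field behaviour of any particular forest.

## Problem sizes used in the checked runs

Simulation-based checks run at: 500-tree inventories (30 replicates) for the
leaf-mass/leaf-area slope comparison; a 50-species × 20-tree design with 100
replicates for CI-coverage of (slope, elevation, species sd); 2000 fitted +
2000 held-out trees for interval coverage; and a 30-tree stand against a
50,000-draw Monte-Carlo oracle for the propagation rule.  These sizes give
binomial/Monte-Carlo noise comfortably inside the asserted tolerances.

## Known limitations

- Independence across trees in the propagation ignores the shared sampling
  uncertainty of the allometry's coefficients; with published coefficients
  only, no covariance term is computable.
- The robust SMA weighting is one reasonable Huber-type scheme; other robust
  estimators would give slopes differing at the ~0.01 level.
- The common-slope LR statistic weights groups by nᵢ without a small-sample
  correction; its null behaviour is verified by simulation at the group sizes
  used here.
- Monocot exclusion relies on a per-row flag or a user-supplied species list;
  no taxonomy is bundled.
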
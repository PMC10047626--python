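# Methods

## The model

`matemeta` estimates how strongly mate choice depends on the chooser's own
state (age, attractiveness, body size, condition, mating status, parasite
load) by meta-analysing correlation coefficients across studies and species.
Each extracted result is converted to a correlation *r*, sign-coded so that
*r* > 0 means "choosier when young / attractive / large / in good condition /
mated / lightly parasitized", and transformed to Fisher's Z,
`zr = arctanh(r)`, with sampling variance `v = 1/(n − 3)` where *n* is the
total number of animals in the test.

The coded effects are modelled with a four-level random-effects structure:

```
zr_i = β0 (+ moderator terms) + a_sp(i) + s_sp(i) + u_study(i) + e_i + m_i
```

* `a` — phylogenetic effects, jointly normal with covariance
  `σ²_phylo · A`, where `A` is the Brownian-motion correlation matrix of the
  species tree;
* `s` — independent species effects, variance `σ²_species`;
* `u` — study effects, variance `σ²_study`;
* `e` — observation-level effects, variance `σ²_obs` (required to estimate
  residual heterogeneity when several effects share a study);
* `m_i` — known sampling error, variance `v_i`.

Variance components are estimated by restricted maximum likelihood; fixed
effects are the GLS solution at the REML variances, with Wald-z 95%
confidence intervals (a `crit="t"` flag switches to t critical values).
Prediction intervals add the summed variance components to the squared SE
before back-transforming with `tanh`.

### Effect-size conversions

* Group comparisons: Hedges' d with the small-sample correction
  `J = 1 − 3/(4(n1+n2−2) − 1)`, then `r = d / sqrt(d² + a)` with the exact
  unequal-n constant `a = (n1+n2)²/(n1 n2)`. The common `a = 4`
  approximation is *not* used; the exact form reduces bias for the
  unbalanced designs typical of field studies. Note the t-statistic route
  (`d = t·sqrt(1/n1 + 1/n2)`) carries no J correction — the two routes agree
  exactly once J is divided out, and differ by O(1/n) otherwise.
* Two-group test statistics: t as above; F with one numerator df as
  `|t| = sqrt(F)`, the sign supplied by the recorded direction.
* 2×2 choice-frequency tables: the phi coefficient
  `(ad − bc)/sqrt((a+b)(c+d)(a+c)(b+d))`. Tables with a zero margin are
  rejected; a single zero cell is computed as-is (no continuity correction).
* Reported correlations of exactly ±1 are clamped to ±0.999 (logged) so the
  Z transform stays finite.
* The variance is `1/(n − 3)` for every data type, keyed to total n.

Nonsignificant results reported without a direction ("directionless" points)
are coded `zr = 0` — keeping their true `1/(n−3)` variance, not an inflated
one — and analyses run on both a *full* variant (zeros retained) and a
*reduced* variant (zeros dropped).

### Phylogeny

Input supertrees carry topology only, so branch lengths are set by Grafen's
method: each internal node at height `(descendant tips − 1)^ρ` (ρ = 1, the
method's default), normalized to root height 1, tips at height 0. The
Brownian correlation between two species is then the root-to-MRCA depth.
Polytomies are kept as-is — the node-height rule handles them and resolving
them randomly would inject noise. Subset analyses re-prune the tree and
re-calibrate by default (a `recalibrate=False` flag instead inherits the
full tree's branch lengths; both keep depth 1, but re-calibration re-derives
heights the same way the full tree got them, keeping variance components
comparable — chosen as the default for exactly that reason).

### Heterogeneity

Total and level-wise I² follow the multilevel partition against a "typical"
sampling variance `σ²_m = (k−1)Σw / ((Σw)² − Σw²)`, `w_i = 1/v_i`:
`I²_level = 100 σ²_level / (Σσ² + σ²_m)`. The level values are additive to
the total by construction. I² is reported from the intercept-only fit;
moderator models report marginal R² instead:
`R² = Var(Xβ̂) / (Var(Xβ̂) + Σσ²)` with the sample variance over the k
fitted values.

### Moderators

One meta-regression per moderator (no interactions). The omnibus fit uses
reference-level dummy coding and excludes categorical levels with fewer than
10 effects; significance is the Wald chi-square QM over the non-intercept
coefficients. Per-level means come from a no-intercept refit with one
indicator per level on *all* records (including small levels). Pairwise
post hoc contrasts among the well-populated levels use Wald z with Holm
adjustment (the adjustment method was an open choice; Holm dominates
Bonferroni at no distributional cost).

### Publication bias

Two multilevel meta-regressions, both through the same REML code path:

* the *test* model: no intercept, covariates = mean-centered publication
  year and the standard error `sqrt(v_i)` (a multilevel Egger-type test).
  The minus-intercept form is implemented literally as specified;
  `include_intercept=True` restores the conventional all-in variant.
* the *adjustment* model: intercept + mean-centered year + the variance
  `v_i`; `tanh` of the intercept is the bias-adjusted mean correlation with
  its CI/PI. The two models deliberately use different precision covariates
  (SE vs variance). The adjustment is always computed, significant trend or
  not. Constant covariate columns are dropped with a warning, so degenerate
  designs collapse to the unadjusted fit.

## Numerical choices

* REML optimization on log-variances: L-BFGS-B with the analytic score
  (`dl/dσ²_l = ½[(Py)'M_l(Py) − tr(P M_l)]`) from five starts (equal split,
  zero boundary, all-in-one-component, 0.1 each, observation-heavy),
  followed by a Nelder-Mead polish (fatol 1e−10). Components driven below
  1e−12 are reported as exactly 0.
* If the marginal covariance fails its Cholesky factorization, a 1e−10
  ridge is added once, with a logged warning.
* Fixed components: `fit_reml(..., fixed_sigma2={...})` pins named
  components (used e.g. to reduce the bias test to classic weighted Egger
  regression in validation).
* Species labels are matched after space/underscore normalization and case
  folding; no fuzzy synonym matching.
* CSV round trips are bit-exact (`float_precision="round_trip"` on read).

## The synthetic-data generator

`SimulationTruth` defaults define the standard study conditions used by the
validation studies: 40 species (Yule topology via sequential random tip
splitting, Grafen-calibrated), 80 studies × 2 effects (k = 160), grand mean
β0 = 0.1 Zr, variance components (phylogeny, species, study, observation) =
(0.02, 0.01, 0.03, 0.04) — moderate heterogeneity with I² ≈ 85%, matching
the "high heterogeneity, small mean" regime typical of multispecies
behavioural meta-analyses — per-test sample sizes uniform on 10..100
(behavioural mate-choice tests rarely exceed ~100 animals), years 1980–2020,
no trend and no censoring unless requested. Censoring converts
nonsignificant effects (two-sided 5% Wald) to directionless zeros with
probability `censor_prob`; significant effects are never censored. A single
root seed is split into per-stage streams so adding a stage never perturbs
earlier draws.

What the generator does *not* emulate: real taxonomic composition,
correlated moderators, study-specific measurement scales, non-normal true
effect distributions, or dependence between sample size and effect size
other than through censoring. Passing recovery tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness to
their violation.

## Validation studies and their problem sizes

* **Oracle equivalence** — 20 random fixtures (k ≤ 15, two variance
  components, half with a phylogenetic structure) fitted both by the
  production path and by an independent dense brute-force REML (explicit
  `inv`/`slogdet`, simplex search on the SD scale). Agreement is ~1e−8,
  asserted at 1e−6 (β) and 1e−4 (σ²). One fit is also cross-checked against
  `metafor::rma.mv` via Rscript; estimates agree to ~4 decimals.
* **Parameter recovery** — 200 independent datasets at the default design.
  β0 bias and CI coverage are scored, and mean variance components are
  required to track truth within 3×MC-SEM (floor 0.003, allowing the small
  skew from truncating boundary estimates at zero).
* **QM calibration** — 2000 null datasets (3-level moderator with no effect,
  60 studies × 2 effects, study+observation components only, n ∈ 40..200);
  the type-I error at α = 0.05 is asserted within [0.035, 0.065] (measured
  values across seeds fall around 0.04–0.065).

## Known limitations

* **Wald CI coverage of the grand mean under strong phylogenetic structure
  is anticonservative.** At the default recovery design the measured 95% CI
  coverage is ≈ 0.80–0.84 depending on seed, not 0.95. This is a property of the estimator class,
  not of this implementation: `metafor::rma.mv` produces the same estimates,
  SEs and coverage on identical data. The cause is that σ²_phylo is weakly
  identified — a calibrated tree offers only a few effectively independent
  deep clades — and the plug-in Wald interval ignores the uncertainty in
  σ̂²_phylo. Profile-likelihood or parametric-bootstrap intervals would be
  needed for nominal coverage; they are out of scope here.
* The QM test is asymptotic; at few effects per level it turns mildly
  liberal (the calibration study uses ≥ 40 per level).
* Frequency-table payload inversion in the generator is exact only up to
  integer-count discretization.
* No robust (cluster-sandwich) variance estimators, likelihood-ratio model
  comparison, trim-and-fill or selection models, odds-ratio/survival
  conversions, or >2-group designs.
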
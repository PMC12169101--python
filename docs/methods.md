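# Methods

## Data model and preprocessing

The unit of observation is one taxon's abundance at one site.  Sites nest
in studies (a location/year dataset), studies nest in sources (a primary
publication).  A study enters the analysis only if it has at least one
reference site and one managed site; violations are excluded with a
machine-readable reason in the exclusion log, never silently.

**Site averaging and the zero-fill rule.**  Abundances are averaged
arithmetically over the sites of each study × system.  A species recorded
at some sites of a study × system but not others is treated as an observed
zero at the sites where it is absent: absence from a sampled site is data,
and the alternative (averaging only over sites of presence) systematically
inflates means for patchy species.  A species never recorded in a
study × system is absent, not present at density zero; consequently a
reference-side species always has strictly positive mean abundance, and
this is validated at comparison time.

**Taxon names** are matched after trimming, collapsing internal whitespace
and case-folding; the original spelling is preserved.  A name without a
second epithet is genus-level and is matched across communities by name
equality like any other label, but never matches the threat-status table,
whose keys are binomials.  Threat status joins by exact normalized binomial;
unmatched is a valid outcome, not an error.  The threatened-animal subset
keeps VU/EN/CR animal records only, and is modelled for similarity,
richness and total abundance but not intactness.

## Metrics

Per study × managed system, against the study's reference community:

- IN = mean over reference species of min(A_m/A_r, 1).  Managed-only
  species are removed before ratios are formed; truncation at 1 stops
  abundance increases of some species from masking losses of others.
  Truncation is applied after site averaging, following the stated
  processing order (average, then ratio, then truncate).
- SI = 2T/(2T+F), with F the total count of species unique to either side.
- SR = ln(S_m/S_r); TA = ln of the total-abundance ratio, with novel
  species contributing to the managed side.  When a side has zero richness
  or zero total, SR/TA are recorded as missing rather than clamped — no
  pseudo-count convention is assumed.

Metric values are stored untransformed; the Smithson–Verkuilen compression
is a modelling device and is applied inside the fitting routine, with n
equal to the number of observations entering that particular fit (per
metric × subset, after subsetting and row exclusions).

## Mixed models

**Beta family (IN, SI).**  y_i ~ Beta(μ_i φ, (1−μ_i) φ) with
logit(μ_i) = x_i'β + u_source [+ v_study].  Study weights w_i = √(reference
richness) multiply the per-observation log-likelihood terms, raw and
unnormalized.  The marginal likelihood integrates the random intercepts
numerically: adaptive Gauss–Hermite quadrature (15 nodes by default,
recentred and rescaled at each source's conditional mode) for the single
intercept, and a Laplace approximation over each source's joint
(u, v_1..v_S) block for the nested structure.  The inner mode search is a
damped Newton iteration with per-source backtracking so accepted steps
never decrease the penalized objective — this keeps the outer likelihood
surface smooth, which finite-difference optimization requires.  Outer
parameters (β, ln φ, ln σ) are maximized by BFGS from seeded multi-starts
(3 by default), followed by a simplex polish and a BFGS restart; variance
parameters live on the log scale.  Standard errors come from the inverse
finite-difference Hessian of the negative marginal log-likelihood; a
non-positive-definite Hessian is repaired by eigenvalue clipping and the
fit flagged.

**Gaussian family (SR, TA).**  Weighted linear mixed model with
Var(e_i) = σ_e²/w_i (weights as residual-precision multipliers, the lme4
convention), fit by maximum likelihood with β profiled out by GLS at each
variance evaluation; the marginal covariance is built densely, which is
cheap at metric-table sizes (hundreds of rows).  A random-effect variance
optimized to numerical zero is reported as a singular fit, not an error.
Fixed-effect p-values use the normal approximation without denominator-df
corrections.

**Coding.**  With management as the only fixed effect the design is
cell-means (one coefficient per system, no intercept), so each coefficient
is directly that system's link-scale mean; with additive covariates
(taxonomic class, continent, time) the model switches to treatment coding
with the alphabetically first system as baseline.  Log time is ln(t+1) so
freshly harvested stands (t = 0) are admissible.

**Random structures.**  Pooled animal models use nested source/study
intercepts; plant, per-class, threatened and per-system time models use a
source-only intercept (those subsets rarely have multiple studies per
source).  Per-system time models always use the source-only structure.

**Inference.**  Omnibus tests are likelihood-ratio chi-square tests of
nested fixed-effect structures on identical rows and random structure, with
df equal to the parameter-count difference.  Time-form selection fits
intercept-only, linear-time and log-time models per system (≥5 dated
records required) and picks the lower-BIC time form, ties going to linear;
BIC = −2ℓ + k ln n with k counting fixed effects plus dispersion plus
variance components.  Pairwise contrasts are z-tests on link-scale
coefficient differences, Bonferroni-multiplied by the number of pairs
actually formed, and only ever within the wood set or within the food set —
wood- and food-producing systems serve different functions and are not
interchangeable, so cross-set comparisons are not meaningful.  The
Bonferroni correction (not the studentized range) governs the adjustment.
Back-transformation maps estimates and Wald interval endpoints through the
inverse link (inverse logit, or exp for log-response ratios); percent
change is (1 − value) × 100 against the reference level of 1.

## Synthetic databases

The generator emulates a compiled field-study database: sources (default
60) with 1–3 studies each, studies covering 1–2 managed systems plus a
reference, communities of mean richness 20 drawn from a lognormal
species-abundance distribution (ln-scale mean 1, sd 1), replicated over 3
sites with multiplicative lognormal observation noise (sd 0.3, unit mean).
A system transforms the reference community by extirpating each species
with probability p_loss, multiplying survivors by exp(L) with
L ~ N(logratio_mu + source effect + time effect, logratio_sigma²), and
adding Poisson(influx) novel species.  Source effects are N(0, 0.5²) on the
log-ratio scale.  Default per-system (mu, sigma, p_loss, influx) values
follow the intervention-intensity gradient seen in real managed-forest
compilations — partial-harvest systems mild (RI: −0.5, 0.8, 0.05, 1),
plantation-style systems severe (PL: −1.0, 0.8, 0.35, 2; PC: −1.5, 0.8,
0.55, 2) — chosen so that expected richness ratios are ≈1 for the light
wood systems, ≈0.75 for forest plantations and ≈0.55 for perennial tree
crops, and expected intactness declines from ≈0.6 (RI) to ≈0.14 (PC).
Threat categories are assigned independently of effect size with 10%
prevalence by default; an optional vulnerable-specialist mode is a
documented extension point, off by default.

Expected intactness has the closed form
E[IN] = (1−p_loss)·(e^{μ+σ²/2} Φ(−μ/σ−σ) + Φ(μ/σ)) with σ² the total
log-ratio variance including the source component; it was verified against
10⁶-draw Monte Carlo before being used as a test oracle (σ = 0 degenerates
to min(e^μ, 1)·(1−p_loss)).

What the generator does **not** emulate: spatial structure, phylogenetic
correlation, temporal autocorrelation within studies, detection error that
differs between managed and reference sites, and taxonomic synonym noise.
Passing tests therefore demonstrate that the pipeline recovers known
effects from data with the right nesting, abundance and effect structure —
not that any particular real-world compilation satisfies those assumptions.

## Validation design and problem sizes

The validation suite simulates at the model level where the question is
purely statistical, and end-to-end where the pipeline plumbing matters.
Recovery of logit-scale system means uses 100 replicates of 200 studies
(three systems, source SD 0.5, φ = 10) with equal weights, so the weighted
estimator coincides with exact maximum likelihood and Wald coverage is
interpretable against its nominal level; bias is assessed per system and
coverage pooled over the three system means.  Likelihood-ratio calibration
uses 500 null Gaussian-family simulations (150 observations, 50 sources).
Time-form selection uses 50 replicates of 100 dated studies with a
ln(t+1) trend of slope 0.5 against noise sd 0.3 (the Gaussian family keeps
the comparison fast; a beta-family end-to-end run through the generator is
checked once alongside).  Contrast power uses a 1.0-logit
agroforest-vs-perennial-crop gap at 200 studies.  These sizes are an
explicit scaling-down of the real compilation (182 studies, but thousands
of species) chosen to make each property measurable in seconds to minutes.

## Numerical choices and limitations

- Quadrature order 15 (configurable); Laplace for nested structures only.
- Convergence: BFGS gradient tolerance 1e-8, simplex polish tolerances
  1e-9/1e-11; multi-start perturbation sd 0.3 on all parameters.
- φ is plateau-capped at 1e8: degenerate zero-variance data drive the beta
  dispersion to infinity, and a plateau lets β still be optimized exactly.
- Weighted marginal likelihood is a quasi-likelihood: with weights that do
  not reflect true precision differences its standard errors are
  model-based, not robust.  ML (not REML) throughout, so variance
  components carry the usual downward finite-sample bias.
- The model battery records failed fits (rank deficiency, no usable rows)
  and continues; failures land in `fit_failures.txt`.
- Exact replication of lme4/glmmTMB output is a non-goal; agreement is
  checked against closed forms and dense-integration oracles instead.
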
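# Methods

## Model

The package fits exponential-family mixed models with random intercepts:
conditional on random effects `u`, the outcome has density
`f(y_ij | eta_ij, phi)` with canonical link `g(mu) = eta = X beta + Z u +
offset`.  Supported families are Poisson (log link), Bernoulli (logit) and
gaussian (identity); for Poisson and Bernoulli the dispersion is fixed at
`phi = 1`, for gaussian it is estimated.  Random effects are independent
across grouping factors with `u_k ~ N(0, sigma_k^2 I)`; the package targets
two factors (patient and facility, possibly crossed) but handles any
number.  Survival-type outcomes are encoded for the Poisson family as a
string of per-encounter zeros possibly terminated by a single one, with
log encounter duration as the offset — the piecewise-exponential link
between Poisson regression and survival analysis.

## Estimation

All estimators are built from the hierarchical log-likelihood
`h = log f(y|beta,u,phi) + log f(u|gamma)` and its Laplace-approximate
adjusted profiles `p_w(h) = h(w_hat) - 1/2 log|-H(h,w)/2pi|`, where `w` is
the eliminated block and `w_hat` solves `dh/dw = 0`.

* HL(1,1): variance components maximize `p_{beta,u}(h)` (REML); fixed
  effects then maximize `p_u(h)` at the REML variance components; random
  effects are taken from the stage-2 inner mode rather than a third
  conditional optimization (`refit_random_effects` exposes the third
  optimization for comparison; in practice the two modes agree closely).
* HL(0,1): stage 1 only, with `beta, u` read from the final joint inner
  mode.  This is mathematically the estimator computed by glmmTMB's REML
  option, and the two were verified to agree to four decimals on shared
  datasets during development.
* ML: joint maximization of `p_u(h)` over `(beta, log sigma)`, the
  single-node adaptive Gauss–Hermite (Laplace) maximum-likelihood fit.

For gaussian models the Laplace approximation is exact, so HL(1,1)
reproduces closed-form REML and ML reproduces closed-form ML; the test
suite enforces agreement to 1e-6 relative against a dense-marginal oracle.

### Inner problem

The inner mode is found by full Newton steps with step-halving (at most 30
halvings, accepting the first step that does not decrease `h`), starting
from zero or a warm start, to a score sup-norm of 1e-8 within 100
iterations.  Non-convergence is flagged, never silent.  The negative
Hessian `A' W A + blockdiag(0, G^{-1})` is positive definite away from
degenerate data; a non-PD factorization aborts the solve with a diagnostic
(the usual cause is quasi-separation of a sparse dummy covariate, whose
coefficient has no finite maximizer).

For random intercepts, each factor's own block of `Z'WZ` is diagonal, so
the solver eliminates the largest factor's block exactly and
Cholesky-factors the small dense Schur complement over the fixed effects
and remaining factors (at most a few hundred columns).  This is an exact
factorization of the same matrix, ordered to exploit structure; when the
remainder would exceed 600 columns the solver falls back to SuperLU in
symmetric mode with a fill-reducing permutation, whose positive U-diagonal
doubles as the positive-definiteness certificate.  The sparsity pattern is
derived from the grouping structure, never detected numerically.

### Outer problem

Variance-component SDs (and the gaussian dispersion) are optimized on the
log scale by L-BFGS-B with a lower bound `sigma >= 1e-4`; estimates at the
bound are reported with a boundary flag and their standard errors marked
unreliable.  Outer gradients are central finite differences (step 3e-5 on
the log scale) over warm-started inner solves; convergence uses a relative
objective tolerance of 1e-12 and projected gradient 2e-6.  Stage 2 uses
the same machinery over `beta`, except for gaussian models, where the
log-determinant adjustment does not depend on `beta` and the exact
profiled GLS score is used as the outer gradient with a
machine-precision objective tolerance.  These tolerances were chosen so
that the gaussian route agrees with the closed-form REML oracle to better
than 1e-6 relative.

Standard errors come from central-difference numerical Hessians of the
relevant adjusted profile at its optimum: stage 1 for the variance
components (delta method maps log-scale SEs to the SD scale), stage 2 for
the fixed effects; HL(0,1) reads the fixed-effect block of the inverse
joint curvature instead.  ML uses the numerical Hessian of the joint
objective.  A numerical Hessian that is not negative definite yields NaN
standard errors and a diagnostic, not an exception.

## Verification oracles

`hlik.quadrature` provides three independent evaluations of the marginal
likelihood used only for testing and benchmarking: per-group adaptive
Gauss–Hermite quadrature for single-factor models (order 1 reproduces the
Laplace value exactly, order 25 serves as ground truth in tests); the
exact dense gaussian marginal with ML/REML criteria (capped at N = 2000);
and a tensor-product Gauss–Hermite grid over all random effects jointly
for crossed toys with q <= 4.  Derivatives in the core are analytic and
are checked against finite-difference oracles in the suite.

## Synthetic data

The scenario generators emulate the structure of EHR repeated-measures
data: each patient receives `2 + Poisson(3)` encounters (median ≈ 5); a
configurable fraction of patients (exactly `ceil(fraction * n)` of them)
visits 2–4 distinct facilities while the rest are fully nested; outcomes
are sparse Poisson counts (intercept −3.0, realized events/observation
≈ 0.07, under the 0.10 ceiling) or sparse Bernoulli outcomes
(intercept-only fixed part; events/observation < 0.015; a "more variable"
configuration raises the patient SD from 0.3 to 2.0 with intercept −6.5).
Default random-intercept SDs are 0.3 (patient) and 0.4 (facility).  The
smooth covariate effect is generated from a natural cubic spline with
fixed knots on [−2, 2] and fixed coefficients, and the paired model
configuration fits with the same knots, so every fixed-effect coefficient
has an exact ground truth for bias and MSE computation.  Replicate `r`
uses seed `base_seed + r`; all generators are bit-reproducible.

A clinical-style generator produces encounter tables with potassium,
eGFR, age, Charlson score, race, gender, inpatient status and encounter
durations; death is drawn from a piecewise-exponential model whose
log-hazard is U-shaped in potassium with minimum risk at 4.0 meq/l, and a
death truncates the patient's encounter sequence.  The default baseline
hazard gives roughly 3% encounter mortality, large enough that all six
race levels see events at moderate sample sizes (at very small sizes the
rarest level is quasi-separated and the p = 18 clinical model is rightly
unidentifiable).  The generator reproduces structure, not the marginal
covariate distributions of any real EHR database.

What passing tests show — and do not show: recovery and agreement results
are statements about these generating processes (canonical links, correct
model specification, gaussian random effects, missing-free data), not
about any real clinical dataset.

## Natural splines

Non-linear covariate effects use natural cubic regression splines in the
textbook truncated-power form, with the cubic columns rescaled by the
squared boundary span for conditioning on wide covariate scales (age,
eGFR); the rescaling changes coordinates, not the spanned space.  Knots
default to boundary knots at the 1st/99th percentiles with interior knots
at equally spaced quantiles; fixed knot sets can be supplied for exact
reproducibility.  The test suite checks the natural constraints (zero
curvature at and beyond the boundary, linear tails) and span-equivalence
with an independent B-spline-plus-constraint construction.  Relative-risk
curves exponentiate `[B(v) - B(ref)] . beta_spline` with delta-method
pointwise 95% bands from the spline block of the coefficient covariance.

## Evaluation metrics

Absolute standardized bias is `100 |mean(est) - truth| / SD(est)` over
replicates (the empirical-SE convention of the simulation-study
literature; the alternative denominators — truth, or model SE — give very
different magnitudes and are not used).  MSE is the plain mean squared
deviation.  Method agreement on random effects is summarized numerically
in Bland–Altman style (correlation, mean difference, 1.96-SD limits).
Replicates on which a fit aborts (quasi-degenerate data; about 1–2% of the
sparsest binary scenario at 100 patients) are dropped from all methods
jointly and counted.

## Problem sizes and known limitations

The study-level checks use 1000 patients in 50 facilities (about 5000
rows, 1050 random effects) with 50 shared replicates for method
comparison and 200 replicates for recovery, and 200/60 replicates for the
sparse-binary comparisons at 100/1000 patients; these sizes give
standardized-bias Monte-Carlo noise of a few percentage points while
keeping a full run in minutes on one CPU.

Two properties of the Laplace objectives at these sparse conditions are
worth knowing.  First, with ~5 sparse encounters per patient the REML
profile underestimates the patient-level SD (mean ≈ 0.24 against a truth
of 0.3 over 200 replicates, with boundary collapses in roughly a fifth of
them) — per-cluster information, not the number of clusters, controls
this bias.  Second, the HL(0,1) joint-mode shortcut shifts the intercept
upward; the shift is small in absolute terms (~0.1) but large relative to
the replicate SD, and it does not shrink as patients are added at fixed
cluster size.  Both behaviours are reproduced exactly by glmmTMB on the
same data and are reported honestly by the acceptance checks rather than
tuned away.  Higher-order Laplace corrections, random slopes, non-normal
random effects and dispersion modelling are out of scope.
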
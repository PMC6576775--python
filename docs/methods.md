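# Methods

## The model

The package fits a three-scale occupancy model to pooled camera-trap
detection histories. Latent occupancy z ~ Bernoulli(Ψ) is drawn per site;
conditional on z = 1, latent availability a_t ~ Bernoulli(θ) is drawn per
daily occasion; conditional on z·a_t = 1, each pooling method s records the
species with probability p_s, conditionally independently across methods.
Detections are impossible when the site is unoccupied or the species
unavailable, and the model admits no false positives. Marginalizing the
latent states gives the site likelihood

    L_i = Ψ_i ∏_t [ θ_i ∏_s p_is^y (1−p_is)^(1−y) + (1−θ_i)·1{no detection at t} ]
          + (1−Ψ_i)·1{no detection anywhere},

where occasions with at least one detection pin a_t = 1 (their
"false absences" at other methods are informative), all-zero occasions sum
the unavailable and available-but-missed causes, and missing visits
contribute no factor. The total log-likelihood is the sum over sites;
it is invariant to site order and, with occasion-constant θ and p, to
occasion order within a site.

Assumptions worth stating plainly: sites are independent and closed over
the survey (the same z all season); θ is constant across occasions within a
site (occasion-varying availability is not implemented — the model family
here only places site-level covariates on θ); and methods are conditionally
independent given availability. Physically overlapping methods (a
three-camera method containing a two-camera method) violate that last
assumption at the camera level; the shared availability state absorbs the
common cause, and the remaining dependence is a documented approximation of
the model family, not something the likelihood corrects.

## Links, parameters, sharing

All three scales use the logit link. Linear predictors are built from a
covariate table with a site-level block (study area, access type, tree-loss
proportions at several buffer radii) and a (site, method)-level block
(mean/min/max distance from the access feature to the method's member
cameras). Categorical covariates are treatment-coded with fixed baselines
(Area: SL; Access: RD; method factor: the map's first method, m1).
Continuous covariates are standardized by z-scoring with the sample
(n−1) standard deviation; the scaler is returned so a transform fitted on
one data set can be reapplied to another (e.g. simulated data standardized
with field-data scalers). Constant columns are an error, not a silent skip,
when standardization is requested explicitly.

"One effect on Ψ and θ" is implemented as a single shared slope vector over
identical term lists with two free intercepts, preserving distinct baseline
rates while forcing a common covariate response. The convention is a
declared design choice: with k slope columns the shared model spends
k + 2 parameters against 2k + 2 for separate effects.

`fit_model` also accepts `theta_fixed`, pinning availability at a constant
with zero parameters; `theta_fixed=1.0` collapses the likelihood to the
single-season occupancy model, which doubles as an internal consistency
check and a cheap single-scale fitter.

## Numerical choices

- Likelihood evaluation is fully vectorized and accumulated in log space
  (`log_expit` for all probability logs, `logaddexp` for the two-cause
  occasion terms and the site-level mixture), so boundary parameter values
  produce −inf log-likelihoods rather than NaNs.
- Optimization: L-BFGS-B on the packed link-scale coefficient vector,
  objective tolerance 1e-10, gradient tolerance 1e-8, default 10 starts —
  the zero vector (all probabilities 0.5) plus uniform draws in [−2, 2]
  from a seeded generator. The best optimum is kept; a fit where no start
  converges is returned as an explicit failure with no estimates.
- Standard errors: inverse of a central-finite-difference observed
  information (statsmodels `approx_hess`). If the matrix is not positive
  definite the fit reports SEs as unavailable with a warning — never
  imaginary numbers.
- Boundary flagging: any fitted |linear predictor| > 6 (probability within
  ~0.0025 of 0 or 1) raises a boundary warning. The cutoff is set where the
  optimizer actually stalls on degenerate data (all-zero or saturated
  histories stop near |logit| ≈ 7–8 under the stated objective tolerance);
  a 10-cutoff would miss true boundary optima.
- Delta-method SEs for probability-scale predictions: se(q) =
  q(1−q)·sqrt(xᵀVx) with the gradient scattered through the shared-parameter
  packing.
- AICc uses n = number of sites (the independent sampling unit), errors
  when n ≤ K + 1, and exact ranking ties are broken by fewer parameters,
  then lexical model id — logged, never silent.

## Pooling rules

A method's pooled occasion value is 1 if any member camera detected, and
MISSING only when **all** member cameras are missing; a single active camera
makes the occasion an informative 0. This maximizes data use and is the
natural reading of "detection at any one or more camera"; the partial-missing
case is a declared convention, since pooled-input software conventions vary.
Pooling is a deterministic function of the detection array and the method
map, so nested methods are monotone (a subset method's detection implies the
superset's) and a single-camera method returns that camera's history
verbatim. Occasion binning from raw timestamps is out of scope: input is
already daily (any other bin width is accepted as pre-binned input).

## The synthetic-data generator

Defaults emulate the target study conditions: 32 sites × 5 cameras in the
T-configuration (three cameras in line 100 m apart, two perpendicular at
150 m), per-site occasion counts drawn uniformly on 16–23 days, and the
five-method map m1={A}, m2={B,C}, m3={A,B,C}, m4={D,E}, m5={B,D,E}.
Missing visits are injected per camera-day (snow, battery) or per whole
camera (total failure), after which original values are unrecoverable.
Covariates are generated internally consistently: area frequencies 12/32,
12/32, 8/32; access split evenly between road and snowmobile sites (no
field split is published, so an uninformative half/half is used);
per-camera distance to the access feature uniform on 10–320 m, with
per-method DistMin/DistAve/DistMax computed from the member cameras so
their ordering holds by construction; tree-loss proportions Beta(2, 8)
(mean 0.2, right-skewed — managed-forest-like) at every buffer scale.
Covariate effects enter on the logit scale, consistent with the fitter.

The method-level generator matches the fitted model exactly (conditional
independence across methods) and is the right input for parameter-recovery
and selection-behaviour studies. The camera-level generator is the
physically realistic one: cameras detect independently with probabilities
q_c given availability, pooling induces p_s = 1 − ∏(1−q_c) and positive
dependence between methods sharing cameras. What the generator does *not*
emulate: animal movement and home-range geometry, lure saturation (θ is
design-independent here, though attractant density plausibly raises it),
seasonal or behavioural trends in availability, and spatial correlation
between sites. Passing recovery tests therefore demonstrate estimator
correctness under the model's own assumptions — not robustness to the ways
real surveys violate them.

## Staged selection workflow

Stage 1 compares constant detection against the method factor. Stage 2 adds
each candidate detection covariate to the stage-1 winner, collects the
covariates appearing in any model within 2 ΔAICc of the top, fits their
additive combinations (capped at 3 covariates beyond the method factor to
bound the search), and retains the single top-ranked detection structure.
Stage 3 first compares tree-loss buffer scales in otherwise identical
models and keeps the AICc-best buffer (exact ties keep the smaller buffer,
logged), then places each occupancy-level covariate on Ψ only, on Ψ and θ
shared, and on both separately, and ranks the candidate set. Detection
estimates are model-averaged over the final ranking on the probability
scale (link-scale averaging is available as an option) with unconditional
standard errors Σwᵢ·sqrt(SEᵢ² + (q̂ᵢ − q̄)²). When several models sit within
2 ΔAICc of the top detection structure, rank 1 is retained — a declared
convention. A stage with zero converged candidates aborts with the partial
result preserved.

## Problem sizes used in the test suite and acceptance script

Likelihood-equivalence checks enumerate latent states exactly for histories
up to 6 occasions (1000 randomized instances, tolerance 1e-10). Parameter
recovery is demonstrated at 2000 sites × 20 occasions, where Monte-Carlo
error puts every estimate within ±0.03 of truth; selection behaviour at 200
sites × 50 replicates, where a realistic method effect yields ΔAICc > 2 in
effectively every replicate. Acceptance fits use 3 multi-starts (the
likelihood at these sizes is, in practice, unimodal; the multi-start
default of 10 remains for small, boundary-prone data sets).

## Known limitations

- No overdispersion (c-hat / QAICc) machinery and no spatial-autocorrelation
  diagnostics; site independence is taken as given by design.
- θ cannot vary by occasion, and detection covariates cannot vary by
  occasion (no weather-type covariates).
- No Bayesian/MCMC fitting, random effects, or abundance-model variants.
- Model-averaged probability-scale estimates near 0 or 1 inherit the usual
  delta-method SE distortions; link-scale averaging mitigates but does not
  remove this.
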
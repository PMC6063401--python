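# Methods

`multicause` implements a factorial family of binary-choice observer models
for visuo-vestibular heading perception, the numerical machinery to compute
their trial-level likelihoods, and a fully Bayesian model-comparison stack.
This note records the model definitions, the numerical choices, and the
design decisions taken where more than one reasonable construction exists.

## Observer models

On each bisensory trial a visual heading `s_vis` (reliability level
`c_vis ∈ {high, med, low}`) and a vestibular heading `s_vest` (degrees,
rightward positive) produce noisy internal measurements `x_vis`, `x_vest`
with conditionally independent Gaussian densities centered on the true
headings.  The observer entertains two causal scenarios — a single common
heading (C = 1) or two distinct headings (C = 2) — and is Bayesian within
each scenario; the *strategy* factor controls how the scenarios are
combined:

* **Bay** — computes `Pr(C = 1 | x_vis, x_vest, c_vis)` with prior
  probability of a common cause `p_c`; the explicit (unity-judgment) rule
  thresholds this posterior at 1/2, the implicit (inertial-discrimination)
  rule model-averages the scenario posteriors over heading sign.
* **BayPM** — probability matching: the scenario is chosen randomly with
  probability equal to its posterior.  The Bernoulli draw is marginalized
  analytically inside the response probability, never simulated.
* **Fix** — a fixed criterion: the common-cause branch is used whenever
  `|x_vis − x_vest| < κ_c`, ignoring reliability.
* **SFu** (explicit only) — stochastic fusion: reports 'unity' with
  probability `η(c_vis)` regardless of the measurements; its only
  parameters are `η_high, η_med, η_low` and it carries no lapse.
* **FFu** (implicit only) — forced fusion, `C ≡ 1`; algebraically identical
  to Bay with `p_c = 1` (verified to 1e-10 in the tests).

The *noise* factor is constant (`C`, `σ(s) = σ0`) or eccentricity-dependent
(`X`), with `σ(s) = σ0 √(1 + w² s²)` (`s` in degrees).  This form is
quadratic near straight ahead and is used identically on the generative and
the observer side.  Base SDs: one `σ0_vest` plus one `σ0_vis` per
reliability level; one shared `w_vis` across reliabilities.

The *prior* factor is independent (`I`): a common central Gaussian
`N(0, σ_prior²)` for each heading, factorized under C = 2 — or empirical
(`E`): a discrete prior on the experimental design grid.  For C = 1 the
empirical support is the 11 mean headings {−25°, …, 25°} with weights
∝ `N(s | 0, σ_prior²)`; for C = 2 it is the 88 pairs (11 means × 8 nonzero
signed disparities) with weights ∝ `N(s̄ | 0, σ_prior²) · N(Δ | 0,
Δ_prior²)`, renormalized.  Zero disparity is excluded from the C = 2
support because the design's 'different' trials always have nonzero
disparity.  All models include a lapse rate λ (uniform random response)
except stochastic fusion.

Unisensory left/right discrimination: with a symmetric prior and symmetric
noise the posterior rule `Pr(s > 0 | x) > 1/2` reduces exactly to the sign
of the measurement, so the response probability has a closed form (the
truncated-normal mass right of zero) and the prior is irrelevant.

Ties (any decision statistic exactly at its threshold, and discrete prior
mass at `s_vest = 0` when computing rightward probability) contribute
probability 1/2 to each option; these are measure-zero events under
continuous noise and the convention avoids direction bias.

## Measurement domain and integration

Measurements live on [−90°, 90°] and all densities are renormalized
(truncated) on that interval, on both the generative and the observer side;
a wrapped-normal density is available at the density level and is
numerically indistinguishable from the plain normal at the noise levels of
this design (tested to 1e-10).  Stimulus headings stay within ±45°.

Trial response probabilities marginalize the measurement-conditional
decision rules over the unseen measurements.  The integrals use a single
global equispaced grid (default 401 nodes per dimension) so that the
decision statistics — which depend on the parameters but not on the trial's
stimuli — are computed once per (parameter vector, reliability, task) as
matrix products over the prior support, and reused across all trials.  A
plain trapezoid rule would be first-order inaccurate because the decision
rules are step functions of the measurements; the integrator therefore:

1. decomposes each decision field into smooth parts plus indicator
   components `A(x) · [T(x) > 0]` with smooth statistics `T` (for the fixed
   criterion, the band indicator itself is one such component);
2. finds every grid cell whose corners straddle `T = 0` and replaces the
   trapezoid's bilinear smear there with an exact integral of the
   bilinear-contour indicator against the separable Gaussian density
   (Gauss–Legendre of order 8 along the visual axis, analytic Gaussian mass
   along the vestibular axis);
3. re-integrates cells crossed by *several* boundaries (e.g. the
   fixed-criterion band edge meeting a posterior boundary) by 12×12
   subdivision of the cell with bilinearly interpolated statistics.

This makes the quadrature error second order in the grid spacing: doubling
the default resolution changes probed response probabilities by less than
1e-4, and a forward-sampling Monte Carlo oracle at 10⁶ draws agrees within
3 standard errors across the factorial space (both are test-enforced).
Per-trial probabilities are clamped at 1e-10 before logging (λ may be 0
during optimization) and the number of clamped trials is reported.
The continuous (independent) prior uses its own equispaced heading grid
(default 201 nodes); the choice-posterior computed on it matches a 10×
finer grid to 1e-4.

## Fitting

Parameters are mapped to a unit cube — linearly for bounded parameters,
logarithmically for scale parameters (`σ0`, `κ_c`, `σ_prior`, `Δ_prior`,
with bounds [0.5°, 80°], [0.25°, 180°], [1°, 120°], [1°, 120°]; weights,
probabilities and λ on [0, 1]).  The sampling prior is uniform in these
transformed coordinates (log-uniform for the scale parameters), so
posterior evaluations need no Jacobian terms and the marginal likelihood is
reparameterization-invariant.

*Maximum likelihood*: seeded Latin-hypercube multistart with a
bound-constrained Powell search in the cube.  The contract is multistart
dominance — the returned optimum must match or beat every evaluated start
(and, in tests, the generating parameters) — not a particular optimizer.

*Posterior sampling*: an affine-invariant ensemble sampler (emcee) with
2(k + 1) walkers, burn-in defaulting to half the run, split-R̂ and bulk-ESS
diagnostics (warning threshold R̂ > 1.1, never a silent failure), and the
per-draw per-trial log-likelihood matrix stored for PSIS-LOO and the
marginal-likelihood estimator.  One master seed fans out to all streams.

## Model comparison

* **AICc / BIC** from the ML solution (closed forms).
* **PSIS-LOO**: per-trial importance ratios smoothed by Pareto-smoothed
  importance sampling (arviz), self-normalized per trial; Pareto shape
  `k_i > 0.7` flags a trial, `k_i > 1` raises an error-level warning.  With
  a single draw the score degenerates to the plug-in log-likelihood sum.
* **Log marginal likelihood** by the weighted harmonic mean estimator with
  a finite-support weight density: a variational Gaussian mixture fitted to
  the posterior draws, each component replaced by a uniform ellipsoid, the
  common Mahalanobis radius chosen to minimize the empirical variance of
  the estimator's summands; degenerate mixture fits fall back to a single
  ellipsoid with a warning.  Accurate to 0.1 nats on conjugate toys
  (test-enforced).
* **Hierarchical group model selection**: variational Dirichlet posterior
  over model frequencies; exceedance probabilities by Monte Carlo over the
  Dirichlet posterior (seeded, ties broken by draw order); Bayesian omnibus
  risk as the posterior probability of the equal-frequency null computed
  from the variational free energy against the exact null evidence, with
  the null mixing models by the normalized prior weights.  Protected
  exceedance `φ̃_i = (1 − BOR) φ_i + BOR/K`.
* **Factor level**: posterior concentrations agglomerate by summation over
  factor components.  Prior weights are balanced so each component of each
  factor carries equal prior mass (iterative proportional fitting; for the
  seven-model explicit space this yields the 1×/2×/4× multipliers for
  Bay/Fix/SFu), and the prior scale defaults to (mean components per
  factor)/(number of models) so agglomerated concentrations are of order 1.
  The factor-level omnibus risk applies the same free-energy comparison to
  the component-aggregated evidence — the most direct extension, adopted as
  a package decision.
* **Compatibility probability**: per subject and parameter, the likelihood
  that one shared value (H0) versus task-specific values (H1) generated the
  task posteriors, using Gaussian KDEs of model-averaged draws against a
  truncated Cauchy prior fitted to the pooled average posterior (median /
  half-IQR matching, truncated to the draw range); `C_p` is the protected
  exceedance of H0 across subjects.
* **Absolute goodness of fit**: `g = 1 − (Ĥ_G + LOO)/(Ĥ_G − N log 2)`,
  with `Ĥ_G` the alternating-digamma (Grassberger) entropy estimate of the
  response counts grouped into repeated identical conditions (by default
  the full stimulus condition; the grouping is configurable).  `g = 0` at
  chance and `g = 1` when the model captures all estimated intrinsic
  entropy.  The estimator needs several repeats per group: with
  near-singleton groups it overestimates the intrinsic entropy and `g` can
  exceed 1 (the result is flagged high-variance), so coarser behavioral
  cells such as disparity × reliability are preferable at this design's
  trial counts.

## Synthetic experiments

The generator reproduces the study design: mean heading uniform on the 11
values {−25°, …, 25°}; disparity magnitude uniform on {0°, 5°, 10°, 20°,
40°} (so zero disparity on exactly 1/5 of trials in expectation), nonzero
disparities signed at random; reliability uniform over three levels;
`s_vis = s̄ − Δ/2`, `s_vest = s̄ + Δ/2`, giving 297 unique bisensory
conditions.  Trials are drawn i.i.d. with target totals rather than
scheduled to per-condition minimum repeats.  Default per-task counts sit
mid-range of the study's totals (500 unisensory, 900 unity judgments, 2500
inertial discriminations); unisensory trials split evenly across the four
stimulus streams.  Default generating parameters are the group posterior
means reported for this paradigm (e.g. `σ0_vest = 6.49°`, `p_c = 0.56`);
stochastic-fusion η defaults are reliability-graded round values.  Visual
coherence percentages (subject-specific staircases in the real experiment)
are abstracted into the three `σ0_vis` parameters.

Model-free summaries follow the study's analysis: unity proportions by
signed disparity and reliability; vestibular bias = −PSE from ML
cumulative-Gaussian psychometric fits of rightward-response proportions
against `s_vest`, within the 11 published `s_vis` bins, with the lapse
fixed (default 0) and non-converged bins flagged.  The psychometric curve
is a descriptive statistic: the true curves are not exact cumulative
Gaussians under causal inference or eccentric noise.

What the simulator does *not* emulate: motion-platform kinematics, session
structure and breaks, coherence staircases, sequential effects, and any
departure of real observers from the model family.  Passing recovery tests
therefore demonstrate internal consistency of the pipeline — that the
fitting and comparison machinery recovers known generators at realistic
trial counts — not that real subjects obey these models.

## Problem sizes used in the test suite

The default suite keeps runtimes practical by scaling problem sizes, as
package choices: quadrature/Monte-Carlo agreement is checked at 10⁶ draws
on a 3-condition probe for every factorial cell plus a 20-condition probe
for the eccentric/empirical Bayesian cells; parameter recovery fits the
explicit + unisensory tasks at the study's per-task trial counts (900 +
500) with a 3-start ML fit and a 1500-draw posterior; the lapse-coverage
experiment uses the unisensory model (closed-form likelihood) with 5
replicates at N = 3000; model recovery runs 2 replicates per generator.
Fits in the tests use a 101-node measurement grid, whose log-likelihood
differs from the converged value by ≲ 0.2 nats on ~4000-trial datasets —
far below the evidence differences the tests assert on.

## Known limitations

* The exact supplementary-material forms of the eccentricity law, the
  empirical-prior approximation and the adaptive integration grid of the
  original study were not available; the forms above are documented
  stand-ins with test-enforced convergence and oracle agreement.
* The marginal-likelihood estimator inherits the usual sensitivity of
  harmonic-mean estimators to the weight density; the variance-minimizing
  radius and conjugate-toy checks bound but do not eliminate this.
* Model-averaged compatibility analysis assumes KDE-representable marginal
  posteriors; heavily multimodal posteriors would need more draws.
* No hierarchical (shared-across-subject) parameter priors and no
  continuous-report (estimation) responses.
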
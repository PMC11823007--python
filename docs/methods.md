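# Methods

`trrkit` studies a question that recurs across cognitive neuroscience:
how reliably does a trial-level condition contrast — here the Stroop
effect, the difference between incongruent and congruent trials —
distinguish one person from another across widely separated testing
repetitions?  The package implements two methodological answers jointly:
a multivariate spatial model that reduces each trial's vertex pattern to
a scalar with a noise-aware linear projection, and a hierarchical
Bayesian location-scale model that estimates test–retest reliability
(TRR) while separating trial-level from individual-level variance.  A
synthetic-data generator with fully recorded ground truth makes every
claim testable.

## The generative model behind the synthetic data

One "region" is a set of V vertices.  For participant p, repetition
r ∈ {test, retest}, session, run, condition c ∈ {incon, congr} and
trial t, the latent trial amplitude is

    alpha = (m_mean[r] + mu_mean[p,r]) ± (m_stroop[r] + mu_stroop[p,r]) / 2

with + for incongruent trials, so that `m_stroop + mu_stroop` is exactly
the incongruent-minus-congruent difference.  Per-participant effects
(mu_mean, mu_stroop) are drawn from bivariate normals across repetitions
with SDs `sd_individual_mean`, `sd_individual_stroop` and correlations
`rho_mean`, `rho_stroop`; **`rho_stroop` is the true TRR**.  Trial noise
is Student-t (or Gaussian at `t_df = inf`) with scale
`exp(gamma + tau[p,r])`, `gamma = log(trial_noise_sd)`; `tau` is a
per-participant log-scale effect with SD `sd_scale_random`.  The
location/scale random effects are uncorrelated by default (`rho_scale`
and the location–scale cross-correlation are not pinned by any reported
analysis; 0 is the neutral choice and is configurable).

Spatially, a trial's pattern is `alpha * topography + noise`.  The
unit-norm topography carries `signal_uniform_fraction` of its squared
norm on the uniform direction u = 1/sqrt(V); trial noise has covariance

    s^2 [ f_u u u' + (1 - f_u)/(V-1) Q Q' ],      s = exp(gamma + tau)

with f_u = `noise_uniform_fraction` and Q an orthonormal basis of u's
complement.  This "dominant-uniform" noise geometry, with signal partly
off-uniform, is the regime in which a multivariate decoder can
out-perform the spatial mean: most trial-level variability lies along u,
where the uniform projection is maximally exposed.

Default study conditions mirror the design the analyses assume:
27 participants × 2 repetitions × 3 sessions × 2 runs, ~108 trials/run
in two conditions over 8 words × 8 colors, V ≈ 50–100 vertices, percent
signal change units.  The default effect scale (population Stroop 0.05,
individual SD 0.025, trial noise scale 0.15 → trial/subject variability
ratio 6) sits in the range the hierarchical analyses report for real
parcels (ratios roughly 5–15).  Word/color labels are assigned
round-robin so every word (and, for congruent trials, every color) cell
is near-balanced, guaranteeing the undersampling count k ≥ 1.

What the generator deliberately does **not** emulate: hemodynamic
convolution, spatial smoothing, autocorrelated physiological noise,
session-specific signal topographies, learning/habituation trends, and
behavioral responses.  Passing tests therefore demonstrate correctness
of the estimators under the generative assumptions, not robustness to
every property of real recordings.

## Trial estimation (timeseries path)

The optional TR-resolution path injects each trial's pattern additively
into TRs onset+4..onset+6 (onset TR = index 0) and recovers it by
*selective averaging*: the mean of those same three TRs after
detrending.  Detrending regresses, per vertex, per-run Legendre
polynomials of order `1 + floor(D/150)` (D = run duration in seconds;
720 s → order 5) plus six motion regressors concatenated in time across
the two runs of a session.  Orthogonal polynomials are used purely for
numerical stability — residuals are invariant to the basis.  Trials
whose averaged window contains a framewise displacement strictly above
0.9 mm are censored; a frame at exactly 0.9 mm is retained.  Onset gaps
of 1–3 TRs make neighboring windows overlap; the resulting leakage is a
documented property of the estimator (tested against an explicit
superposition oracle), not an error.

## Spatial models

Both projections consume identical mean-pattern ("cocktail") centered
data — per vertex and run, half the sum of the two condition means is
subtracted — so univariate and multivariate scores differ only through
the weights.  Univariate weights are 1/V (the spatial mean).
Multivariate weights come from linear discriminant analysis: the average
of the two within-condition covariance matrices (unbiased, equal-weight)
is shrunk by multiplying off-diagonals by 0.75, inverted against the
condition mean difference, and normalized to unit length with the sign
fixed so incongruent projects higher.  Decoders are fit
leave-one-session-out (training on the other two sessions, both
repetitions' runs) on 100 stratified undersampled training sets; the 100
weight vectors are averaged element-wise and renormalized.  Averaging
weights (rather than decision values or accuracies) is our choice where
the combination rule was open: linear decoders compose linearly and the
result remains a single interpretable projection.

Undersampling strata are (condition × word) cells within each run, with
k = the minimum cell count in that run.  An 8-cell per-word
stratification reproduces the k magnitudes reported for real sessions
(k ≈ 4–6), keeps congruent color balance exact (word = color there), and
never demands the impossible 56-way word×color balance that a literal
pair stratification would; incongruent color balance follows
approximately from the generator's round-robin assignment.

## Reliability models

**Summary statistic.**  The Stroop contrast per (participant,
repetition) is the difference of condition means over uncensored
baseline-session trials.  ICC(3,1) in its consistency form equals the
Pearson correlation of those contrasts across participants and is
computed exactly that way; the variance-decomposition reading
(cross-repetition covariance ξ² and residual σ²) is reported alongside.
With trial noise of scale ν and T trials per condition, the expected ICC
is attenuated by the factor σ²/(σ² + ν²(1/T_i + 1/T_c)) — the analytic
oracle used in tests.

**Hierarchical Bayesian.**  Trial scores follow a Student-t with
per-cell location and log-scale, each decomposed into population fixed
effects and participant random effects.  Four covariance structures are
implemented:

| structure | coding   | random effects |
|-----------|----------|----------------|
| `full`    | flat     | one 8-dim MVN over (mu, tau) |
| `ils`     | flat     | independent 4-dim MVNs for mu and tau |
| `ils_sym` | contrast | independent 2-dim MVNs per mean/stroop component |
| `homog`   | contrast | location only; a single residual scale gamma |

Under flat coding the TRR is extracted per draw by the repetition
contrast W (+1 incongruent, −1 congruent per repetition) applied to the
location covariance; under contrast coding it is the sampled correlation
of the location-stroop block directly.  In `ils_sym` the scale random
effects mirror the location coding (mean/stroop components per
repetition) — implied rather than stated by the source formulation, and
adopted here.

Priors are explicit, weakly informative equivalents of common package
defaults: location fixed effects ~ normal(0, 10·SD(y)); log-scale fixed
effects ~ normal(log SD(y), 10) (the log scale is unitless, so a
data-SD-scaled width would be dimensionally wrong); random-effect SDs ~
half-Student-t(3, 0, 2.5·SD(y)) for location and half-Student-t(3, 0,
2.5) for log-scale effects; correlations ~ LKJ(1); t degrees of freedom
~ Gamma(2, 0.1) bounded below by 1 (one df shared per model).

**Sampling.**  Posterior draws come from the package's own No-U-Turn
sampler with hand-coded analytic gradients, verified against finite
differences and a brute-force density oracle in the test suite.
Correlation matrices are parameterized through canonical partial
correlations (tanh of unconstrained values building a Cholesky factor
row by row); random effects are non-centered (effects = diag(sd)·L·z,
z ~ N(0,1)) to remove funnel geometry at small group SDs; SDs and the
df use log transforms.  Warmup adapts the step size by dual averaging
(target acceptance 0.8, the averaging restarted whenever the metric
changes) and a diagonal mass matrix in expanding windows.  Numerically
unsafe points (|log scale| > 40, non-finite coordinates) evaluate to
−inf with a zero gradient and are treated as divergences.  Defaults are
4 chains × 2000 iterations (1000 warmup); the reduced profile used in
simulation studies is 2 × 600 (300 warmup) with tree depth capped at 6.
Split R-hat and bulk ESS (via arviz) are attached to every fit; a
convergence warning is raised when max R-hat > 1.01, min ESS < 100, or
more than 10% of post-warmup transitions diverge.

**Summaries.**  The MAP of the TRR posterior is the mode of a Gaussian
KDE computed on the artanh (Fisher-z) scale and transformed back with
tanh — boundary-safe near ±1.  (Weighting the z-density by the
change-of-variables Jacobian to target the rho-scale density was
evaluated and rejected: the cosh² factor outruns Gaussian KDE tails and
inflates modes toward ±1.)  The posterior mean averages artanh draws
before tanh; q05/q95 are empirical percentiles; precision is 1/ln(SD),
increasing toward 0⁻ as the posterior tightens.  t⁺ is the posterior
mean over posterior SD of the population Stroop effect averaged over
repetitions per draw — reported as is, never converted to a p-value.
The trial/subject variability ratio divides the geometric mean of the
two repetitions' trial-level scales, exp(½Σ_r gamma[mean,r]), by an
aggregate of the location-stroop covariance block.  Two readings of
that aggregate are implemented: the literal matrix-log trace
exp(½Tr(log Σ)) = sqrt(det Σ), and a diagonal geometric mean of the two
repetition SDs, exp(½Σ_r ln SD_r).  They differ whenever the block is
correlated — and even at zero correlation the literal form is a product
of SDs where the diagonal form is their geometric mean; both are
exposed (`diagonal=` flag) and neither is asserted as the intended one.
Model comparison uses PSIS-LOO (arviz) on the stored per-draw pointwise
log likelihood, with pairwise elpd differences and Pareto-k flags.

## Noise geometry

Per participant and region, trials are centered within condition,
pooled, and the covariance eigendecomposed; dimension SDs are square
roots of eigenvalues.  Alignment of a weight vector to dimension d is
the squared cosine with eigenvector d (basis-complete: alignments sum to
1; sign-invariant).  Susceptibility is the alignment-weighted **sum** of
dimension SDs — deliberately not sqrt(w'Σw); the two agree only in the
single-spike limit, and the summed form is the contract.  The
susceptibility log-ratio ln(univ/multiv) is positive when the uniform
contrast is more exposed to trial-level variability.  Within-subject
spectra are ranked before any cross-subject averaging.

## Numerical and design choices

- Covariances use the unbiased (n−1) denominator; the pooled noise
  covariance removes one mean per condition (n−2 total).
- The undersampling k is computed per run (not per session).
- LDA on a singular shrunken covariance raises by default; a
  pseudo-inverse fallback is available by flag.
- Degenerate detrending regressors (constant or rank-duplicating
  columns) are dropped with a warning; all-zero columns silently.
- ICC with zero variance in either repetition returns NaN with an
  explicit `degenerate` flag rather than raising.
- Variance comparisons between univariate and multivariate scores
  standardize both weight vectors to unit norm first; raw Eq.-style
  1/V weights would make the comparison scale-confounded.
- Pipeline stages derive their seeds deterministically from the global
  seed plus the stage name; identical configurations yield byte-identical
  tables.

## Simulation scale

The bundled studies (test suite and `scripts/acceptance.py`) use the
following problem sizes, chosen as the package's demonstration scale:
parameter recovery at P = 30 participants, 80 trials/condition/
repetition, true TRR ∈ {0.3, 0.8}, trial/subject ratio 4, reduced MCMC
2 × 600, 10 replicates per truth value in tests (6 in the acceptance
script); the precision/variability grid at P = 16, ratios 1–8; decoding
advantage at V = 20–24 vertices with 90% uniform noise and 25% uniform
signal.  At P = 30 the realized sample correlation of 30 participants'
latent effects has an SD of ≈ 0.1–0.17 around the nominal TRR, so
recovery is assessed on replicate means (bias), not per-replicate error.

## Known limitations

- The NUTS implementation mixes more slowly than a mature PPL at
  near-zero trial noise (the likelihood then pins per-participant
  effects, where a centered parameterization would be preferable); the
  reduced profile reports ESS in the tens there.  Convergence warnings
  surface these cases.
- `full` and `ils` structures are fit with the generic (loop-based)
  correlation transform and are slower per gradient than `ils_sym`.
- The LKJ prior is implemented up to normalizing constants (fine for
  MCMC and model comparison on the same data, not for marginal
  likelihoods).
- Selective averaging is biased under window overlap by design; the
  bias is characterized by tests, not corrected.
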
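# trrkit

Test–retest reliability (TRR) of trial-level condition contrasts, for
researchers who ask whether a task contrast — canonically the Stroop
effect, mean(incongruent) − mean(congruent) — is a stable individual
trait across testing repetitions separated by weeks or months.  The
package implements, and lets you stress-test on synthetic data with
known ground truth, the joint use of:

- **multivariate spatial models** — a shrinkage linear discriminant
  (LDA) projection of each trial's multi-vertex activation pattern onto
  a scalar, fitted leave-one-session-out on stratified undersampled
  training sets, against the univariate baseline (the spatial mean,
  weights 1/V);
- **hierarchical Bayesian reliability models** — location-scale
  Student-t models of trial scores with participant random effects,
  in four covariance structures (Full, ILS, ILS-Sym, Homogeneous),
  sampled with a built-in No-U-Turn sampler with analytic gradients;
- the **summary-statistic baseline ICC(3,1)** (consistency form =
  Pearson correlation of per-person Stroop contrasts across
  repetitions), whose attenuation by trial noise the hierarchical model
  corrects;
- a **noise-geometry analysis** (PCA of trial-level variability,
  weight-vector alignments, susceptibility log-ratios) explaining *why*
  the multivariate contrast gains precision: most trial noise lies along
  the spatially uniform direction, to which the univariate contrast is
  bound.

## The model at the core

Trial scores are modelled as

    y[c, r, p, t] ~ StudentT(nu_df, alpha[c, r, p], exp(eta[c, r, p]))
    alpha = m[c, r] + mu[c, r, p]          (location: fixed + random)
    eta   = gamma[c, r] + tau[c, r, p]     (log scale: fixed + random)
    (mu, tau)[p] ~ MVN(0, Sigma)

with condition c, repetition r ∈ {test, retest}, participant p.  The
TRR is the correlation, inside Sigma, between the test and retest
Stroop-contrast components of mu — extracted by a repetition contrast
under flat coding, or directly as a sampled correlation under
mean/stroop contrast coding (ILS-Sym).  Expected attenuation of the
summary statistic follows

    E[ICC(3,1)] ≈ rho * sigma^2 / (sigma^2 + nu^2 (1/T_i + 1/T_c)),

sigma = individual Stroop SD, nu = trial noise SD, T_i/T_c = trials per
condition: the variance ratio nu/sigma governs both ICC attenuation and
the width of the hierarchical TRR posterior.  See `docs/methods.md` for
the full model, priors, sampler, and design choices.

## Worked example

Simulate one region (20 participants, 40 vertices, true TRR 0.7, trial
noise 5× the individual Stroop SD, 85% of noise variance on the uniform
spatial direction), decode, and estimate reliability both ways:

```python
from trrkit.bayes import MCMCSettings
from trrkit.pipeline import PipelineConfig, run_pipeline
from trrkit.synthetic import GeneratorConfig

cfg = PipelineConfig(
    generator=GeneratorConfig(
        n_participants=20, n_vertices=40, trials_per_condition_per_run=20,
        population_stroop=0.1, sd_individual_stroop=0.03, rho_stroop=0.7,
        trial_noise_sd=0.15, noise_uniform_fraction=0.85,
        signal_uniform_fraction=0.35,
    ),
    n_undersample_subsets=30,
    structures=("ils_sym",),
    mcmc=MCMCSettings(n_chains=2, n_iter=1500, n_warmup=750),
    output_dir="demo_out", seed=7,
)
bundle = run_pipeline(cfg)
print(open("demo_out/report.txt").read())
```

which prints (abridged):

```
generating TRR (rho_stroop): +0.700

summary-statistic reliability, ICC(3,1):
  univ    ICC = +0.316
  multiv  ICC = +0.802

hierarchical TRR (posterior summaries):
  univ    ils_sym  MAP = +0.379 mean = +0.552 90% CI = [-0.428, +0.959] SD = 0.435
  multiv  ils_sym  MAP = +0.778 mean = +0.778 90% CI = [+0.546, +0.891] SD = 0.107

attenuation check (univ/ils_sym): ICC +0.316 < hierarchical MAP +0.379 (truth +0.700)

noise geometry: median susceptibility log-ratio (univ vs multiv) = +1.868
(positive = uniform contrast more exposed to trial noise)
```

Reading the numbers: the univariate ICC is attenuated far below the
generating TRR of 0.7 because trial noise dominates the uniform
direction; the hierarchical model deattenuates it but with a wide
posterior.  The LDA contrast avoids the noisy uniform dimension
(positive susceptibility log-ratio), so its ICC sits near the truth and
its TRR posterior is much tighter — the Fig-1-style phenomenon the
framework exists to demonstrate.  The same pipeline is available from
the shell: `trrkit run-all --seed 7 --out demo_out`, plus stagewise
subcommands `simulate`, `decode`, `trr`, `geometry`, `recover`.

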
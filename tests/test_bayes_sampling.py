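"""Posterior sampling: determinism, conjugate limit, prior predictive,
TRR contrast algebra, and the derived summaries."""

import warnings

import numpy as np
import pytest

from trrkit.bayes import (
    HierarchicalModelSpec,
    MCMCSettings,
    PosteriorSamples,
    build_model,
    sample_posterior,
    summarize_trr,
    t_plus,
    trr_posterior,
    variability_ratio,
)
from trrkit.synthetic import GeneratorConfig, generate_trial_scores


def toy_scores(P=4, T=4, seed=3, **kw):
    cfg = GeneratorConfig(
        n_participants=P, n_vertices=2, trials_per_condition_per_run=T,
        sessions=("baseline",), signal_uniform_fraction=1.0,
        noise_uniform_fraction=1.0, seed=seed, **kw,
    )
    table, truth = generate_trial_scores(cfg)
    return table, truth


def quiet_sample(model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sample_posterior(model)


def make_samples(model, **arrays):
    """PosteriorSamples shell with hand-built draw arrays."""
    defaults = dict(
        model=model,
        theta=np.zeros((1, 1, model.n_free)),
        m=np.zeros((1, 1, model.n_m)),
        g=np.zeros((1, 1, model.n_g)),
        sd=np.ones((1, 1, model.K)),
        corr=[np.broadcast_to(np.eye(len(b)), (1, 1, len(b), len(b))).copy() for b in model.blocks],
        df=np.full((1, 1), 30.0),
        effects=np.zeros((1, 1, model.P, model.K)),
        rho=np.zeros((1, 1)),
        rhat={},
        ess={},
        n_divergent=np.zeros(1),
        divergence_fraction=0.0,
    )
    defaults.update(arrays)
    return PosteriorSamples(**defaults)


# ---------------------------------------------------------------------------
# sampling contracts
# ---------------------------------------------------------------------------
def test_identical_seed_identical_draws():
    table, _ = toy_scores()
    mcmc = MCMCSettings(n_chains=2, n_iter=120, n_warmup=60, seed=4)
    a = quiet_sample(build_model(HierarchicalModelSpec("homog", mcmc=mcmc), table))
    b = quiet_sample(build_model(HierarchicalModelSpec("homog", mcmc=mcmc), table))
    np.testing.assert_array_equal(a.theta, b.theta)
    mcmc2 = MCMCSettings(n_chains=2, n_iter=120, n_warmup=60, seed=5)
    c = quiet_sample(build_model(HierarchicalModelSpec("homog", mcmc=mcmc2), table))
    assert not np.array_equal(a.theta, c.theta)


def test_conjugate_limit_recovers_gaussian_posterior_mean():
    """Fixed-effects-only Gaussian subcase: the sampled posterior mean of the
    population Stroop effect matches the closed-form normal posterior mean
    computed at the known residual SD."""
    sigma = 0.2
    table, _ = toy_scores(
        P=5, T=60, seed=8,
        sd_individual_mean=0.0, sd_individual_stroop=0.0, sd_scale_random=0.0,
        population_stroop=0.1, trial_noise_sd=sigma,
    )
    spec = HierarchicalModelSpec(
        "homog", df_fixed=np.inf, random_effects=False,
        mcmc=MCMCSettings(n_chains=2, n_iter=800, n_warmup=400, seed=1),
    )
    model = build_model(spec, table)
    samples = quiet_sample(model)

    # closed form: m | y ~ N((X'X/s^2 + S0^-1)^-1 X'y/s^2, .) with X the
    # cell design expanded through the contrast matrix
    X = model.A_fix[model.idx_cell]
    prec = X.T @ X / sigma**2 + np.eye(4) / model.m_prior_sd**2
    mean_closed = np.linalg.solve(prec, X.T @ model.y / sigma**2)
    stroop_closed = 0.5 * (mean_closed[1] + mean_closed[3])

    draws = samples.stroop_fixed_draws().ravel()
    ess = max(min(samples.ess.values()), 50)
    mcse = draws.std() / np.sqrt(ess)
    assert abs(draws.mean() - stroop_closed) < 3 * mcse + 1e-4


def test_prior_predictive_rho_near_uniform():
    """With the likelihood disabled the TRR prior is LKJ(1) on a 2x2 block,
    i.e. uniform on (-1, 1)."""
    table, _ = toy_scores()
    spec = HierarchicalModelSpec(
        "ils_sym", likelihood=False,
        mcmc=MCMCSettings(n_chains=2, n_iter=900, n_warmup=300, seed=2),
    )
    samples = quiet_sample(build_model(spec, table))
    rho = samples.rho.ravel()
    assert abs(rho.mean()) < 0.12
    assert rho.std() == pytest.approx(1 / np.sqrt(3), abs=0.07)
    assert rho.min() < -0.9 and rho.max() > 0.9


def test_divergence_and_diagnostic_fields_present():
    table, _ = toy_scores()
    samples = quiet_sample(
        build_model(
            HierarchicalModelSpec(
                "ils_sym", mcmc=MCMCSettings(n_chains=2, n_iter=150, n_warmup=80, seed=3)
            ),
            table,
        )
    )
    assert set(samples.rhat) == set(samples.model.parameter_manifest)
    assert np.all(samples.sd > 0)
    for block in samples.corr:
        off = block[..., 1, 0]
        assert np.all((off > -1) & (off < 1))
    assert np.all(samples.df >= 1)
    assert 0 <= samples.divergence_fraction <= 1


# ---------------------------------------------------------------------------
# TRR contrast algebra
# ---------------------------------------------------------------------------
def test_trr_is_identity_for_contrast_coding():
    table, _ = toy_scores()
    model = build_model(HierarchicalModelSpec("ils_sym"), table)
    rng = np.random.default_rng(0)
    vals = np.tanh(rng.standard_normal((2, 7)))
    corr = [np.broadcast_to(np.eye(2), (2, 7, 2, 2)).copy() for _ in range(4)]
    b = model.block_names.index("mu_stroop")
    corr[b][..., 0, 1] = vals
    corr[b][..., 1, 0] = vals
    samples = make_samples(
        model,
        theta=np.zeros((2, 7, model.n_free)),
        m=np.zeros((2, 7, 4)), g=np.zeros((2, 7, 4)),
        sd=np.ones((2, 7, 8)), corr=corr, df=np.full((2, 7), 30.0),
        effects=np.zeros((2, 7, model.P, 8)), rho=np.zeros((2, 7)),
    )
    np.testing.assert_array_equal(trr_posterior(samples), vals)


def test_trr_contrast_matrix_reproduces_constructed_correlation():
    """Flat coding: build the 4x4 location covariance from mean/stroop
    components with stroop correlation 0.7; the W-contrast must return
    exactly 0.7."""
    table, _ = toy_scores()
    model = build_model(HierarchicalModelSpec("ils"), table)
    # components: (mean_t, stroop_t, mean_r, stroop_r)
    comp_cov = np.diag([0.3**2, 1.0, 0.3**2, 1.0])
    comp_cov[1, 3] = comp_cov[3, 1] = 0.7
    # cells = A comp with A the +-1/2 contrast expansion
    A = np.array([[1, 0.5, 0, 0], [1, -0.5, 0, 0], [0, 0, 1, 0.5], [0, 0, 1, -0.5]])
    cov = A @ comp_cov @ A.T
    sd4 = np.sqrt(np.diag(cov))
    R = cov / np.outer(sd4, sd4)
    samples = make_samples(
        model,
        sd=np.concatenate([sd4, np.ones(4)])[None, None, :],
        corr=[
            R[None, None, :, :],
            np.eye(4)[None, None, :, :],
        ],
    )
    rho = trr_posterior(samples)
    assert rho[0, 0] == pytest.approx(0.7, abs=1e-12)


def test_trr_diagonal_covariance_gives_zero():
    table, _ = toy_scores()
    model = build_model(HierarchicalModelSpec("ils"), table)
    samples = make_samples(model, sd=np.ones((1, 1, 8)))
    assert trr_posterior(samples)[0, 0] == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def test_summarize_trr_degenerate_posterior_and_precision_limit():
    rng = np.random.default_rng(1)
    sds, precisions = [], []
    for jitter in (0.05, 0.01, 0.002):
        draws = 0.8 + jitter * rng.standard_normal(4000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = summarize_trr(draws)
        assert s.map == pytest.approx(0.8, abs=5 * jitter)
        assert s.post_mean == pytest.approx(0.8, abs=5 * jitter)
        sds.append(s.sd)
        precisions.append(s.precision)
    assert sds[0] > sds[1] > sds[2]
    # precision = 1/ln(sd) rises toward 0- as the posterior tightens
    assert precisions[0] < precisions[1] < precisions[2] < 0


def test_precision_arithmetic_from_definition():
    rng = np.random.default_rng(2)
    for sd_target, want in [(0.1, 1 / np.log(0.1)), (0.5, 1 / np.log(0.5))]:
        z = rng.standard_normal(5000)
        draws = (z - z.mean()) / z.std() * sd_target  # exact sd, mean 0
        s = summarize_trr(draws)
        assert s.sd == pytest.approx(sd_target, abs=1e-12)
        assert s.precision == pytest.approx(want, abs=1e-9)
    assert 1 / np.log(0.1) == pytest.approx(-0.4343, abs=1e-4)
    assert 1 / np.log(0.5) == pytest.approx(-1.4427, abs=1e-4)


def test_post_mean_zero_for_symmetric_draws():
    rng = np.random.default_rng(3)
    half = 0.6 * rng.random(2000)
    draws = np.concatenate([half, -half])  # exactly symmetric
    s = summarize_trr(draws)
    assert s.post_mean == pytest.approx(0.0, abs=1e-12)
    assert abs(s.map) < 0.1


def test_t_plus_definition_and_antisymmetry():
    table, _ = toy_scores()
    model = build_model(HierarchicalModelSpec("ils_sym"), table)
    rng = np.random.default_rng(4)
    c, s_noise = 0.3, 0.07
    m = np.zeros((1, 3000, 4))
    noise = s_noise * rng.standard_normal((1, 3000))
    m[..., 1] = c + noise  # stroop_test
    m[..., 3] = c + noise  # stroop_retest
    samples = make_samples(model, m=m, g=np.zeros((1, 3000, 4)),
                           sd=np.ones((1, 3000, 8)),
                           df=np.full((1, 3000), 30.0),
                           effects=np.zeros((1, 3000, model.P, 8)),
                           rho=np.zeros((1, 3000)),
                           corr=[np.broadcast_to(np.eye(2), (1, 3000, 2, 2)).copy() for _ in range(4)],
                           theta=np.zeros((1, 3000, model.n_free)))
    got = t_plus(samples)
    assert got == pytest.approx(c / s_noise, rel=0.05)
    flipped = make_samples(model, m=-m, g=np.zeros((1, 3000, 4)),
                           sd=np.ones((1, 3000, 8)),
                           df=np.full((1, 3000), 30.0),
                           effects=np.zeros((1, 3000, model.P, 8)),
                           rho=np.zeros((1, 3000)),
                           corr=[np.broadcast_to(np.eye(2), (1, 3000, 2, 2)).copy() for _ in range(4)],
                           theta=np.zeros((1, 3000, model.n_free)))
    assert t_plus(flipped) == pytest.approx(-got, abs=1e-12)


def test_variability_ratio_geometric_mean_and_reading_divergence():
    table, _ = toy_scores()
    model = build_model(HierarchicalModelSpec("ils_sym"), table)
    g = np.zeros((1, 1, 4))
    g[..., model.g_names.index("gamma[mean_test]")] = np.log(2.0)
    g[..., model.g_names.index("gamma[mean_retest]")] = np.log(2.0)
    sd = np.ones((1, 1, 8))
    b = model.block_names.index("mu_stroop")
    sd[..., model.blocks[b]] = 2.0  # Sigma = diag(4, 4)
    samples = make_samples(model, g=g, sd=sd)
    log_mode, ratio = variability_ratio(samples)  # literal Tr(log Sigma)
    # gamma_bar = 2; sigma_bar = sqrt(det diag(4,4)) = 4 -> ratio = 1/2
    assert ratio == pytest.approx(0.5, abs=1e-10)
    log_mode_d, ratio_d = variability_ratio(samples, diagonal=True)
    # diagonal reading: sigma_bar = sqrt(2 * 2) = 2 -> ratio = 1
    assert ratio_d == pytest.approx(1.0, abs=1e-10)
    assert ratio != ratio_d  # the two documented readings differ


def test_variability_ratio_requires_ils_sym():
    table, _ = toy_scores()
    model = build_model(HierarchicalModelSpec("homog"), table)
    samples = make_samples(model, sd=np.ones((1, 1, 4)),
                           effects=np.zeros((1, 1, model.P, 4)),
                           g=np.zeros((1, 1, 1)),
                           corr=[np.broadcast_to(np.eye(2), (1, 1, 2, 2)).copy() for _ in range(2)])
    with pytest.raises(ValueError, match="ils_sym"):
        variability_ratio(samples)
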
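"""Spatial-model contracts: centering, shrinkage LDA, undersampling, CV."""

import numpy as np
import pandas as pd
import pytest

from trrkit.datasets import TrialPatternSet
from trrkit.decoding import (
    center_patterns,
    fit_decoder_cv,
    lda_weights,
    project,
    shrink_covariance,
    undersample_splits,
    univariate_weights,
)
from trrkit.synthetic import GeneratorConfig, generate_trial_patterns

from conftest import make_labels


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------
def test_centering_zeroes_mean_of_condition_means(small_patterns):
    centered = center_patterns(small_patterns)
    lab = centered.labels
    for _, idx in lab.groupby(["participant", "repetition", "session", "run"]).groups.items():
        sub = lab.loc[idx]
        m_i = centered.values[sub.index[sub["condition"] == "incon"]].mean(axis=0)
        m_c = centered.values[sub.index[sub["condition"] == "congr"]].mean(axis=0)
        np.testing.assert_allclose(0.5 * (m_i + m_c), 0.0, atol=1e-12)


def test_centering_is_idempotent_and_preserves_contrast(small_patterns):
    once = center_patterns(small_patterns)
    twice = center_patterns(once)
    np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def contrast(p):
        lab = p.labels
        return (
            p.values[(lab["condition"] == "incon").to_numpy()].mean(axis=0)
            - p.values[(lab["condition"] == "congr").to_numpy()].mean(axis=0)
        )

    np.testing.assert_allclose(
        contrast(once), contrast(small_patterns), atol=1e-12
    )


def test_centering_hand_computed_shift():
    """Run with incon mean 2, congr mean 0 at one vertex: that vertex is
    shifted by -1 and the Stroop contrast is unchanged."""
    labels = make_labels(n_per_condition=8, runs=(1,), repetitions=("test",))
    values = np.zeros((len(labels), 1))
    values[(labels["condition"] == "incon").to_numpy(), 0] = 2.0
    patterns = TrialPatternSet(values, labels)
    centered = center_patterns(patterns)
    np.testing.assert_allclose(centered.values, values - 1.0, atol=1e-14)


def test_centering_requires_both_conditions():
    labels = make_labels(n_per_condition=4, runs=(1,), repetitions=("test",))
    labels = labels[labels["condition"] == "incon"].reset_index(drop=True)
    patterns = TrialPatternSet(np.zeros((len(labels), 2)), labels)
    with pytest.raises(ValueError, match="missing condition"):
        center_patterns(patterns)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------
def test_univariate_weights_are_uniform():
    assert univariate_weights(4).w == pytest.approx([0.25] * 4)
    assert univariate_weights(1).w == pytest.approx([1.0])
    with pytest.raises(ValueError):
        univariate_weights(0)


def test_univariate_projection_is_spatial_mean(small_patterns):
    scores = project(small_patterns, univariate_weights(2))
    np.testing.assert_allclose(
        scores.table["score"].to_numpy(), small_patterns.values.mean(axis=1)
    )


@pytest.mark.parametrize(
    "S, lam, expected",
    [
        (np.eye(3), 0.25, np.eye(3)),
        (np.array([[1.0, 0.8], [0.8, 1.0]]), 0.25, np.array([[1.0, 0.6], [0.6, 1.0]])),
        (np.array([[2.0, 0.5], [0.5, 3.0]]), 1.0, np.array([[2.0, 0.0], [0.0, 3.0]])),
    ],
)
def test_shrink_covariance(S, lam, expected):
    np.testing.assert_allclose(shrink_covariance(S, lam), expected)


def test_shrink_covariance_rejects_bad_lambda():
    with pytest.raises(ValueError):
        shrink_covariance(np.eye(2), 1.5)


def _patterns_from_classes(x_incon, x_congr):
    n_i, n_c = len(x_incon), len(x_congr)
    rows = []
    for t in range(n_i):
        rows.append((0, "test", "baseline", 1, "incon", t, t % 8, (t + 1) % 8, False))
    for t in range(n_c):
        rows.append((0, "test", "baseline", 1, "congr", n_i + t, t % 8, t % 8, False))
    labels = pd.DataFrame(
        rows,
        columns=[
            "participant", "repetition", "session", "run", "condition",
            "trial", "word", "color", "censored",
        ],
    )
    return TrialPatternSet(np.vstack([x_incon, x_congr]), labels)


def test_lda_isotropic_case_parallel_to_mean_difference():
    rng = np.random.default_rng(0)
    x_i = rng.standard_normal((4000, 2)) + np.array([1.0, 0.0])
    x_c = rng.standard_normal((4000, 2))
    w = lda_weights(_patterns_from_classes(x_i, x_c), lam=0.0).w
    assert abs(w[0]) > 0.99  # ~ (1, 0)
    assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-12)


def test_lda_2x2_closed_form():
    """S = [[1, .8], [.8, 1]], lam 0.25 -> shrunk [[1, .6], [.6, 1]];
    mean diff (1, 1) -> w proportional to (0.625, 0.625) -> (1, 1)/sqrt(2)."""
    rng = np.random.default_rng(1)
    # construct data whose pooled covariance and mean difference are exact
    n = 6000
    L = np.linalg.cholesky(np.array([[1.0, 0.8], [0.8, 1.0]]))
    z = rng.standard_normal((n, 2))
    z = (z - z.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(z.T, ddof=1))).T
    base = z @ L.T  # empirical covariance exactly S
    x_i = base + 0.5 * np.array([1.0, 1.0])
    x_c = base - 0.5 * np.array([1.0, 1.0])
    w = lda_weights(_patterns_from_classes(x_i, x_c), lam=0.25).w
    np.testing.assert_allclose(w, [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-10)


def test_lda_maximizes_between_within_ratio_against_grid_oracle():
    """The returned direction attains the best between/within variance ratio
    over a dense grid of 2-D unit vectors (with matched shrinkage)."""
    rng = np.random.default_rng(2)
    cov = np.array([[1.0, 0.6], [0.6, 2.0]])
    L = np.linalg.cholesky(cov)
    x_i = rng.standard_normal((300, 2)) @ L.T + np.array([0.8, 0.3])
    x_c = rng.standard_normal((300, 2)) @ L.T
    patterns = _patterns_from_classes(x_i, x_c)
    w = lda_weights(patterns, lam=0.25).w

    cond = patterns.labels["condition"].to_numpy()
    Xi, Xc = patterns.values[cond == "incon"], patterns.values[cond == "congr"]
    S = 0.5 * (np.cov(Xi.T, ddof=1) + np.cov(Xc.T, ddof=1))
    S = shrink_covariance(S, 0.25)
    md = Xi.mean(0) - Xc.mean(0)

    def criterion(v):
        return float((v @ md) ** 2 / (v @ S @ v))

    angles = np.linspace(0, np.pi, 20001)
    grid_best = max(criterion(np.array([np.cos(a), np.sin(a)])) for a in angles)
    assert criterion(w) >= grid_best - 1e-6


def test_lda_identical_means_rejected():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((50, 2))
    with pytest.raises(ValueError, match="identical class means"):
        lda_weights(_patterns_from_classes(x, x))


# ---------------------------------------------------------------------------
# undersampling
# ---------------------------------------------------------------------------
def test_undersampling_exhaustive_when_cells_equal():
    labels = make_labels(n_per_condition=24, runs=(1,), repetitions=("test",))
    # every (condition, word) cell has exactly 3 trials
    subsets = undersample_splits(labels, n_subsets=5, seed=0)
    for sub in subsets:
        assert len(sub) == len(labels)


def test_undersampling_balances_conditions_under_imbalance():
    lab_i = make_labels(n_per_condition=16, runs=(1,), repetitions=("test",))
    lab = lab_i[
        (lab_i["condition"] == "congr") | (lab_i["trial"] < 8)
    ].reset_index(drop=True)  # 8 incon (1/word), 16 congr (2/word)
    subsets = undersample_splits(lab, n_subsets=10, seed=1)
    for sub in subsets:
        cond = lab.loc[sub, "condition"]
        assert (cond == "incon").sum() == (cond == "congr").sum() == 8
        words = lab.loc[sub].groupby(["condition", "word"]).size()
        assert (words == 1).all()  # k = 1 per (condition, word) cell


def test_undersampling_deterministic_given_seed():
    # 12 trials/condition over 8 words: cells of 1 and 2 -> k = 1, so the
    # sampled subsets genuinely depend on the seed
    labels = make_labels(n_per_condition=12)
    a = undersample_splits(labels, n_subsets=3, seed=5)
    b = undersample_splits(labels, n_subsets=3, seed=5)
    c = undersample_splits(labels, n_subsets=3, seed=6)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def test_undersampling_reports_empty_cell():
    labels = make_labels(n_per_condition=8, runs=(1,), repetitions=("test",))
    labels = labels[~((labels["condition"] == "incon") & (labels["word"] == 3))]
    with pytest.raises(ValueError, match="word cells \\[3\\]"):
        undersample_splits(labels.reset_index(drop=True))


# ---------------------------------------------------------------------------
# cross-validated decoding
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def spatial_patterns():
    cfg = GeneratorConfig(
        n_participants=1,
        n_vertices=12,
        trials_per_condition_per_run=16,
        sessions=("baseline", "proactive", "reactive"),
        population_stroop=0.15,
        trial_noise_sd=0.1,
        noise_uniform_fraction=0.85,
        signal_uniform_fraction=0.3,
        seed=11,
    )
    patterns, _ = generate_trial_patterns(cfg)
    return patterns


def test_cv_weights_unit_norm_and_partition(spatial_patterns):
    w = fit_decoder_cv(spatial_patterns, "baseline", n_subsets=10, seed=0)
    assert np.linalg.norm(w.w) == pytest.approx(1.0, abs=1e-12)
    assert w.training_sessions == ("proactive", "reactive")
    assert w.n_resamples == 10


def test_cv_on_noise_free_data_equals_single_fit():
    """With zero trial noise every undersampled fit sees the same class
    geometry, so the averaged weights equal a single fit's weights."""
    cfg = GeneratorConfig(
        n_participants=1,
        n_vertices=6,
        trials_per_condition_per_run=8,
        sessions=("baseline", "proactive", "reactive"),
        population_stroop=0.2,
        sd_individual_mean=0.0,
        sd_individual_stroop=0.0,
        trial_noise_sd=1e-6,   # tiny jitter keeps covariances nonsingular
        noise_uniform_fraction=0.5,
        signal_uniform_fraction=0.5,
        seed=4,
    )
    patterns, _ = generate_trial_patterns(cfg)
    w_cv = fit_decoder_cv(patterns, "baseline", n_subsets=8, seed=0).w
    from trrkit.decoding import center_patterns as cp

    train = patterns.select(
        (patterns.labels["session"] != "baseline").to_numpy()
    )
    w_single = lda_weights(cp(train)).w
    np.testing.assert_allclose(np.abs(w_cv @ w_single), 1.0, atol=1e-6)


def test_cv_requires_single_participant():
    cfg = GeneratorConfig(
        n_participants=2,
        n_vertices=4,
        trials_per_condition_per_run=8,
        noise_uniform_fraction=0.5,
        signal_uniform_fraction=0.5,
        seed=0,
    )
    patterns, _ = generate_trial_patterns(cfg)
    with pytest.raises(ValueError, match="single participant"):
        fit_decoder_cv(patterns, "baseline")


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------
def test_projection_basis_vector_picks_vertex(small_patterns):
    from trrkit.decoding import DecoderWeights

    w = DecoderWeights(np.array([0.0, 1.0]), "multiv")
    scores = project(small_patterns, w)
    np.testing.assert_allclose(
        scores.table["score"].to_numpy(), small_patterns.values[:, 1]
    )


def test_projection_is_linear(small_patterns):
    w = univariate_weights(2)
    a, b = 2.0, -3.0
    combo = TrialPatternSet(
        a * small_patterns.values + b * small_patterns.values**2,
        small_patterns.labels,
    )
    s_combo = project(combo, w).table["score"].to_numpy()
    s1 = project(small_patterns, w).table["score"].to_numpy()
    sq = TrialPatternSet(small_patterns.values**2, small_patterns.labels)
    s2 = project(sq, w).table["score"].to_numpy()
    np.testing.assert_allclose(s_combo, a * s1 + b * s2, atol=1e-12)


def test_projection_drops_censored_trials(small_patterns):
    labels = small_patterns.labels.copy()
    labels.loc[0, "censored"] = True
    patterns = TrialPatternSet(small_patterns.values, labels)
    scores = project(patterns, univariate_weights(2))
    assert len(scores.table) == len(labels) - 1


def test_projection_dimension_mismatch(small_patterns):
    with pytest.raises(ValueError, match="mismatch"):
        project(small_patterns, univariate_weights(5))
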
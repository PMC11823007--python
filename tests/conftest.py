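import numpy as np
import pandas as pd
import pytest

from trrkit.datasets import LABEL_COLUMNS, TrialPatternSet, TrialScores
from trrkit.synthetic import GeneratorConfig, generate_trial_patterns, generate_trial_scores


def make_labels(
    n_per_condition=8,
    participants=(0,),
    repetitions=("test", "retest"),
    sessions=("baseline",),
    runs=(1, 2),
):
    """Balanced label table: one trial per word per condition by default."""
    rows = []
    for p in participants:
        for r in repetitions:
            for s in sessions:
                for run in runs:
                    t = 0
                    for c in ("incon", "congr"):
                        for k in range(n_per_condition):
                            w = k % 8
                            col = w if c == "congr" else (w + 1) % 8
                            rows.append((p, r, s, run, c, t, w, col, False))
                            t += 1
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)


@pytest.fixture
def small_patterns():
    """Deterministic 2-vertex patterns for a single participant."""
    labels = make_labels(n_per_condition=8)
    rng = np.random.default_rng(42)
    values = rng.standard_normal((len(labels), 2))
    # add a condition contrast on vertex 0
    values[labels["condition"] == "incon", 0] += 1.0
    return TrialPatternSet(values, labels)


@pytest.fixture
def scalar_scores():
    """Scalar synthetic scores (moderate noise) as a TrialScores table."""
    cfg = GeneratorConfig(
        n_participants=12,
        n_vertices=2,
        trials_per_condition_per_run=12,
        sessions=("baseline",),
        signal_uniform_fraction=1.0,
        noise_uniform_fraction=1.0,
        rho_stroop=0.6,
        trial_noise_sd=0.08,
        seed=7,
    )
    table, truth = generate_trial_scores(cfg)
    table = table.assign(model="scalar")
    return TrialScores(table[TrialScores.REQUIRED]), truth


@pytest.fixture
def spatial_config():
    """Spiked-uniform-noise generator with partly off-uniform signal."""
    return GeneratorConfig(
        n_participants=4,
        n_vertices=24,
        trials_per_condition_per_run=16,
        sessions=("baseline", "proactive", "reactive"),
        population_stroop=0.12,
        sd_individual_stroop=0.03,
        rho_stroop=0.6,
        trial_noise_sd=0.15,
        noise_uniform_fraction=0.9,
        signal_uniform_fraction=0.25,
        seed=5,
    )
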
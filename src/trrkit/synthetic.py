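"""Synthetic trial-level multivoxel data with known ground truth.

The generator emulates the hierarchical statistical structure assumed by
the reliability models: per-participant location and log-scale effects
drawn from correlated bivariate normals across the test/retest
repetitions, Student-t (or Gaussian) trial noise, and a spatial
expansion in which the trial-noise covariance concentrates a configured
fraction of variance on the spatially uniform direction while the
signal topography may lie partly off-uniform.  Every draw is recorded
in a :class:`SyntheticTruth` so recovery can be tested exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import CONDITIONS, REPETITIONS, SESSIONS, LABEL_COLUMNS, TrialPatternSet
from .trials import RunTimeseries, WINDOW_OFFSETS

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "RunRecording",
    "generate_trial_patterns",
    "generate_trial_scores",
    "generate_run_timeseries",
]

N_WORDS = 8
N_COLORS = 8


@dataclass
class GeneratorConfig:
    """Generating truth for one region's trial patterns.

    Units are percent signal change throughout.  ``population_stroop``
    and ``population_mean`` are the fixed effects m per repetition
    (scalar broadcasts to both).  ``trial_noise_sd`` is the t/Gaussian
    *scale* of trial noise (exp gamma); ``sd_scale_random`` is the SD of
    the per-participant log-scale effect tau.  ``noise_uniform_fraction``
    puts that share of trial-noise variance on the uniform spatial
    direction u = 1/sqrt(V); ``signal_uniform_fraction`` puts that share
    of the squared signal-topography norm on u.
    """

    n_participants: int = 27
    n_vertices: int = 60
    trials_per_condition_per_run: int = 54
    n_runs_per_session: int = 2
    sessions: tuple[str, ...] = SESSIONS
    repetitions: tuple[str, ...] = REPETITIONS
    population_stroop: float | tuple[float, float] = 0.05
    population_mean: float | tuple[float, float] = 0.0
    sd_individual_stroop: float = 0.025
    sd_individual_mean: float = 0.10
    rho_stroop: float = 0.5
    rho_mean: float = 0.5
    trial_noise_sd: float = 0.15
    sd_scale_random: float = 0.2
    rho_scale: float = 0.0
    noise_uniform_fraction: float = 0.8
    signal_uniform_fraction: float = 0.3
    shared_topography: bool = True
    t_df: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_vertices", "trials_per_condition_per_run",
                     "n_runs_per_session"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("sd_individual_stroop", "sd_individual_mean", "trial_noise_sd",
                     "sd_scale_random"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_stroop", "rho_mean", "rho_scale"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        for name in ("noise_uniform_fraction", "signal_uniform_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.t_df is not None and not (self.t_df > 0):
            raise ValueError("t_df must be positive (inf for Gaussian)")
        if self.n_vertices < 2 and (
            self.signal_uniform_fraction < 1 or self.noise_uniform_fraction < 1
        ):
            raise ValueError(
                "n_vertices < 2 leaves no orthogonal direction; set both "
                "uniform fractions to 1"
            )

    def rep_values(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.repeat(arr, len(self.repetitions))
        if arr.size != len(self.repetitions):
            raise ValueError("per-repetition value has wrong length")
        return arr


@dataclass
class SyntheticTruth:
    """Everything drawn by the generator, for recovery tests."""

    config: GeneratorConfig
    mu_mean: np.ndarray            # (P, 2) per-participant location, mean component
    mu_stroop: np.ndarray          # (P, 2)
    tau: np.ndarray                # (P, 2) per-participant log-scale effects
    gamma: float                   # log trial_noise_sd
    m_mean: np.ndarray             # (2,) fixed effects per repetition
    m_stroop: np.ndarray           # (2,)
    topographies: dict = field(default_factory=dict)   # condition -> (V,) unit vec
    uniform_direction: np.ndarray | None = None        # u = 1/sqrt(V)
    noise_basis: np.ndarray | None = None              # (V, V-1) orthonormal complement
    noise_dir_sds: np.ndarray | None = None            # per-direction noise SDs [u, rest...]
    realized_stroop: np.ndarray | None = None          # (P, 2) m + mu, stroop component
    realized_mean: np.ndarray | None = None            # (P, 2)
    sample_mean_stroop: np.ndarray | None = None       # (2,)

    @property
    def noise_covariance(self) -> np.ndarray:
        """Implied spatial trial-noise covariance at tau = 0."""
        u = self.uniform_direction
        sds = self.noise_dir_sds
        cov = sds[0] ** 2 * np.outer(u, u)
        if self.noise_basis is not None and self.noise_basis.shape[1]:
            cov = cov + self.noise_basis @ (
                np.diag(sds[1:] ** 2) @ self.noise_basis.T
            )
        return cov

    def write_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
            },
            "gamma": float(self.gamma),
            "m_mean": self.m_mean.tolist(),
            "m_stroop": self.m_stroop.tolist(),
            "mu_mean": self.mu_mean.tolist(),
            "mu_stroop": self.mu_stroop.tolist(),
            "tau": self.tau.tolist(),
            "realized_stroop": self.realized_stroop.tolist(),
            "realized_mean": self.realized_mean.tolist(),
            "sample_mean_stroop": self.sample_mean_stroop.tolist(),
            "topographies": {k: v.tolist() for k, v in self.topographies.items()},
            "noise_dir_sds": self.noise_dir_sds.tolist()
            if self.noise_dir_sds is not None
            else None,
        }
        doc["config"]["t_df"] = (
            "inf" if np.isinf(self.config.t_df) else float(self.config.t_df)
        )
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _draw_bivariate(rng, sd: float, rho: float, n: int) -> np.ndarray:
    """n draws of a correlated (test, retest) pair with common SD."""
    if sd == 0:
        return np.zeros((n, 2))
    cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov)
    return rng.standard_normal((n, 2)) @ L.T


def _word_color(condition: str, k: int) -> tuple[int, int]:
    """Round-robin word/color assignment: balanced words, near-balanced colors."""
    if condition == "congr":
        w = k % N_WORDS
        return w, w
    w = k % N_WORDS
    c = (w + 1 + (k // N_WORDS) % (N_COLORS - 1)) % N_COLORS
    return w, c


def _standard_noise(rng, size, df: float) -> np.ndarray:
    if np.isinf(df):
        return rng.standard_normal(size)
    return rng.standard_t(df, size)


def generate_trial_scores(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Scalar trial scores (the pre-spatial core of the generator).

    Returns a long table with one row per trial (columns: the factor
    labels plus ``alpha``, ``noise_scale`` and ``score``) and the truth.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    P = config.n_participants
    reps = list(config.repetitions)
    m_mean = config.rep_values(config.population_mean)
    m_stroop = config.rep_values(config.population_stroop)

    mu_mean = _draw_bivariate(rng, config.sd_individual_mean, config.rho_mean, P)
    mu_stroop = _draw_bivariate(rng, config.sd_individual_stroop, config.rho_stroop, P)
    tau = _draw_bivariate(rng, config.sd_scale_random, config.rho_scale, P)
    gamma = float(np.log(config.trial_noise_sd)) if config.trial_noise_sd > 0 else -np.inf

    rows = []
    T = config.trials_per_condition_per_run
    for p in range(P):
        for ri, rep in enumerate(reps):
            for session in config.sessions:
                for run in range(1, config.n_runs_per_session + 1):
                    counters = {c: 0 for c in CONDITIONS}
                    order = []
                    for c in CONDITIONS:
                        order += [c] * T
                    order = list(rng.permutation(order))
                    for t_idx, c in enumerate(order):
                        k = counters[c]
                        counters[c] += 1
                        w, col = _word_color(c, k)
                        sign = 0.5 if c == "incon" else -0.5
                        alpha = (
                            m_mean[ri]
                            + mu_mean[p, ri]
                            + sign * (m_stroop[ri] + mu_stroop[p, ri])
                        )
                        scale = (
                            float(np.exp(gamma + tau[p, ri]))
                            if np.isfinite(gamma)
                            else 0.0
                        )
                        rows.append(
                            (p, rep, session, run, c, t_idx, w, col, False, alpha, scale)
                        )
    table = pd.DataFrame(
        rows, columns=LABEL_COLUMNS + ["alpha", "noise_scale"]
    )
    z = _standard_noise(rng, len(table), config.t_df)
    table["score"] = table["alpha"] + table["noise_scale"] * z

    realized_stroop = m_stroop[None, :] + mu_stroop
    realized_mean = m_mean[None, :] + mu_mean
    truth = SyntheticTruth(
        config=config,
        mu_mean=mu_mean,
        mu_stroop=mu_stroop,
        tau=tau,
        gamma=gamma,
        m_mean=m_mean,
        m_stroop=m_stroop,
        realized_stroop=realized_stroop,
        realized_mean=realized_mean,
        sample_mean_stroop=realized_stroop.mean(axis=0),
    )
    return table, truth


def generate_trial_patterns(
    config: GeneratorConfig,
) -> tuple[TrialPatternSet, SyntheticTruth]:
    """Spatial trial patterns: signal topography times the trial's latent
    amplitude plus spatially structured noise.

    The trial-noise covariance is ``s^2 (f_u u u^T + (1-f_u)/(V-1) Q Q^T)``
    with ``s = exp(gamma + tau)``, u the uniform direction and Q an
    orthonormal basis of its complement; the (unit-norm) signal
    topography carries ``signal_uniform_fraction`` of its squared norm on
    u.  Deterministic given ``config.seed``.
    """
    table, truth = generate_trial_scores(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    V = config.n_vertices
    u = np.ones(V) / np.sqrt(V)

    if V > 1:
        A = np.concatenate([u[:, None], rng.standard_normal((V, V - 1))], axis=1)
        Q_full, _ = np.linalg.qr(A)
        # fix sign so the first column is +u
        if Q_full[0, 0] < 0:
            Q_full = -Q_full
        Q = Q_full[:, 1:]
    else:
        Q = np.zeros((1, 0))

    suf = config.signal_uniform_fraction
    topo = {}
    q_shared = Q @ _unit(rng.standard_normal(V - 1)) if V > 1 and suf < 1 else None
    for c in CONDITIONS:
        if suf >= 1 or V == 1:
            topo[c] = u.copy()
        else:
            q_c = q_shared if config.shared_topography else Q @ _unit(
                rng.standard_normal(V - 1)
            )
            topo[c] = np.sqrt(suf) * u + np.sqrt(1 - suf) * q_c

    nuf = config.noise_uniform_fraction
    n_orth = V - 1
    base_sds = np.zeros(1 + n_orth)
    base_sds[0] = np.sqrt(nuf)
    if n_orth:
        base_sds[1:] = np.sqrt((1 - nuf) / n_orth)

    n_trials = len(table)
    alpha = table["alpha"].to_numpy()
    scale = table["noise_scale"].to_numpy()
    cond = table["condition"].to_numpy()

    signal = np.empty((n_trials, V))
    for c in CONDITIONS:
        mask = cond == c
        signal[mask] = alpha[mask, None] * topo[c][None, :]

    z_u = _standard_noise(rng, n_trials, config.t_df)
    noise = (scale * base_sds[0] * z_u)[:, None] * u[None, :]
    if n_orth:
        z_o = _standard_noise(rng, (n_trials, n_orth), config.t_df)
        noise = noise + (scale[:, None] * z_o * base_sds[1:][None, :]) @ Q.T

    values = signal + noise
    truth.topographies = topo
    truth.uniform_direction = u
    truth.noise_basis = Q
    truth.noise_dir_sds = float(np.exp(truth.gamma) if np.isfinite(truth.gamma) else 0.0) * base_sds
    labels = table[LABEL_COLUMNS].copy()
    patterns = TrialPatternSet(values, labels, {"seed": config.seed})
    return patterns, truth


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ----------------------------------------------------------------------
# TR-resolution timeseries
# ----------------------------------------------------------------------
@dataclass
class RunRecording:
    """One simulated run: series, ground-truth onsets, FD trace."""

    timeseries: RunTimeseries
    onsets: pd.DataFrame      # trial labels + onset TR index
    fd: np.ndarray


def generate_run_timeseries(
    patterns: TrialPatternSet,
    tr_seconds: float = 1.2,
    iti_tr_choices: tuple[int, ...] = (1, 2, 3),
    drift_amplitude: float = 0.0,
    motion_config: dict | None = None,
    seed: int = 0,
    run_duration_s: float | None = None,
    lead_in_tr: int = 4,
) -> list[RunRecording]:
    """Expand trial patterns into per-run vertex x TR series.

    Each trial's pattern is injected additively into TRs onset+4..+6;
    inter-onset gaps are drawn uniformly from ``iti_tr_choices`` (gaps of
    1-3 TRs make neighboring windows overlap, mirroring the dense task
    design -- the resulting leakage is a property of the estimator, not
    an error).  Optional polynomial drift and motion-coupled nuisance are
    added; ``motion_config`` keys: ``amplitude`` (motion trace scale),
    ``coupling`` (signal per unit motion), ``fd_spikes`` (list of
    ``(tr_index, mm)`` displacement spikes).

    Raises if ``run_duration_s`` is too short for the requested trials.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    rng = np.random.default_rng(seed)
    motion_config = motion_config or {}
    recordings = []
    group_cols = ["participant", "repetition", "session", "run"]
    for keys, idx in patterns.labels.groupby(group_cols, sort=True).groups.items():
        idx = np.asarray(idx)
        sub = patterns.labels.loc[idx].sort_values("trial")
        order = sub.index.to_numpy()
        n_trials = len(order)

        gaps = rng.choice(iti_tr_choices, size=n_trials - 1) if n_trials > 1 else []
        onsets = (
            np.concatenate(([lead_in_tr], lead_in_tr + np.cumsum(gaps))).astype(int)
            if n_trials
            else np.array([], dtype=int)
        )
        min_tr = int(onsets[-1]) + WINDOW_OFFSETS[-1] + 2 if n_trials else lead_in_tr
        if run_duration_s is None:
            n_tr = min_tr
        else:
            n_tr = int(round(run_duration_s / tr_seconds))
            if n_tr < min_tr:
                raise ValueError(
                    f"run of {n_tr} TRs too short for {n_trials} trials "
                    f"(needs >= {min_tr})"
                )

        V = patterns.n_vertices
        values = np.zeros((V, n_tr))
        for onset, row in zip(onsets, order):
            window = onset + np.asarray(WINDOW_OFFSETS)
            values[:, window] += patterns.values[row][:, None]

        if drift_amplitude > 0:
            x = np.linspace(-1, 1, n_tr)
            basis = np.polynomial.legendre.legvander(x, 3)[:, 1:]  # degrees 1..3
            coeffs = drift_amplitude * rng.standard_normal((V, basis.shape[1]))
            values += coeffs @ basis.T

        amp = float(motion_config.get("amplitude", 0.0))
        motion = np.zeros((6, n_tr))
        if amp > 0:
            t = np.arange(n_tr)
            freqs = 0.005 + 0.02 * rng.random(6)
            phases = 2 * np.pi * rng.random(6)
            motion = amp * (
                np.sin(np.outer(freqs, t) + phases[:, None])
                + 0.3 * rng.standard_normal((6, n_tr))
            )
        for tr_idx, mm in motion_config.get("fd_spikes", []):
            motion[0, int(tr_idx)] += mm  # a step in one trace yields an FD spike
        coupling = motion_config.get("coupling", None)
        if coupling is not None:
            coupling = np.asarray(coupling, dtype=float)
            values += np.outer(np.ones(V), coupling @ motion)

        fd = np.zeros(n_tr)
        fd[1:] = np.sum(np.abs(np.diff(motion, axis=1)), axis=0)

        participant, repetition, session, run = keys
        ts = RunTimeseries(
            values=values,
            tr_seconds=tr_seconds,
            participant=participant,
            repetition=repetition,
            session=session,
            run=run,
            motion=motion,
            fd=fd,
        )
        onset_table = sub.reset_index(drop=True).copy()
        onset_table["onset_tr"] = onsets
        onset_table["pattern_row"] = order  # row index into patterns.values
        recordings.append(RunRecording(timeseries=ts, onsets=onset_table, fd=fd))
    return recordings
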
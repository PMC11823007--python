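"""Single-trial activation estimates from run timeseries.

Implements the selective-averaging estimator: per-run polynomial
detrending plus motion regression (motion concatenated across the two
runs of a session), averaging of the 4th-6th TRs after each trial
onset, and censoring of trials whose averaged window contains a
framewise-displacement excursion above 0.9 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RunTimeseries",
    "detrend_order",
    "percent_signal_change",
    "detrend",
    "selective_average",
    "censor",
    "estimate_trials",
    "FD_CENSOR_MM",
    "WINDOW_OFFSETS",
]

#: framewise-displacement censoring threshold (strict >) in mm
FD_CENSOR_MM = 0.9

#: TR offsets averaged per trial; the onset TR is offset 0
WINDOW_OFFSETS = (4, 5, 6)


@dataclass
class RunTimeseries:
    """Vertex x TR series (percent signal change) plus nuisance traces."""

    values: np.ndarray          # (n_vertices, n_tr)
    tr_seconds: float
    participant: object = None
    repetition: str | None = None
    session: str | None = None
    run: int | None = None
    motion: np.ndarray | None = None   # (6, n_tr)
    fd: np.ndarray | None = None       # (n_tr,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be vertices x TRs")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        n_tr = self.values.shape[1]
        if self.motion is None:
            self.motion = np.zeros((6, n_tr))
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.shape != (6, n_tr):
            raise ValueError(f"motion must be 6 x {n_tr}")
        if self.fd is None:
            self.fd = np.zeros(n_tr)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.shape != (n_tr,):
            raise ValueError(f"fd must have length {n_tr}")

    @property
    def n_tr(self) -> int:
        return self.values.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_tr * self.tr_seconds


def detrend_order(duration_s: float) -> int:
    """Polynomial detrending order: 1 + floor(D / 150) for duration D in s."""
    return 1 + int(np.floor(duration_s / 150.0))


def percent_signal_change(values: np.ndarray) -> np.ndarray:
    """Divisive normalization: 100 * (x / temporal mean - 1), per vertex."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=-1, keepdims=True)
    if np.any(mean == 0):
        raise ValueError("zero-mean vertex timeseries cannot be normalized")
    return 100.0 * (values / mean - 1.0)


def _legendre_basis(n_tr: int, order: int) -> np.ndarray:
    """Columns of Legendre polynomials of degree 0..order on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_tr)
    return np.polynomial.legendre.legvander(x, order)


def _drop_degenerate(design: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Remove constant-zero or rank-duplicating columns with a warning."""
    keep = []
    for j in range(design.shape[1]):
        col = design[:, j]
        if np.allclose(col, 0.0):  # silent: an all-zero regressor is a no-op
            continue
        if np.allclose(col, col[0]) and j > 0:  # constant (intercept kept once)
            warnings.warn(f"dropping degenerate detrending regressor {names[j]!r}")
            continue
        keep.append(j)
    design = design[:, keep]
    kept_names = [names[j] for j in keep]
    # rank check on the survivors
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        q, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        redundant = [k for k, d in enumerate(diag) if d < tol]
        for k in sorted(redundant, reverse=True):
            warnings.warn(f"dropping rank-deficient detrending regressor {kept_names[k]!r}")
            design = np.delete(design, k, axis=1)
            del kept_names[k]
    return design, kept_names


def detrend(ts: RunTimeseries, concat_partner: RunTimeseries | None = None) -> RunTimeseries:
    """Residualize a run against per-run polynomials and motion regressors.

    Polynomial bases (order ``1 + floor(D/150)``) are fit per run; the 6
    motion parameters are fit across both runs concatenated in time when
    ``concat_partner`` is supplied.  Returns the residual series for
    ``ts`` with identical shape.
    """
    if concat_partner is not None:
        if (
            concat_partner.participant != ts.participant
            or concat_partner.repetition != ts.repetition
        ):
            raise ValueError("concatenation partner must share participant and repetition")
        runs = [ts, concat_partner]
    else:
        runs = [ts]

    n_total = sum(r.n_tr for r in runs)
    blocks = []
    names: list[str] = []
    offset = 0
    for i, r in enumerate(runs):
        order = detrend_order(r.duration_s)
        basis = _legendre_basis(r.n_tr, order)
        block = np.zeros((n_total, basis.shape[1]))
        block[offset : offset + r.n_tr] = basis
        blocks.append(block)
        names += [f"run{i}_poly{d}" for d in range(basis.shape[1])]
        offset += r.n_tr
    motion = np.concatenate([r.motion for r in runs], axis=1).T  # (n_total, 6)
    design = np.concatenate(blocks + [motion], axis=1)
    names += [f"motion{k}" for k in range(6)]
    design, _ = _drop_degenerate(design, names)

    data = np.concatenate([r.values for r in runs], axis=1).T  # (n_total, V)
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    resid = (data - design @ beta).T
    out = resid[:, : ts.n_tr]
    return RunTimeseries(
        values=out,
        tr_seconds=ts.tr_seconds,
        participant=ts.participant,
        repetition=ts.repetition,
        session=ts.session,
        run=ts.run,
        motion=ts.motion.copy(),
        fd=ts.fd.copy(),
    )


def selective_average(ts: RunTimeseries, onsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial estimates: mean of TRs onset+4, +5, +6 (onset TR = 0).

    Returns ``(estimates, missing)``: estimates is trials x vertices;
    trials whose window would run past the end of the run are marked
    missing (NaN row) rather than silently truncated.
    """
    onsets = np.asarray(onsets, dtype=int)
    n_trials = onsets.size
    est = np.full((n_trials, ts.n_vertices), np.nan)
    missing = np.zeros(n_trials, dtype=bool)
    for k, onset in enumerate(onsets):
        window = onset + np.asarray(WINDOW_OFFSETS)
        if onset < 0 or window[-1] >= ts.n_tr:
            missing[k] = True
            continue
        est[k] = ts.values[:, window].mean(axis=1)
    return est, missing


def estimate_trials(recordings) -> "TrialPatternSet":
    """Full single-trial estimation: detrend, selectively average, censor.

    ``recordings`` is a sequence of run recordings (as produced by the
    synthetic timeseries generator): each carries a RunTimeseries, an
    onset table with the trial labels, and the FD trace.  Runs of the
    same (participant, repetition, session) are detrended with their
    motion regressors concatenated in time.  Returns the estimates as a
    TrialPatternSet with censored/missing trials flagged.
    """
    from .datasets import LABEL_COLUMNS, TrialPatternSet

    by_session: dict = {}
    for rec in recordings:
        ts = rec.timeseries
        by_session.setdefault((ts.participant, ts.repetition, ts.session), []).append(rec)

    frames = []
    blocks = []
    for key, recs in sorted(by_session.items(), key=lambda kv: str(kv[0])):
        for i, rec in enumerate(recs):
            partner = recs[1 - i].timeseries if len(recs) == 2 else None
            resid = detrend(rec.timeseries, concat_partner=partner)
            onsets = rec.onsets["onset_tr"].to_numpy()
            est, missing = selective_average(resid, onsets)
            flags = censor(est, onsets, rec.timeseries.fd) | missing
            labels = rec.onsets[LABEL_COLUMNS].copy()
            labels["censored"] = labels["censored"].to_numpy(dtype=bool) | flags
            frames.append(labels)
            blocks.append(est)
    values = np.concatenate(blocks, axis=0)
    labels = pd.concat(frames, ignore_index=True)
    return TrialPatternSet(values, labels)


def censor(
    estimates: np.ndarray, onsets: np.ndarray, fd: np.ndarray, threshold: float = FD_CENSOR_MM
) -> np.ndarray:
    """Censored flag per trial: any in-window FD strictly above threshold.

    The comparison is strict (``>``): a frame at exactly the threshold is
    retained.
    """
    onsets = np.asarray(onsets, dtype=int)
    fd = np.asarray(fd, dtype=float)
    flags = np.zeros(onsets.size, dtype=bool)
    for k, onset in enumerate(onsets):
        window = onset + np.asarray(WINDOW_OFFSETS)
        window = window[(window >= 0) & (window < fd.size)]
        flags[k] = bool(np.any(fd[window] > threshold))
    return flags
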
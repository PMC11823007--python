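"""Spatial models: reduce each trial's vertex pattern to a scalar score.

Two linear projections are supported: the univariate (uniform-weight)
spatial mean, and a multivariate shrinkage-LDA discriminant fitted in
leave-one-session-out cross-validation over stratified undersampled
training sets.  Both consume the identical mean-pattern-centered data so
their outputs differ only through the weight vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CONDITIONS, TrialPatternSet, TrialScores

__all__ = [
    "DecoderWeights",
    "center_patterns",
    "univariate_weights",
    "shrink_covariance",
    "lda_weights",
    "undersample_splits",
    "fit_decoder_cv",
    "project",
    "decode_participant",
]

RUN_KEY = ["participant", "repetition", "session", "run"]


@dataclass
class DecoderWeights:
    """A spatial weight vector with fit provenance."""

    w: np.ndarray
    model: str                       # "univ" | "multiv"
    training_sessions: tuple[str, ...] = ()
    n_resamples: int = 0
    participant: object = None
    region: object = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.model == "univ":
            if not np.allclose(self.w, 1.0 / self.w.size):
                raise ValueError("univariate weights must all equal 1/V")
        elif self.model == "multiv":
            if abs(np.linalg.norm(self.w) - 1.0) > 1e-10:
                raise ValueError("multivariate weights must be unit length")
        else:
            raise ValueError(f"unknown model tag {self.model!r}")

    def write_csv(self, path) -> None:
        """One weight per line, provenance in '#'-prefixed header lines."""
        with open(path, "w") as fh:
            fh.write(f"# model: {self.model}\n")
            fh.write(f"# training_sessions: {','.join(self.training_sessions)}\n")
            fh.write(f"# n_resamples: {self.n_resamples}\n")
            fh.write(f"# participant: {self.participant}\n")
            for v in self.w:
                fh.write(f"{float(v)!r}\n")

    @classmethod
    def read_csv(cls, path) -> "DecoderWeights":
        meta, values = {}, []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                elif line.strip():
                    values.append(float(line))
        sessions = tuple(s for s in meta.get("training_sessions", "").split(",") if s)
        return cls(
            np.asarray(values),
            meta.get("model", "multiv"),
            training_sessions=sessions,
            n_resamples=int(meta.get("n_resamples", 0) or 0),
            participant=meta.get("participant") or None,
        )


def univariate_weights(n_vertices: int) -> DecoderWeights:
    """Uniform weights 1/V: projection equals the spatial mean."""
    if n_vertices < 1:
        raise ValueError("n_vertices must be >= 1")
    return DecoderWeights(np.full(n_vertices, 1.0 / n_vertices), "univ")


def center_patterns(patterns: TrialPatternSet) -> TrialPatternSet:
    """Mean-pattern (cocktail) centering.

    Per vertex and per run, subtracts the mean of the two condition
    means; after centering that quantity is identically zero, while the
    within-run condition contrast is untouched.
    """
    values = patterns.values.copy()
    labels = patterns.labels
    for keys, idx in labels.groupby(RUN_KEY, sort=False).groups.items():
        idx = np.asarray(idx)
        cond = labels.loc[idx, "condition"].to_numpy()
        means = []
        for c in CONDITIONS:
            rows = idx[cond == c]
            if rows.size == 0:
                raise ValueError(f"run {keys} is missing condition {c!r}; cannot center")
            means.append(values[rows].mean(axis=0))
        center = 0.5 * (means[0] + means[1])
        values[idx] -= center[None, :]
    return TrialPatternSet(values, labels.copy(), dict(patterns.meta))


def shrink_covariance(S: np.ndarray, lam: float = 0.25) -> np.ndarray:
    """Shrink off-diagonal covariance entries toward zero by a fixed amount.

    The diagonal is unchanged; every off-diagonal entry is multiplied by
    ``1 - lam`` (lam = 0.25 shrinks by 25%).
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T):
        raise ValueError("covariance must be symmetric")
    if not 0 <= lam <= 1:
        raise ValueError("shrinkage lambda must lie in [0, 1]")
    out = (1.0 - lam) * S
    np.fill_diagonal(out, np.diag(S))
    return out


def _class_stats(X: np.ndarray, cond: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean difference (incon - congr) and equal-weight average of the two
    within-condition sample covariances (n-1 denominator)."""
    covs, means = [], {}
    for c in CONDITIONS:
        Xc = X[cond == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"need >= 2 trials of condition {c!r} to fit LDA")
        means[c] = Xc.mean(axis=0)
        covs.append(np.cov(Xc, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1]))
    mdiff = means["incon"] - means["congr"]
    return mdiff, 0.5 * (covs[0] + covs[1])


def lda_weights(
    train: TrialPatternSet, lam: float = 0.25, allow_pinv: bool = False
) -> DecoderWeights:
    """Shrinkage-LDA discriminant: w proportional to S_shrunk^-1 (mean diff),
    normalized to unit Euclidean length, signed so the incongruent mean
    projects above the congruent mean."""
    cond = train.labels["condition"].to_numpy()
    mdiff, S = _class_stats(train.values, cond)
    if np.allclose(mdiff, 0):
        raise ValueError("identical class means: the discriminant is zero")
    S_shrunk = shrink_covariance(S, lam)
    try:
        w = np.linalg.solve(S_shrunk, mdiff)
    except np.linalg.LinAlgError:
        if not allow_pinv:
            raise np.linalg.LinAlgError(
                "singular shrunken covariance; increase lambda or pass allow_pinv=True"
            )
        w = np.linalg.pinv(S_shrunk) @ mdiff
    norm = np.linalg.norm(w)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("degenerate discriminant (zero or non-finite norm)")
    w = w / norm
    if float(w @ mdiff) < 0:
        w = -w
    return DecoderWeights(w, "multiv")


def undersample_splits(
    labels: pd.DataFrame, n_subsets: int = 100, seed: int = 0
) -> list[np.ndarray]:
    """Stratified random undersampling subsets of trial row indices.

    Strata are (condition, word) cells within each run; per subset, k
    trials are drawn without replacement from every cell, with k the
    minimum cell count in that run.  For congruent trials word == color,
    so color balance is exact there and approximate (via the generator's
    round-robin assignment) for incongruent trials.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels = labels.reset_index(drop=True)
    run_groups = labels.groupby(RUN_KEY, sort=True).groups
    per_run_cells: list[tuple[np.ndarray, int]] = []
    for run_key, idx in run_groups.items():
        idx = np.asarray(idx)
        sub = labels.loc[idx]
        for c in CONDITIONS:
            if not (sub["condition"] == c).any():
                raise ValueError(f"run {run_key} has no {c!r} trials")
        cells = sub.groupby(["condition", "word"], sort=True).groups
        # every condition x word cell must be populated
        for c in CONDITIONS:
            present = {w for (cc, w) in cells if cc == c}
            missing = set(range(8)) - present
            if missing:
                raise ValueError(
                    f"run {run_key}, condition {c!r}: empty word cells {sorted(missing)}"
                )
        k = min(len(rows) for rows in cells.values())
        per_run_cells.append(
            ([np.asarray(rows) for rows in cells.values()], k)
        )

    subsets = []
    for _ in range(n_subsets):
        take = []
        for cells, k in per_run_cells:
            for rows in cells:
                take.append(rng.choice(rows, size=k, replace=False))
        subsets.append(np.sort(np.concatenate(take)))
    return subsets


def fit_decoder_cv(
    patterns: TrialPatternSet,
    held_out_session: str,
    lam: float = 0.25,
    n_subsets: int = 100,
    seed: int = 0,
) -> DecoderWeights:
    """Leave-one-session-out LDA for one participant.

    Training data are the concatenated trials of the two non-held-out
    sessions (both repetitions, both runs), mean-pattern centered; LDA is
    fit on ``n_subsets`` stratified undersampled subsets, the weight
    vectors are averaged element-wise and renormalized to unit length.
    """
    participants = patterns.labels["participant"].unique()
    if participants.size != 1:
        raise ValueError("fit_decoder_cv expects a single participant's patterns")
    sessions = [s for s in patterns.labels["session"].unique() if s != held_out_session]
    if len(sessions) < 2:
        raise ValueError(
            f"need >= 2 training sessions besides {held_out_session!r}, found {sessions}"
        )
    train = patterns.select(
        patterns.labels["session"].isin(sessions).to_numpy()
    ).uncensored()
    train = center_patterns(train)
    subsets = undersample_splits(train.labels, n_subsets=n_subsets, seed=seed)

    ws = []
    failures = 0
    for rows in subsets:
        try:
            ws.append(lda_weights(train.select(rows), lam=lam).w)
        except (ValueError, np.linalg.LinAlgError) as err:
            failures += 1
            if failures > n_subsets // 2:
                raise RuntimeError(
                    f"more than half of the {n_subsets} undersampled LDA fits failed; "
                    f"last error: {err}"
                ) from err
    if failures:
        warnings.warn(f"{failures}/{n_subsets} undersampled LDA fits failed and were skipped")
    w = np.mean(ws, axis=0)
    w = w / np.linalg.norm(w)
    return DecoderWeights(
        w,
        "multiv",
        training_sessions=tuple(sorted(sessions)),
        n_resamples=len(ws),
        participant=participants[0],
    )


def project(patterns: TrialPatternSet, weights: DecoderWeights) -> TrialScores:
    """Scores y = X w for the uncensored trials, labels carried through."""
    if patterns.n_vertices != weights.w.size:
        raise ValueError(
            f"vertex mismatch: patterns have {patterns.n_vertices}, weights {weights.w.size}"
        )
    kept = patterns.uncensored()
    table = kept.labels[
        ["participant", "repetition", "session", "run", "condition", "trial", "word", "color"]
    ].copy()
    table["model"] = weights.model
    table["score"] = kept.values @ weights.w
    return TrialScores(table)


def decode_participant(
    patterns: TrialPatternSet,
    lam: float = 0.25,
    n_subsets: int = 100,
    seed: int = 0,
) -> TrialScores:
    """Univariate and cross-validated multivariate scores for one participant.

    Both projections consume the identical centered patterns.  The
    multivariate score for each session uses weights trained on the other
    two sessions; the univariate projection needs no training.
    """
    centered = center_patterns(patterns)
    univ = project(centered, univariate_weights(patterns.n_vertices))

    pieces = []
    rng = np.random.default_rng(seed)
    for session in sorted(centered.labels["session"].unique()):
        w = fit_decoder_cv(
            patterns,
            held_out_session=session,
            lam=lam,
            n_subsets=n_subsets,
            seed=int(rng.integers(2**31 - 1)),
        )
        mask = (centered.labels["session"] == session).to_numpy()
        pieces.append(project(centered.select(mask), w).table)
    multiv = pd.concat(pieces, ignore_index=True)
    return TrialScores(pd.concat([univ.table, multiv], ignore_index=True))
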
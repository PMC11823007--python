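"""Summary-statistic reliability: trial-averaged Stroop contrasts and ICC(3,1).

The consistency-form intraclass correlation of a two-way model equals
the Pearson correlation, across participants, between the test and
retest Stroop contrasts; it is computed that way here (exact and
dependency-free), with the variance-decomposition reading
(xi^2, sigma^2) reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import TrialScores

__all__ = ["StroopSummary", "ICCResult", "stroop_contrast", "icc31"]


@dataclass
class StroopSummary:
    """Per (participant, repetition) Stroop contrast and trial counts."""

    table: pd.DataFrame  # columns: participant, repetition, stroop, n_incon, n_congr

    def wide(self) -> pd.DataFrame:
        """participants x {test, retest} matrix of Stroop contrasts."""
        return self.table.pivot(index="participant", columns="repetition", values="stroop")


def stroop_contrast(
    scores: TrialScores, session_filter: str | list[str] | None = "baseline"
) -> StroopSummary:
    """Mean(incon) - mean(congr) per participant and repetition.

    Scores are filtered to ``session_filter`` first (the reliability
    analyses scope to the baseline session); participants missing a
    repetition are excluded with a warning.
    """
    df = scores.table
    if session_filter is not None:
        sessions = (
            [session_filter] if isinstance(session_filter, str) else list(session_filter)
        )
        df = df[df["session"].isin(sessions)]
        if df.empty:
            raise ValueError(f"no scores left after session filter {session_filter!r}")

    rows = []
    for (p, r), sub in df.groupby(["participant", "repetition"], sort=True):
        incon = sub.loc[sub["condition"] == "incon", "score"]
        congr = sub.loc[sub["condition"] == "congr", "score"]
        if incon.empty or congr.empty:
            raise ValueError(
                f"participant {p}, repetition {r}: a condition is absent after filtering"
            )
        rows.append((p, r, incon.mean() - congr.mean(), len(incon), len(congr)))
    table = pd.DataFrame(
        rows, columns=["participant", "repetition", "stroop", "n_incon", "n_congr"]
    )
    counts = table.groupby("participant")["repetition"].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete:
        warnings.warn(f"excluding participants missing a repetition: {incomplete}")
        table = table[~table["participant"].isin(incomplete)].reset_index(drop=True)
    return StroopSummary(table)


@dataclass
class ICCResult:
    """ICC(3,1) with its variance-decomposition reading."""

    icc: float
    xi2: float          # cross-repetition covariance of Stroop effects
    sigma2: float       # residual variance (mean within-rep variance minus xi2)
    n_participants: int
    degenerate: bool = False

    def __float__(self) -> float:
        return self.icc


def icc31(summary: StroopSummary) -> ICCResult:
    """Consistency ICC(3,1) = Pearson correlation of test vs retest contrasts.

    Degenerate inputs (zero variance in either repetition) return NaN
    with an explicit flag rather than raising.
    """
    wide = summary.wide()
    for rep in ("test", "retest"):
        if rep not in wide.columns:
            raise ValueError(f"summary lacks the {rep!r} repetition")
    wide = wide.dropna()
    n = len(wide)
    if n < 3:
        raise ValueError(f"need >= 3 participants with both repetitions, have {n}")
    x = wide["test"].to_numpy(dtype=float)
    y = wide["retest"].to_numpy(dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    cov = np.cov(x, y, ddof=1)[0, 1]
    if vx == 0 or vy == 0:
        return ICCResult(np.nan, cov, 0.5 * (vx + vy) - cov, n, degenerate=True)
    icc = cov / np.sqrt(vx * vy)
    sigma2 = 0.5 * (vx + vy) - cov
    return ICCResult(float(icc), float(cov), float(sigma2), n)
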
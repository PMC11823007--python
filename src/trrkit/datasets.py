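"""Core in-memory containers and their delimited-text serializations.

A :class:`TrialPatternSet` pairs a trials x vertices activation matrix
(percent signal change) with a full factor-label table; a
:class:`TrialScores` table holds one scalar projection per uncensored
trial.  Both round-trip through plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LABEL_COLUMNS", "TrialPatternSet", "TrialScores"]

LABEL_COLUMNS = [
    "participant",
    "repetition",
    "session",
    "run",
    "condition",
    "trial",
    "word",
    "color",
    "censored",
]

CONDITIONS = ("incon", "congr")
REPETITIONS = ("test", "retest")
SESSIONS = ("baseline", "proactive", "reactive")


@dataclass
class TrialPatternSet:
    """Trial x vertex activation patterns with factor labels.

    ``values`` has one row per trial; ``labels`` carries the columns in
    :data:`LABEL_COLUMNS` aligned row-for-row with ``values``.
    """

    values: np.ndarray
    labels: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D trials x vertices array")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"labels ({len(self.labels)}) and values ({self.values.shape[0]}) disagree"
            )
        missing = set(LABEL_COLUMNS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"labels missing columns: {sorted(missing)}")
        self.labels = self.labels.reset_index(drop=True)
        uncensored = ~self.labels["censored"].to_numpy(dtype=bool)
        if np.any(~np.isfinite(self.values[uncensored])):
            raise ValueError("missing values among uncensored trials")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def select(self, mask: np.ndarray) -> "TrialPatternSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return TrialPatternSet(
            self.values[idx], self.labels.iloc[idx].reset_index(drop=True), dict(self.meta)
        )

    def uncensored(self) -> "TrialPatternSet":
        return self.select(~self.labels["censored"].to_numpy(dtype=bool))

    # -- serialization: wide dialect (one row per trial, v0..v{V-1} columns)
    def to_frame(self) -> pd.DataFrame:
        wide = pd.DataFrame(
            self.values, columns=[f"v{i}" for i in range(self.n_vertices)]
        )
        return pd.concat([self.labels.reset_index(drop=True), wide], axis=1)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        header_meta = {"seed": self.meta.get("seed", "")}
        with open(path, "w") as fh:
            for k, v in header_meta.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrialPatternSet":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        vcols = sorted(vcols, key=lambda c: int(c[1:]))
        return cls(df[vcols].to_numpy(float), df[LABEL_COLUMNS], meta)

    # -- serialization: long dialect (one row per trial x vertex)
    def to_long(self) -> pd.DataFrame:
        frame = self.to_frame()
        return frame.melt(
            id_vars=LABEL_COLUMNS,
            var_name="vertex",
            value_name="value",
        ).assign(vertex=lambda d: d["vertex"].str[1:].astype(int))

    @classmethod
    def from_long(cls, df: pd.DataFrame, meta: dict | None = None) -> "TrialPatternSet":
        wide = df.pivot(
            index=LABEL_COLUMNS, columns="vertex", values="value"
        ).sort_index(axis=1)
        labels = wide.index.to_frame(index=False)
        return cls(wide.to_numpy(float), labels, meta or {})


@dataclass
class TrialScores:
    """Scalar projection per trial with factor labels and a model tag.

    The table holds one row per *uncensored* trial; censored trials are
    dropped at projection time.
    """

    table: pd.DataFrame

    REQUIRED = [
        "participant",
        "repetition",
        "session",
        "run",
        "condition",
        "trial",
        "model",
        "score",
    ]

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"scores table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    def filter(self, **levels) -> "TrialScores":
        df = self.table
        for col, val in levels.items():
            allowed = val if isinstance(val, (list, tuple, set)) else [val]
            df = df[df[col].isin(allowed)]
        return TrialScores(df.reset_index(drop=True))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrialScores":
        return cls(pd.read_csv(path))
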
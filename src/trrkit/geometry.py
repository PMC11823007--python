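"""Noise geometry: the spectrum of trial-level variability and each
contrast's susceptibility to it.

Within-condition-centered trials are pooled across conditions and
eigendecomposed; the resulting dimensions (in SD units) are related to
the univariate and multivariate weight vectors through squared-cosine
alignments, and summarized as a susceptibility (alignment-weighted sum
of dimension SDs) whose univariate/multivariate log-ratio is positive
when the uniform contrast is more exposed to trial noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import CONDITIONS, TrialPatternSet
from .decoding import DecoderWeights

__all__ = [
    "NoiseSpectrum",
    "noise_pca",
    "alignment",
    "susceptibility",
    "susceptibility_log_ratio",
    "plot_spectrum",
]


@dataclass
class NoiseSpectrum:
    """Eigen-SDs (descending) and eigenvectors of trial-noise covariance."""

    sds: np.ndarray            # (V,) sorted descending, score units
    eigvecs: np.ndarray        # (V, V), column d pairs with sds[d]
    n_trials: int = 0
    participant: object = None
    region: object = None
    alignments: dict = field(default_factory=dict)   # model tag -> (V,) squared cos

    @property
    def n_dims(self) -> int:
        return self.sds.size


def noise_pca(patterns: TrialPatternSet) -> NoiseSpectrum:
    """Spectrum of the pooled within-condition trial covariance.

    Trials are centered at their own condition's mean (removing the
    condition contrast), pooled, and eigendecomposed; SDs are square
    roots of eigenvalues.  Rank deficiency yields trailing zero SDs.
    """
    kept = patterns.uncensored()
    cond = kept.labels["condition"].to_numpy()
    centered = []
    for c in CONDITIONS:
        Xc = kept.values[cond == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"need >= 2 trials of condition {c!r} for the noise spectrum")
        centered.append(Xc - Xc.mean(axis=0, keepdims=True))
    pooled = np.concatenate(centered, axis=0)
    # pooled within-condition covariance: one mean per condition is removed
    cov = pooled.T @ pooled / (pooled.shape[0] - len(CONDITIONS))
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    return NoiseSpectrum(
        sds=np.sqrt(eigvals),
        eigvecs=eigvecs[:, order],
        n_trials=pooled.shape[0],
        participant=_single(kept.labels["participant"]),
    )


def _single(series):
    vals = series.unique()
    return vals[0] if len(vals) == 1 else None


def _weight_vector(w) -> np.ndarray:
    vec = w.w if isinstance(w, DecoderWeights) else np.asarray(w, dtype=float)
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValueError("zero weight vector has no direction")
    return vec / norm


def alignment(spectrum: NoiseSpectrum, w) -> np.ndarray:
    """Squared cosine of each noise eigenvector with the weight direction.

    The eigenvectors form an orthonormal basis, so the alignments sum to
    one for any weight vector (Parseval).
    """
    vec = _weight_vector(w)
    if vec.size != spectrum.n_dims:
        raise ValueError("dimension mismatch between spectrum and weights")
    a = (spectrum.eigvecs.T @ vec) ** 2
    if isinstance(w, DecoderWeights):
        spectrum.alignments[w.model] = a
    return a


def susceptibility(spectrum: NoiseSpectrum, w) -> float:
    """Total trial-level SD along a weight direction: sum_d SD_d * alignment_d.

    Note this alignment-weighted *sum of SDs* is not sqrt(w' Cov w)/|w|
    except in the single-spike limit; the summed form is the contract.
    """
    a = alignment(spectrum, w)
    return float(np.sum(spectrum.sds * a))


def plot_spectrum(spectrum: NoiseSpectrum, ax=None, max_dims: int | None = 20):
    """Dimension/SD/alignment chart: eigen-SDs on the left axis, squared-
    cosine alignments of each registered weight vector on the right."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    d = spectrum.n_dims if max_dims is None else min(max_dims, spectrum.n_dims)
    dims = np.arange(1, d + 1)
    ax.plot(dims, spectrum.sds[:d], "ko-", label="trial-level SD")
    ax.set_xlabel("noise dimension (ranked)")
    ax.set_ylabel("SD (score units)")
    ax2 = ax.twinx()
    colors = {"univ": "navy", "multiv": "deepskyblue"}
    for tag, a in spectrum.alignments.items():
        ax2.plot(dims, a[:d], "o--", color=colors.get(tag, None), label=f"alignment {tag}")
    ax2.set_ylabel("alignment (squared cosine)")
    ax2.set_ylim(0, 1)
    handles, labels = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(handles + h2, labels + l2, loc="upper right", fontsize=8)
    return ax


def susceptibility_log_ratio(spectrum: NoiseSpectrum, w_univ, w_multiv) -> float:
    """ln(susceptibility_univ / susceptibility_multiv); positive when the
    univariate contrast is more exposed to trial-level variability."""
    s_u = susceptibility(spectrum, w_univ)
    s_m = susceptibility(spectrum, w_multiv)
    if s_m == 0:
        return float(np.inf) if s_u > 0 else float(np.nan)
    return float(np.log(s_u / s_m))
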
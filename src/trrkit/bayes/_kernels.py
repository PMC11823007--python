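"""Fused per-trial likelihood/gradient kernels.

The Student-t trial likelihood and its gradients w.r.t. the per-cell
location and log-scale are the sampler's hot loop (evaluated tens of
thousands of times per fit).  A numba-compiled kernel fuses the
per-trial arithmetic and the scatter-add into participant x cell bins;
a vectorized numpy fallback keeps the package functional without numba.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _t_core_numba(y, idx_pc, loc_flat, eta_flat, df, gaussian, want_ddf, n_bins):
    """Returns (sum of shape-dependent loglik terms, G_alpha, G_eta, ddf_sum).

    The df-dependent normalizing constant is added by the caller (it does
    not vary across trials).  ``gaussian`` selects the df -> inf limit;
    ``df`` must then be an arbitrary finite placeholder (fastmath forbids
    non-finite operands).
    """
    n = y.size
    g_alpha = np.zeros(n_bins)
    g_eta = np.zeros(n_bins)
    lp = 0.0
    ddf = 0.0
    inv_scale_flat = np.exp(-eta_flat)  # only P*4 distinct scales
    for t in range(n):
        k = idx_pc[t]
        eta = eta_flat[k]
        inv_scale = inv_scale_flat[k]
        r = (y[t] - loc_flat[k]) * inv_scale
        q = r * r
        if gaussian:
            lp += -eta - 0.5 * q
            g_alpha[k] += r * inv_scale
            g_eta[k] += -1.0 + q
        else:
            l1 = np.log1p(q / df)
            lp += -eta - 0.5 * (df + 1.0) * l1
            denom = df + q
            g_alpha[k] += (df + 1.0) * r * inv_scale / denom
            g_eta[k] += -1.0 + (df + 1.0) * q / denom
            if want_ddf:
                ddf += -0.5 * l1 + (df + 1.0) * q / (2.0 * df * denom)
    return lp, g_alpha, g_eta, ddf


def _t_core_numpy(y, idx_pc, loc_flat, eta_flat, df, want_ddf, n_bins):
    eta = eta_flat[idx_pc]
    inv_scale = np.exp(-eta)
    r = (y - loc_flat[idx_pc]) * inv_scale
    q = r * r
    if not np.isfinite(df):
        lp = float(np.sum(-eta - 0.5 * q))
        dloc = r * inv_scale
        deta = -1.0 + q
        ddf = 0.0
    else:
        l1 = np.log1p(q / df)
        lp = float(np.sum(-eta - 0.5 * (df + 1.0) * l1))
        denom = df + q
        dloc = (df + 1.0) * r * inv_scale / denom
        deta = -1.0 + (df + 1.0) * q / denom
        ddf = (
            float(np.sum(-0.5 * l1 + (df + 1.0) * q / (2.0 * df * denom)))
            if want_ddf
            else 0.0
        )
    g_alpha = np.bincount(idx_pc, weights=dloc, minlength=n_bins)
    g_eta = np.bincount(idx_pc, weights=deta, minlength=n_bins)
    return lp, g_alpha, g_eta, ddf


def t_likelihood_core(y, idx_pc, loc_flat, eta_flat, df, want_ddf, n_bins):
    if HAVE_NUMBA:
        gaussian = not np.isfinite(df)
        return _t_core_numba(
            y, idx_pc, loc_flat, eta_flat,
            1.0 if gaussian else float(df), gaussian, want_ddf, n_bins,
        )
    return _t_core_numpy(y, idx_pc, loc_flat, eta_flat, float(df), want_ddf, n_bins)
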
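"""Model comparison by Pareto-smoothed importance-sampling LOO.

Thin wrapper over arviz's PSIS-LOO: expected log pointwise predictive
density (elpd) with standard errors per model, pairwise elpd differences
with difference SEs, and Pareto-k diagnostics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["compare_models_loo"]


def _loo_pointwise(model, samples) -> tuple[float, float, np.ndarray, float]:
    """(elpd, se, pointwise elpd, fraction of pareto k > 0.7)."""
    import arviz as az

    ll = samples.pointwise_loglik()  # (chain, draw, n)
    idata = az.from_dict(
        posterior={"lp": samples.theta[..., 0]},
        log_likelihood={"y": ll},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    pointwise = np.asarray(res.loo_i.values)
    k = np.asarray(res.pareto_k.values)
    return float(res.elpd_loo), float(res.se), pointwise, float(np.mean(k > 0.7))


def compare_models_loo(fits: list[tuple[str, object, object]]) -> pd.DataFrame:
    """elpd table for named fits of the *same* trial scores.

    ``fits`` is a list of (name, model, samples).  Returns one row per
    model with columns elpd, se, high_pareto_k_frac, and -- relative to
    the elpd-best model -- elpd_diff and diff_se (SE of the paired
    pointwise differences).  Raises if the fits were not computed on an
    identical trial set.
    """
    if not fits:
        raise ValueError("no fits supplied")
    y0 = fits[0][1].y
    for name, model, _ in fits[1:]:
        if model.n != len(y0) or not np.allclose(model.y, y0):
            raise ValueError(f"fit {name!r} was computed on a different trial set")

    rows = {}
    pointwise = {}
    for name, model, samples in fits:
        elpd, se, pw, k_frac = _loo_pointwise(model, samples)
        rows[name] = {"elpd": elpd, "se": se, "high_pareto_k_frac": k_frac}
        pointwise[name] = pw
        if k_frac > 0:
            warnings.warn(
                f"model {name!r}: {k_frac:.1%} of Pareto-k diagnostics exceed 0.7"
            )

    best = max(rows, key=lambda n: rows[n]["elpd"])
    n_obs = len(y0)
    for name in rows:
        d = pointwise[best] - pointwise[name]
        rows[name]["elpd_diff"] = float(np.sum(d))
        rows[name]["diff_se"] = float(np.sqrt(n_obs * np.var(d)))
    table = pd.DataFrame(rows).T
    table.index.name = "model"
    return table.sort_values("elpd", ascending=False)
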
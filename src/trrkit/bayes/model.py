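"""Hierarchical Bayesian location-scale Student-t models of trial scores.

Trial scores ``y`` (one scalar per trial, labelled by participant,
repetition and condition) are modelled as

    y ~ StudentT(df, alpha[p, cell], exp(eta[p, cell]))

where ``cell`` indexes the four condition x repetition combinations,
``alpha = A (m + mu_p)`` and ``eta = B (g + tau_p)`` are linear maps of
population fixed effects (m, g) plus per-participant random effects
(mu, tau).  Four random-effect covariance structures are supported:

- ``full``     flat condition coding; one 8-dim MVN over (mu, tau).
- ``ils``      flat coding; independent 4-dim MVNs for mu and tau
               (independent location and scale).
- ``ils_sym``  contrast (mean/stroop) coding; independent 2-dim MVNs
               per component for mu and tau (symmetric across
               repetitions); the test-retest correlation of the Stroop
               effect is the correlation of the location-stroop block.
- ``homog``    contrast coding for the location; a single residual
               scale parameter gamma (no tau).

Random effects use a non-centered parameterization: effects =
diag(sd) @ L_corr @ z with z ~ N(0, I), which removes the funnel
geometry at small group SDs.  All gradients are analytic and are
validated against finite differences and a brute-force log-density
oracle in the tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import special

from ._kernels import t_likelihood_core
from .transforms import (
    chol_from_cpc,
    chol_from_cpc_backward,
    lkj_cpc_exponents,
    n_cpc,
)

__all__ = ["MCMCSettings", "HierarchicalModelSpec", "HierarchicalModel", "build_model"]

#: canonical cell order: (condition, repetition)
CELLS = [("incon", "test"), ("congr", "test"), ("incon", "retest"), ("congr", "retest")]

#: contrast-coded fixed/random effect order for location & scale
CONTRAST_TERMS = ["mean_test", "stroop_test", "mean_retest", "stroop_retest"]

# cell value = mean_r + (+1/2 | -1/2) stroop_r  (incon = +)
_A_CONTRAST = np.array(
    [
        [1.0, 0.5, 0.0, 0.0],
        [1.0, -0.5, 0.0, 0.0],
        [0.0, 0.0, 1.0, 0.5],
        [0.0, 0.0, 1.0, -0.5],
    ]
)

# effect-vector order used for ils_sym blocks: (mean_test, mean_retest,
# stroop_test, stroop_retest) -- grouped so each 2x2 repetition block is
# contiguous.  Maps onto cells:
_A_CONTRAST_EFF = np.array(
    [
        [1.0, 0.0, 0.5, 0.0],
        [1.0, 0.0, -0.5, 0.0],
        [0.0, 1.0, 0.0, 0.5],
        [0.0, 1.0, 0.0, -0.5],
    ]
)

SYM_EFF_TERMS = ["mean_test", "mean_retest", "stroop_test", "stroop_retest"]

STRUCTURES = ("full", "ils", "ils_sym", "homog")


@dataclass
class MCMCSettings:
    """Sampler settings; defaults mirror the 4 x 2000 (1000 warmup) contract."""

    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int = 1000
    seed: int = 0
    max_treedepth: int = 8
    target_accept: float = 0.8

    @property
    def n_draws(self) -> int:
        return self.n_iter - self.n_warmup


@dataclass
class HierarchicalModelSpec:
    """Structure, priors and sampler settings for one reliability model."""

    structure: str = "ils_sym"
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    # priors (scales multiplying the data SD where noted)
    prior_m_scale: float = 10.0        # x data SD, normal(0, .)
    prior_g_scale: float = 10.0        # log-scale fixed effects, normal(log sd_y, .)
    prior_sd_loc_scale: float = 2.5    # x data SD, half-t(3, 0, .)
    prior_sd_scale_scale: float = 2.5  # log-scale effect SDs, half-t(3, 0, .)
    lkj_eta: float = 1.0
    df_prior_shape: float = 2.0
    df_prior_rate: float = 0.1
    df_fixed: float | None = None      # fix the t df; np.inf => Gaussian
    # testing-oriented reductions
    random_effects: bool = True
    likelihood: bool = True

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; choose from {STRUCTURES}")

    @property
    def coding(self) -> str:
        return "flat" if self.structure in ("full", "ils") else "contrast"


def _blocks_for(structure: str) -> tuple[int, list[np.ndarray], list[str]]:
    """Effect-vector dimension K, covariance block index sets, block names."""
    if structure == "full":
        return 8, [np.arange(8)], ["mu_tau"]
    if structure == "ils":
        return 8, [np.arange(4), np.arange(4, 8)], ["mu", "tau"]
    if structure == "ils_sym":
        return (
            8,
            [np.array([0, 1]), np.array([2, 3]), np.array([4, 5]), np.array([6, 7])],
            ["mu_mean", "mu_stroop", "tau_mean", "tau_stroop"],
        )
    if structure == "homog":
        return 4, [np.array([0, 1]), np.array([2, 3])], ["mu_mean", "mu_stroop"]
    raise ValueError(structure)


class HierarchicalModel:
    """A fully specified joint density over trial scores.

    Exposes a constrained-space :meth:`log_density` for oracle checks and
    an unconstrained :meth:`logp_and_grad` used by the NUTS sampler.
    """

    def __init__(self, spec: HierarchicalModelSpec, scores: pd.DataFrame):
        required = {"participant", "repetition", "condition", "score"}
        missing = required - set(scores.columns)
        if missing:
            raise ValueError(f"scores table missing columns: {sorted(missing)}")
        reps = set(scores["repetition"].unique())
        if spec.likelihood and reps != {"test", "retest"}:
            raise ValueError(f"both repetitions required, got {sorted(reps)}")
        if "model" in scores.columns and scores["model"].nunique() > 1:
            raise ValueError("scores mix several spatial-model tags; fit one at a time")

        self.spec = spec
        self.structure = spec.structure
        self.y = scores["score"].to_numpy(dtype=float)
        self.n = self.y.size

        participants = np.sort(scores["participant"].unique())
        self.participants = participants
        self.P = participants.size
        p_index = {p: i for i, p in enumerate(participants)}
        self.idx_p = scores["participant"].map(p_index).to_numpy(dtype=np.intp)
        cell_index = {cr: i for i, cr in enumerate(CELLS)}
        self.idx_cell = np.array(
            [cell_index[(c, r)] for c, r in zip(scores["condition"], scores["repetition"])],
            dtype=np.intp,
        )
        if np.any(pd.isna(self.y)):
            raise ValueError("scores contain missing values")
        self.idx_pc = (self.idx_p * 4 + self.idx_cell).astype(np.int64)  # (participant, cell)

        # ---- design -----------------------------------------------------
        flat = spec.coding == "flat"
        self.A_fix = np.eye(4) if flat else _A_CONTRAST
        self.m_names = (
            [f"m[{c},{r}]" for c, r in CELLS]
            if flat
            else [f"m[{t}]" for t in CONTRAST_TERMS]
        )
        if self.structure == "homog":
            self.B_fix = np.ones((4, 1))
            self.g_names = ["gamma"]
        else:
            self.B_fix = self.A_fix
            self.g_names = (
                [f"gamma[{c},{r}]" for c, r in CELLS]
                if flat
                else [f"gamma[{t}]" for t in CONTRAST_TERMS]
            )
        self.n_m = 4
        self.n_g = self.B_fix.shape[1]

        self.K, self.blocks, self.block_names = _blocks_for(self.structure)
        if not spec.random_effects:
            self.K, self.blocks, self.block_names = 0, [], []
        # effect -> cell maps (location part, scale part)
        if self.structure in ("full", "ils"):
            self.A_eff_loc = np.eye(4)      # e[0:4] are mu cells
            self.A_eff_sc = np.eye(4)       # e[4:8] are tau cells
            self.loc_sl = slice(0, 4)
            self.sc_sl = slice(4, 8)
            self.eff_names = [f"mu[{c},{r}]" for c, r in CELLS] + [
                f"tau[{c},{r}]" for c, r in CELLS
            ]
        elif self.structure == "ils_sym":
            self.A_eff_loc = _A_CONTRAST_EFF
            self.A_eff_sc = _A_CONTRAST_EFF
            self.loc_sl = slice(0, 4)
            self.sc_sl = slice(4, 8)
            self.eff_names = [f"mu[{t}]" for t in SYM_EFF_TERMS] + [
                f"tau[{t}]" for t in SYM_EFF_TERMS
            ]
        else:  # homog: location effects only
            self.A_eff_loc = _A_CONTRAST_EFF
            self.A_eff_sc = None
            self.loc_sl = slice(0, 4)
            self.sc_sl = None
            self.eff_names = [f"mu[{t}]" for t in SYM_EFF_TERMS]

        if not spec.random_effects:
            self.eff_names = []
        self.sd_names = [f"sd_{n}" for n in self.eff_names]
        self.cpc_per_block = [n_cpc(len(b)) for b in self.blocks]
        self.n_cpc_total = int(sum(self.cpc_per_block))
        self.lkj_b = [lkj_cpc_exponents(len(b), spec.lkj_eta) for b in self.blocks]
        self.sample_df = spec.df_fixed is None

        # all-2x2 contiguous blocks (ils_sym, homog) admit a batched fast path
        self._blocks_2x2 = bool(self.blocks) and all(
            len(b) == 2 and b[1] == b[0] + 1 for b in self.blocks
        ) and self.K == 2 * len(self.blocks)

        # data-derived prior scales
        sd_y = float(np.std(self.y)) if self.n > 1 else 1.0
        self.sd_y = sd_y if sd_y > 0 else 1.0
        self.m_prior_sd = spec.prior_m_scale * self.sd_y
        self.g_prior_loc = float(np.log(self.sd_y))
        self.g_prior_sd = spec.prior_g_scale
        self.sd_prior_scale = np.array(
            [
                spec.prior_sd_loc_scale * self.sd_y
                if name.startswith("mu")
                else spec.prior_sd_scale_scale
                for name in self.eff_names
            ]
        )

        # ---- unconstrained layout ---------------------------------------
        sizes = {
            "m": self.n_m,
            "g": self.n_g,
            "log_sd": self.K,
            "cpc": self.n_cpc_total,
            "u_df": 1 if self.sample_df else 0,
            "z": self.P * self.K,
        }
        self.slices: dict[str, slice] = {}
        off = 0
        for name, sz in sizes.items():
            self.slices[name] = slice(off, off + sz)
            off += sz
        self.n_free = off

    # ------------------------------------------------------------------
    # manifests
    # ------------------------------------------------------------------
    @property
    def parameter_manifest(self) -> list[str]:
        """Named population-level parameters (excludes per-participant effects)."""
        names = list(self.m_names) + list(self.g_names) + list(self.sd_names)
        for bname, nc in zip(self.block_names, self.cpc_per_block):
            if nc == 1:
                names.append(f"corr_{bname}")
            else:
                names.extend(f"cpc_{bname}[{k}]" for k in range(nc))
        if self.sample_df:
            names.append("df")
        return names

    @property
    def scale_parameter_names(self) -> list[str]:
        """Residual-scale population parameters (the gamma manifest)."""
        return list(self.g_names)

    # ------------------------------------------------------------------
    # constrained-space density (oracle-facing)
    # ------------------------------------------------------------------
    def log_density(self, params: dict) -> float:
        """Joint log prior + log likelihood at named constrained values.

        Expected keys: ``m`` (4,), ``g`` (n_g,), ``sd`` (K,), per-block
        correlation matrices in ``corr`` (list, aligned with
        ``block_names``), ``df`` (scalar, may be inf), and per-participant
        effects ``effects`` (P, K).  Out-of-support values return -inf.
        """
        m = np.asarray(params["m"], dtype=float)
        g = np.atleast_1d(np.asarray(params["g"], dtype=float))
        df = float(params.get("df", self.spec.df_fixed if self.spec.df_fixed else np.inf))
        sd = np.asarray(params.get("sd", np.zeros(self.K)), dtype=float)
        effects = np.asarray(params.get("effects", np.zeros((self.P, self.K))), dtype=float)
        corrs = params.get("corr", [np.eye(len(b)) for b in self.blocks])

        if df < 1 or np.any(sd < 0):
            return -np.inf

        lp = 0.0
        # priors
        lp += float(np.sum(_normal_logpdf(m, 0.0, self.m_prior_sd)))
        lp += float(np.sum(_normal_logpdf(g, self.g_prior_loc, self.g_prior_sd)))
        if self.K:
            if np.any(sd == 0):
                return -np.inf
            lp += float(np.sum(_half_t_logpdf(sd, self.sd_prior_scale)))
            for b_idx, (bidx, R) in enumerate(zip(self.blocks, corrs)):
                R = np.asarray(R, dtype=float)
                d = len(bidx)
                sign, logdet = np.linalg.slogdet(R)
                if sign <= 0:
                    return -np.inf
                lp += (self.spec.lkj_eta - 1.0) * logdet  # LKJ(eta), unnormalized
                cov = R * np.outer(sd[bidx], sd[bidx])
                try:
                    lp += float(np.sum(_mvn_logpdf(effects[:, bidx], cov)))
                except np.linalg.LinAlgError:
                    return -np.inf
        if self.sample_df:
            if not np.isfinite(df):
                return -np.inf
            lp += (self.spec.df_prior_shape - 1.0) * np.log(df) - self.spec.df_prior_rate * df
        # likelihood
        if self.spec.likelihood:
            alpha = (m @ self.A_fix.T)[None, :] + (
                effects[:, self.loc_sl] @ self.A_eff_loc.T if self.K else 0.0
            )
            eta = (g @ self.B_fix.T)[None, :]
            if self.K and self.sc_sl is not None:
                eta = eta + effects[:, self.sc_sl] @ self.A_eff_sc.T
            alpha = np.broadcast_to(alpha, (self.P, 4)).reshape(-1)[self.idx_pc]
            eta = np.broadcast_to(eta, (self.P, 4)).reshape(-1)[self.idx_pc]
            lp += float(np.sum(_t_logpdf(self.y, df, alpha, np.exp(eta))))
        return lp

    # ------------------------------------------------------------------
    # unconstrained-space density and gradient (sampler-facing)
    # ------------------------------------------------------------------
    def unpack(self, theta: np.ndarray) -> dict:
        """Constrained named values from an unconstrained vector."""
        s = self.slices
        m = theta[s["m"]]
        g = theta[s["g"]]
        sd = np.exp(theta[s["log_sd"]])
        cpc = np.tanh(theta[s["cpc"]])
        df = (
            1.0 + np.exp(float(theta[s["u_df"]][0]))
            if self.sample_df
            else float(self.spec.df_fixed)
        )
        z = theta[s["z"]].reshape(self.P, self.K) if self.K else np.zeros((self.P, 0))
        Ls, corrs = [], []
        off = 0
        effects = np.zeros((self.P, self.K))
        for bidx, nc in zip(self.blocks, self.cpc_per_block):
            d = len(bidx)
            L = chol_from_cpc(cpc[off : off + nc], d)
            Ls.append(L)
            corrs.append(L @ L.T)
            effects[:, bidx] = z[:, bidx] @ (sd[bidx, None] * L).T
            off += nc
        return {
            "m": m,
            "g": g,
            "sd": sd,
            "cpc": cpc,
            "chol": Ls,
            "corr": corrs,
            "df": df,
            "z": z,
            "effects": effects,
        }

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log posterior density (with Jacobians) and its gradient.

        Out-of-support or numerically unsafe points (log-scales beyond
        +-40, non-finite coordinates) return -inf with a zero gradient so
        the sampler treats them as divergences instead of propagating
        NaN.
        """
        s = self.slices
        grad = np.zeros_like(theta)
        if not np.all(np.isfinite(theta)):
            return -np.inf, grad
        if np.any(np.abs(theta[s["log_sd"]]) > 40) or (
            self.sample_df and abs(float(theta[s["u_df"]][0])) > 30
        ):
            return -np.inf, grad
        m = theta[s["m"]]
        g = theta[s["g"]]
        x_sd = theta[s["log_sd"]]
        sd = np.exp(x_sd)
        zc = np.tanh(theta[s["cpc"]])

        lp = 0.0
        # --- priors on fixed effects
        lp += float(np.sum(_normal_logpdf(m, 0.0, self.m_prior_sd)))
        grad[s["m"]] -= m / self.m_prior_sd**2
        lp += float(np.sum(_normal_logpdf(g, self.g_prior_loc, self.g_prior_sd)))
        grad[s["g"]] -= (g - self.g_prior_loc) / self.g_prior_sd**2

        # --- half-t prior on sds (+ log Jacobian x)
        if self.K:
            t2 = sd**2 / (3.0 * self.sd_prior_scale**2)
            lp += float(np.sum(-2.0 * np.log1p(t2) + x_sd))
            grad[s["log_sd"]] += -4.0 * t2 / (1.0 + t2) + 1.0

        # --- LKJ prior on CPCs (+ tanh Jacobian): exponent b on (1 - z^2)
        if self.n_cpc_total:
            b_all = np.concatenate(self.lkj_b)
            lp += float(np.sum(b_all * np.log1p(-zc**2)))
            grad[s["cpc"]] += -2.0 * b_all * zc

        # --- df prior (+ Jacobian u)
        if self.sample_df:
            u = float(theta[s["u_df"]][0])
            df = 1.0 + np.exp(u)
            lp += (
                (self.spec.df_prior_shape - 1.0) * np.log(df)
                - self.spec.df_prior_rate * df
                + u
            )
            grad[s["u_df"]] += (
                (self.spec.df_prior_shape - 1.0) / df - self.spec.df_prior_rate
            ) * np.exp(u) + 1.0
        else:
            df = float(self.spec.df_fixed)

        # --- random effects (non-centered)
        z = theta[s["z"]].reshape(self.P, self.K) if self.K else np.zeros((self.P, 0))
        if self.K:
            lp += float(-0.5 * np.sum(z**2) + -0.5 * self.P * self.K * np.log(2 * np.pi))
            gz = -z.copy()  # gradient wrt z from the N(0,1) prior
        effects = np.zeros((self.P, self.K))
        Ls = []
        Lam_b = None
        if self._blocks_2x2:
            nb = len(self.blocks)
            w = np.sqrt(1.0 - zc**2)
            L_b = np.zeros((nb, 2, 2))
            L_b[:, 0, 0] = 1.0
            L_b[:, 1, 0] = zc
            L_b[:, 1, 1] = w
            Lam_b = L_b * sd.reshape(nb, 2, 1)           # diag(sd) @ L per block
            z_b = z.reshape(self.P, nb, 2)
            effects = np.einsum("bjk,pbk->pbj", Lam_b, z_b).reshape(self.P, self.K)
            Ls = list(L_b)
        else:
            off = 0
            for bidx, nc in zip(self.blocks, self.cpc_per_block):
                L = chol_from_cpc(zc[off + 0 : off + nc], len(bidx))
                Ls.append(L)
                effects[:, bidx] = z[:, bidx] @ (sd[bidx, None] * L).T
                off += nc

        if not self.spec.likelihood:
            if self.K:
                grad[s["z"]] += gz.ravel()
            return lp, grad

        # --- likelihood
        alpha_pc = np.broadcast_to((m @ self.A_fix.T)[None, :], (self.P, 4)).copy()
        if self.K:
            alpha_pc += effects[:, self.loc_sl] @ self.A_eff_loc.T
        eta_pc = np.broadcast_to((g @ self.B_fix.T)[None, :], (self.P, 4)).copy()
        if self.K and self.sc_sl is not None:
            eta_pc += effects[:, self.sc_sl] @ self.A_eff_sc.T

        loc_flat = alpha_pc.reshape(-1)
        eta_flat = eta_pc.reshape(-1)
        if np.max(np.abs(eta_flat)) > 40.0 or np.max(np.abs(loc_flat)) > 1e8:
            return -np.inf, np.zeros_like(theta)
        lp_trials, g_alpha, g_eta, ddf_sum = t_likelihood_core(
            self.y, self.idx_pc, loc_flat, eta_flat, df, self.sample_df, self.P * 4
        )
        if np.isfinite(df):
            lp_const = self.n * (
                special.gammaln((df + 1.0) / 2.0)
                - special.gammaln(df / 2.0)
                - 0.5 * np.log(df * np.pi)
            )
            if self.sample_df:
                ddf = float(
                    self.n
                    * (
                        0.5 * special.digamma((df + 1.0) / 2.0)
                        - 0.5 * special.digamma(df / 2.0)
                        - 0.5 / df
                    )
                    + ddf_sum
                )
                grad[s["u_df"]] += ddf * np.exp(u)
        else:  # Gaussian limit
            lp_const = -0.5 * self.n * np.log(2 * np.pi)
        lp += float(lp_trials) + lp_const
        G_alpha = g_alpha.reshape(self.P, 4)
        G_eta = g_eta.reshape(self.P, 4)
        grad[s["m"]] += G_alpha.sum(axis=0) @ self.A_fix
        grad[s["g"]] += G_eta.sum(axis=0) @ self.B_fix

        if self.K:
            Ge = np.zeros((self.P, self.K))
            Ge[:, self.loc_sl] += G_alpha @ self.A_eff_loc
            if self.sc_sl is not None:
                Ge[:, self.sc_sl] += G_eta @ self.A_eff_sc
            if self._blocks_2x2:
                nb = len(self.blocks)
                Ge_b = Ge.reshape(self.P, nb, 2)
                z_b = z.reshape(self.P, nb, 2)
                gz += np.einsum("pbj,bjk->pbk", Ge_b, Lam_b).reshape(self.P, self.K)
                M_b = np.einsum("pbj,pbk->bjk", Ge_b, z_b)
                L_b = np.stack(Ls)
                grad[s["log_sd"]] += (
                    np.sum(M_b * L_b, axis=2) * sd.reshape(nb, 2)
                ).ravel()
                dL_b = M_b * sd.reshape(nb, 2, 1)
                # closed-form 2x2 adjoint: dz = dL[1,0] - dL[1,1] z / sqrt(1-z^2)
                g_cpc = dL_b[:, 1, 0] - dL_b[:, 1, 1] * zc / np.sqrt(1.0 - zc**2)
            else:
                g_sd = np.zeros(self.K)
                g_cpc = np.zeros(self.n_cpc_total)
                off = 0
                for L, bidx, nc in zip(Ls, self.blocks, self.cpc_per_block):
                    Lam = sd[bidx, None] * L
                    gz[:, bidx] += Ge[:, bidx] @ Lam
                    M = Ge[:, bidx].T @ z[:, bidx]  # d x d
                    g_sd[bidx] = np.sum(M * L, axis=1) * sd[bidx]
                    dL = sd[bidx, None] * M
                    g_cpc[off : off + nc] = chol_from_cpc_backward(
                        zc[off : off + nc], len(bidx), dL
                    )
                    off += nc
                grad[s["log_sd"]] += g_sd
            # chain rule through z = tanh(x): dz/dx = 1 - z^2
            grad[s["cpc"]] += g_cpc * (1.0 - zc**2)
            grad[s["z"]] += gz.ravel()
        return lp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_and_grad(theta)[0]

    # ------------------------------------------------------------------
    def initial_value(self, rng: np.random.Generator) -> np.ndarray:
        """Dispersed but sane starting point."""
        theta = 0.1 * rng.standard_normal(self.n_free)
        s = self.slices
        # start location fixed effects near the data cell means, scales near data log-SD
        cell_means = np.zeros(4)
        cell_sds = np.zeros(4)
        for k in range(4):
            mask = self.idx_cell == k
            cell_means[k] = self.y[mask].mean() if mask.any() else 0.0
            cell_sds[k] = self.y[mask].std() if mask.sum() > 1 else self.sd_y
        cell_sds = np.maximum(cell_sds, 1e-3)
        theta[s["m"]] += np.linalg.lstsq(self.A_fix, cell_means, rcond=None)[0]
        target_g = np.linalg.lstsq(self.B_fix, np.log(cell_sds), rcond=None)[0]
        theta[s["g"]] += target_g
        if self.K:
            theta[s["log_sd"]] += np.log(0.3 * self.sd_y) * (
                np.array([n.startswith("sd_mu") for n in self.sd_names])
            ) + np.log(0.3) * (
                np.array([n.startswith("sd_tau") for n in self.sd_names])
            )
        return theta

    # ------------------------------------------------------------------
    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial log likelihood at one unconstrained draw (for LOO)."""
        p = self.unpack(theta)
        alpha_pc = np.broadcast_to((p["m"] @ self.A_fix.T)[None, :], (self.P, 4)).copy()
        eta_pc = np.broadcast_to((p["g"] @ self.B_fix.T)[None, :], (self.P, 4)).copy()
        if self.K:
            alpha_pc += p["effects"][:, self.loc_sl] @ self.A_eff_loc.T
            if self.sc_sl is not None:
                eta_pc += p["effects"][:, self.sc_sl] @ self.A_eff_sc.T
        loc = alpha_pc.reshape(-1)[self.idx_pc]
        eta = eta_pc.reshape(-1)[self.idx_pc]
        return _t_logpdf(self.y, p["df"], loc, np.exp(eta))


def build_model(spec: HierarchicalModelSpec, scores: pd.DataFrame) -> HierarchicalModel:
    """Construct the joint model for a table of trial scores."""
    return HierarchicalModel(spec, scores)


# ----------------------------------------------------------------------
# densities
# ----------------------------------------------------------------------
def _normal_logpdf(x, loc, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - loc) / sd) ** 2


def _half_t_logpdf(x, scale, df=3.0):
    """Half-Student-t(df, 0, scale), unnormalized is fine for MCMC but we
    keep the full constant for oracle comparisons."""
    c = (
        special.gammaln((df + 1) / 2)
        - special.gammaln(df / 2)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        + np.log(2.0)
    )
    return c - (df + 1) / 2 * np.log1p(x**2 / (df * scale**2))


def _t_logpdf(y, df, loc, scale):
    if not np.isfinite(df):
        return _normal_logpdf(y, loc, scale)
    z2 = ((y - loc) / scale) ** 2
    return (
        special.gammaln((df + 1) / 2)
        - special.gammaln(df / 2)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1) / 2 * np.log1p(z2 / df)
    )


def _mvn_logpdf(x2d, cov):
    """Rows of x2d ~ MVN(0, cov)."""
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, x2d.T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    d = cov.shape[0]
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(sol**2, axis=0))
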
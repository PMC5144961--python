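"""Multi-response Gaussian mixed model fitted by blocked Gibbs sampling.

The lifespan model treats each sex's response as a separate trait measured
on different individuals: fixed sex-specific intercepts and centered batch
dummies, a line random effect with an unstructured cross-sex covariance
matrix G = [[V_LF, Cov_MF], [Cov_MF, V_LM]], a vial random effect with
per-sex variances (no cross-sex covariance — a vial holds one sex), and
per-sex residual variances.  The two-step aging model reuses the identical
code path on per-vial aging-rate estimates (β × 100) with the vial term
switched off.

Priors follow the common small-`ν` convention for Gaussian variance
components: inverse-Wishart with belief parameter ν = 0.002 for residual
variances and parameter-expanded priors with ν = 2 for the random-effect
covariance matrices.  Parameter expansion multiplies each trait's random
effects by a working scale with a diffuse normal prior, which keeps the
sampler mixing when a variance is near zero; every conditional remains
conjugate, so the sampler is a pure Gibbs scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import CollapsedData, build_collapsed, check_identifiable


@dataclass
class ModelSpec:
    """Which responses and random terms the model carries."""

    trait: str = "lifespan"           # 'lifespan' or 'aging' (label only)
    vial_term: bool = True            # False for the two-step aging model
    sexes: tuple[str, ...] = ("F", "M")


@dataclass
class PriorSpec:
    """Prior settings; defaults mirror standard weakly-informative choices.

    ``line_nu``/``vial_nu`` are the belief parameters of the (parameter-
    expanded) inverse-Wishart priors on the random-effect covariance
    matrices, with identity scale; the residual prior is inverse-Wishart
    with ``residual_nu`` = 0.002.  ``px_alpha_var`` is the variance of the
    diffuse normal working prior on the expansion scales.
    """

    line_nu: float = 2.0
    line_scale: float = 1.0
    vial_nu: float = 2.0
    vial_scale: float = 1.0
    residual_nu: float = 0.002
    residual_scale: float = 1.0
    parameter_expansion: bool = True
    px_alpha_var: float = 1e6
    fix_residual: dict | None = None   # sex -> fixed variance (testing hook)

    def __post_init__(self) -> None:
        for name in ("line_nu", "vial_nu", "residual_nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ChainConfig:
    """MCMC run lengths.  The full-scale analysis uses 1.1M iterations;
    ``ChainConfig.reduced()`` is the desk-scale default."""

    iterations: int = 1_100_000
    burn_in: int = 100_000
    thin: int = 1000
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def reduced(cls, seed: int = 0, n_chains: int = 2) -> "ChainConfig":
        return cls(iterations=30_000, burn_in=5_000, thin=25,
                   n_chains=n_chains, seed=seed)

    @property
    def n_retained(self) -> int:
        return -((self.iterations - self.burn_in) // -self.thin)


@dataclass
class PosteriorChain:
    """Retained samples (one row per kept iteration) plus run metadata."""

    samples: pd.DataFrame
    spec: ModelSpec
    config: ChainConfig
    seed: int
    sexes: list[str] = field(default_factory=lambda: ["F", "M"])

    def __len__(self) -> int:
        return len(self.samples)

    def g_matrices(self) -> np.ndarray:
        """Per-sample line covariance matrices, shape (n, T, T)."""
        T = len(self.sexes)
        out = np.empty((len(self.samples), T, T))
        for i, si in enumerate(self.sexes):
            out[:, i, i] = self.samples[f"V_L_{si}"]
        if T == 2:
            out[:, 0, 1] = out[:, 1, 0] = self.samples["Cov_MF"]
        return out

    def save(self, csv_path, meta_path=None) -> None:
        self.samples.to_csv(csv_path, index=False)
        meta_path = meta_path or Path(str(csv_path)).with_suffix(".json")
        meta = {"trait": self.spec.trait, "vial_term": self.spec.vial_term,
                "sexes": list(self.sexes), "seed": int(self.seed),
                "iterations": self.config.iterations,
                "burn_in": self.config.burn_in, "thin": self.config.thin}
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, csv_path, meta_path=None) -> "PosteriorChain":
        samples = pd.read_csv(csv_path)
        meta_path = meta_path or Path(str(csv_path)).with_suffix(".json")
        with open(meta_path) as fh:
            meta = json.load(fh)
        spec = ModelSpec(trait=meta["trait"], vial_term=meta["vial_term"],
                         sexes=tuple(meta["sexes"]))
        cfg = ChainConfig(iterations=meta["iterations"],
                          burn_in=meta["burn_in"], thin=meta["thin"],
                          seed=meta["seed"])
        return cls(samples, spec, cfg, meta["seed"], list(meta["sexes"]))


def _inv_wishart_2x2(df: float, scale: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw from IW(df, scale) via Bartlett decomposition (p = 2)."""
    Sinv = np.linalg.inv(scale)
    Lc = np.linalg.cholesky(Sinv)
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    A[1, 0] = rng.standard_normal()
    F = Lc @ A                      # W = F F' ~ Wishart(df, Sinv)
    W = F @ F.T
    det = W[0, 0] * W[1, 1] - W[0, 1] ** 2
    return np.array([[W[1, 1], -W[0, 1]], [-W[0, 1], W[0, 0]]]) / det


def _invgamma(shape: float, scale: float, rng: np.random.Generator) -> float:
    """Inverse-gamma(shape, scale) draw."""
    return float(scale / rng.gamma(shape, 1.0))


def run_gibbs(spec: ModelSpec, prior: PriorSpec, config: ChainConfig,
              data, response: str = "lifespan_days",
              seed: int | None = None) -> PosteriorChain:
    """Blocked Gibbs sampler for the multi-response line/vial model.

    ``data`` is either an individual-record DataFrame or a pre-collapsed
    :class:`~hemivar.design.CollapsedData`.  Update order per iteration:
    fixed effects | line effects (with parameter-expansion scales) | line
    covariance | vial effects and variances | residual variances.  Output
    rows satisfy the positive-semidefinite invariant for every retained G
    sample by construction.
    """
    if not isinstance(data, CollapsedData):
        data = build_collapsed(data, response=response,
                               sexes=list(spec.sexes))
    check_identifiable(data, vial_term=spec.vial_term)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    T, L, nv = data.n_traits, data.n_lines, data.n.size
    p = data.X.shape[1]
    s_idx, l_idx, n = data.sex_idx, data.line_idx, data.n
    ybar, X = data.ybar, data.X
    g_idx = l_idx * T + s_idx
    n_ls = np.bincount(g_idx, weights=n, minlength=L * T).reshape(L, T)
    sex_masks = [s_idx == t for t in range(T)]
    A = [(X[m].T * n[m]) @ X[m] for m in sex_masks]
    N_s = data.per_sex_counts()
    SSW_s = data.per_sex_ssw()
    nv_s = np.array([int(m.sum()) for m in sex_masks], dtype=float)

    # --- initial state -------------------------------------------------
    w0 = n.copy()
    beta = np.linalg.lstsq(X * np.sqrt(w0)[:, None],
                           ybar * np.sqrt(w0), rcond=None)[0]
    xb = X @ beta
    sigma2 = np.empty(T)
    for t in range(T):
        m = sex_masks[t]
        if N_s[t] > nv_s[t]:
            sigma2[t] = max(SSW_s[t] / (N_s[t] - nv_s[t]), 1e-6)
        else:
            sigma2[t] = max(np.var(ybar[m] - xb[m]), 1e-6)
    if prior.fix_residual:
        for t, sx in enumerate(data.sexes):
            if sx in prior.fix_residual:
                sigma2[t] = float(prior.fix_residual[sx])
    line_mean_resid = np.zeros((L, T))
    cnt = np.maximum(np.bincount(g_idx, minlength=L * T).reshape(L, T), 1)
    np.add.at(line_mean_resid, (l_idx, s_idx), ybar - xb)
    line_mean_resid /= cnt
    Gw = np.diag(np.maximum(np.var(line_mean_resid, axis=0), 1e-3))
    eta = np.zeros((L, T))
    lam = np.ones(T)
    psi = np.zeros(nv)
    phi = np.ones(T)
    Vv_w = np.full(T, 1.0)
    v = np.zeros(nv)
    use_px = prior.parameter_expansion

    nu_L, S_L = prior.line_nu, prior.line_nu * prior.line_scale
    nu_V, S_V = prior.vial_nu, prior.vial_nu * prior.vial_scale
    nu_R, S_R = prior.residual_nu, prior.residual_nu * prior.residual_scale

    n_keep = config.n_retained
    cols = list(data.columns)
    for t, sx in enumerate(data.sexes):
        cols.append(f"V_L_{sx}")
    if T == 2:
        cols.append("Cov_MF")
    if spec.vial_term:
        cols += [f"V_V_{sx}" for sx in data.sexes]
    cols += [f"V_R_{sx}" for sx in data.sexes]
    out = np.empty((n_keep, len(cols)))
    kept = 0

    inv_sigma = 1.0 / sigma2
    for it in range(config.iterations):
        w = n * inv_sigma[s_idx]

        # fixed effects
        u_flat = (lam * eta)[l_idx, s_idx]
        r = ybar - u_flat - v
        XtWX = sum(A[t] * inv_sigma[t] for t in range(T))
        XtWr = X.T @ (w * r)
        Lc = np.linalg.cholesky(XtWX)
        mu = np.linalg.solve(XtWX, XtWr)
        z = rng.standard_normal(p)
        beta = mu + np.linalg.solve(Lc.T, z)
        xb = X @ beta

        # line effects (working scale eta, expansion scales lam)
        r2 = ybar - xb - v
        b = np.bincount(g_idx, weights=n * r2, minlength=L * T).reshape(L, T)
        b = b * (lam * inv_sigma)[None, :]
        c = n_ls * (lam ** 2 * inv_sigma)[None, :]
        if T == 2:
            Gdet = Gw[0, 0] * Gw[1, 1] - Gw[0, 1] ** 2
            Gi00, Gi11 = Gw[1, 1] / Gdet, Gw[0, 0] / Gdet
            Gi01 = -Gw[0, 1] / Gdet
            P11 = Gi00 + c[:, 0]
            P22 = Gi11 + c[:, 1]
            l11 = np.sqrt(P11)
            l21 = Gi01 / l11
            l22 = np.sqrt(P22 - l21 ** 2)
            w1 = b[:, 0] / l11
            w2 = (b[:, 1] - l21 * w1) / l22
            m2 = w2 / l22
            m1 = (w1 - l21 * m2) / l11
            z = rng.standard_normal((L, 2))
            x2 = z[:, 1] / l22
            x1 = (z[:, 0] - l21 * x2) / l11
            eta = np.column_stack([m1 + x1, m2 + x2])
        else:
            P = 1.0 / Gw[0, 0] + c[:, 0]
            eta = ((b[:, 0] / P)
                   + rng.standard_normal(L) / np.sqrt(P))[:, None]

        if use_px:
            for t in range(T):
                m = sex_masks[t]
                et = eta[l_idx[m], t]
                rw = r2[m]
                wt = n[m] * inv_sigma[t]
                den = float(np.dot(wt * et, et)) + 1.0 / prior.px_alpha_var
                num = float(np.dot(wt * et, rw))
                lam[t] = num / den + rng.standard_normal() / np.sqrt(den)
        # line covariance (working scale), then back-transform
        S = S_L * np.eye(T) + eta.T @ eta
        if T == 2:
            Gw = _inv_wishart_2x2(nu_L + L, S, rng)
        else:
            Gw = np.array([[_invgamma((nu_L + L) / 2.0, S[0, 0] / 2.0, rng)]])
        G = (lam[:, None] * Gw) * lam[None, :]
        u = lam * eta
        u_flat = u[l_idx, s_idx]

        # vial effects
        if spec.vial_term:
            r3 = ybar - xb - u_flat
            wv = n * inv_sigma[s_idx]
            prec = (phi[s_idx] ** 2) * wv + 1.0 / Vv_w[s_idx]
            mean = phi[s_idx] * wv * r3 / prec
            psi = mean + rng.standard_normal(nv) / np.sqrt(prec)
            if use_px:
                for t in range(T):
                    m = sex_masks[t]
                    wt = n[m] * inv_sigma[t]
                    den = float(np.dot(wt * psi[m], psi[m])) \
                        + 1.0 / prior.px_alpha_var
                    num = float(np.dot(wt * psi[m], r3[m]))
                    phi[t] = num / den + rng.standard_normal() / np.sqrt(den)
            for t in range(T):
                m = sex_masks[t]
                Vv_w[t] = _invgamma((nu_V + nv_s[t]) / 2.0,
                                    (S_V + np.dot(psi[m], psi[m])) / 2.0, rng)
            v = phi[s_idx] * psi
            V_V = phi ** 2 * Vv_w

        # residual variances
        resid = ybar - xb - u_flat - v
        for t in range(T):
            if prior.fix_residual and data.sexes[t] in prior.fix_residual:
                continue
            m = sex_masks[t]
            sse = SSW_s[t] + float(np.dot(n[m], resid[m] ** 2))
            sigma2[t] = _invgamma((nu_R + N_s[t]) / 2.0,
                                  (S_R + sse) / 2.0, rng)
        inv_sigma = 1.0 / sigma2

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            row = list(beta)
            row += [G[t, t] for t in range(T)]
            if T == 2:
                row.append(G[0, 1])
            if spec.vial_term:
                row += list(V_V)
            row += list(sigma2)
            out[kept] = row
            kept += 1

    samples = pd.DataFrame(out[:kept], columns=cols)
    return PosteriorChain(samples=samples, spec=spec, config=config,
                          seed=seed, sexes=list(data.sexes))


def gelman_rubin(chains, parameters: list[str] | None = None,
                 threshold: float = 1.05) -> pd.DataFrame:
    """Potential scale reduction factors with upper 95% limits.

    Classical between/within-chain PSRF (Gelman–Rubin, with the
    Brooks–Gelman degrees-of-freedom adjustment); a parameter is flagged
    when the upper limit exceeds ``threshold``.  Requires ≥ 2 chains of
    equal retained length.
    """
    if len(chains) < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    frames = [c.samples if isinstance(c, PosteriorChain) else pd.DataFrame(c)
              for c in chains]
    n = len(frames[0])
    if any(len(f) != n for f in frames):
        raise ValueError("chains must share retained length")
    if parameters is None:
        parameters = [c for c in frames[0].columns]
    m = len(frames)
    rows = []
    for par in parameters:
        x = np.stack([f[par].to_numpy(dtype=float) for f in frames])
        mu = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        W = s2.mean()
        B = n * mu.var(ddof=1)
        if W <= 0:
            rows.append((par, 1.0, 1.0, False))
            continue
        sigma2_hat = (n - 1) / n * W + B / n
        Vhat = sigma2_hat + B / (m * n)
        var_w = s2.var(ddof=1) / m
        var_b = 2.0 * B ** 2 / (m - 1)
        cov_wb = (n / m) * (np.cov(s2, mu ** 2, ddof=1)[0, 1]
                            - 2.0 * mu.mean() * np.cov(s2, mu, ddof=1)[0, 1])
        var_V = ((n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b
                 + 2 * (n - 1) * (1 + 1 / m) * cov_wb) / n ** 2
        df_V = 2 * Vhat ** 2 / var_V if var_V > 0 else np.inf
        df_adj = (df_V + 3) / (df_V + 1) if np.isfinite(df_V) else 1.0
        R2_fixed = (n - 1) / n
        R2_random = (1 + 1 / m) * B / (n * W)
        psrf = float(np.sqrt(df_adj * (R2_fixed + R2_random)))
        if var_w > 0:
            w_df = 2 * W ** 2 / (s2.var(ddof=1) / m)
            q = stats.f.ppf(0.975, m - 1, w_df)
        else:
            q = stats.chi2.ppf(0.975, m - 1) / (m - 1)
        upper = float(np.sqrt(df_adj * (R2_fixed + q * R2_random)))
        rows.append((par, psrf, upper, upper > threshold))
    return pd.DataFrame(rows, columns=["parameter", "psrf", "upper",
                                       "flagged"])
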
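"""Restricted maximum likelihood for the line/vial variance models.

The restricted log-likelihood is maximized directly over a parameterization
that enforces validity: log variances, and the cross-sex line correlation
through atanh (so the implied covariance matrix is always positive
semidefinite).  Because fixed effects, line effects and vial effects are
constant within vials, the likelihood is evaluated on vial-level sufficient
statistics with a Woodbury-style per-line factorization, which makes each
evaluation cheap even for the full 32,000-fly design.

Null hypotheses are imposed by reparameterization, not penalties: a
constrained parameter is removed from the free vector and reconstructed
from the remaining ones (fixed value, shared across line types, or a fixed
multiple of another parameter).  Likelihood-ratio statistics then compare
nested fits on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import CollapsedData, build_collapsed, check_identifiable

_LOG_BOUNDS = (-18.0, 18.0)
_Z_BOUNDS = (-8.0, 8.0)


class _Pack:
    """Per-dataset precomputation for repeated likelihood evaluations.

    Lines are grouped by vial count so the per-line solves can be batched;
    the grouping, index matrices and per-sex constants do not change during
    optimization, only the covariance components do.
    """

    def __init__(self, data: CollapsedData):
        s, l = data.sex_idx, data.line_idx
        self.sex_idx, self.n = s, data.n
        self.T = data.n_traits
        self.p = data.X.shape[1]
        self.n_obs = data.n_obs
        self.N_s = data.per_sex_counts()
        self.nv_s = np.array([(s == t).sum() for t in range(self.T)], float)
        self.SSW_s = data.per_sex_ssw()
        self.log_n_sum = float(np.sum(np.log(data.n)))
        order = np.argsort(l, kind="stable")
        counts = np.bincount(l[order], minlength=data.n_lines)
        starts = np.concatenate([[0], np.cumsum(counts)])
        self.groups = []
        for k in np.unique(counts[counts > 0]):
            lines_k = np.flatnonzero(counts == k)
            idx = np.stack([order[starts[i]:starts[i] + k] for i in lines_k])
            self.groups.append((int(k), idx, s[idx], data.X[idx],
                                data.ybar[idx]))

    def loglik(self, G: np.ndarray, V_R: np.ndarray,
               V_V: np.ndarray | None = None,
               return_beta: bool = False):
        if np.any(V_R <= 0):
            return -np.inf
        D = V_R[self.sex_idx] / self.n
        if V_V is not None:
            D = D + V_V[self.sex_idx]
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        yViy = 0.0
        logdet = 0.0
        for k, idx, sexg, Xg, yg in self.groups:
            M = G[sexg[:, :, None], sexg[:, None, :]].copy()
            rng_k = np.arange(k)
            M[:, rng_k, rng_k] += D[idx]
            try:
                chol = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                return (-np.inf, None) if return_beta else -np.inf
            logdet += 2.0 * np.sum(np.log(np.einsum("lkk->lk", chol)))
            B = np.concatenate([yg[:, :, None], Xg], axis=2)
            sol = np.linalg.solve(M, B)
            XtViX += np.einsum("lkp,lkq->pq", Xg, sol[:, :, 1:])
            XtViy += np.einsum("lkp,lk->p", Xg, sol[:, :, 0])
            yViy += float(np.einsum("lk,lk->", yg, sol[:, :, 0]))
        sign, ld_fix = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return (-np.inf, None) if return_beta else -np.inf
        beta = np.linalg.solve(XtViX, XtViy)
        quad = yViy - float(beta @ XtViy)
        term_within = float(np.sum((self.N_s - self.nv_s) * np.log(V_R))
                            + np.sum(self.SSW_s / V_R))
        const = self.log_n_sum + (self.n_obs - self.p) * np.log(2 * np.pi)
        ll = -0.5 * (term_within + logdet + quad + ld_fix + const)
        return (ll, beta) if return_beta else ll


def _get_pack(data: CollapsedData) -> _Pack:
    pack = getattr(data, "_reml_pack", None)
    if pack is None:
        pack = _Pack(data)
        data._reml_pack = pack
    return pack


def restricted_loglik(data: CollapsedData, G: np.ndarray, V_R: np.ndarray,
                      V_V: np.ndarray | None = None) -> float:
    """Restricted log-likelihood of one line type's data at the given components.

    ``G`` is the T×T line covariance, ``V_R``/``V_V`` per-sex residual and
    vial variances (``V_V=None`` when the model has no vial term).
    """
    return _get_pack(data).loglik(np.asarray(G, float),
                                  np.asarray(V_R, float),
                                  None if V_V is None
                                  else np.asarray(V_V, float))


def _gls_beta(data: CollapsedData, G, V_R, V_V):
    """GLS fixed-effect estimates at the fitted components."""
    _, beta = _get_pack(data).loglik(G, V_R, V_V, return_beta=True)
    return beta


# ------------------------------------------------------------------ fits

@dataclass
class REMLFit:
    components: dict
    beta: dict
    loglik: float
    converged: bool
    n_free: int
    constraints: list = field(default_factory=list)
    message: str = ""


def _moment_starts(data: CollapsedData, vial_term: bool) -> dict:
    """Crude ANOVA-flavoured starting values."""
    out = {}
    for t, sx in enumerate(data.sexes):
        m = data.sex_idx == t
        N, nv = data.n[m].sum(), int(m.sum())
        total = np.var(data.ybar[m]) + 1e-6
        if N > nv:
            vr = max(data.ss[m].sum() / (N - nv), 1e-6)
        else:
            vr = 0.6 * total
        lm = pd.Series(data.ybar[m]).groupby(data.line_idx[m]).mean()
        vl = max(float(lm.var()) - total / max(nv / max(len(lm), 1), 1.0), 0.0)
        vl = max(vl, 0.05 * total)
        out[("V_L", sx)] = vl
        out[("V_R", sx)] = vr
        if vial_term:
            out[("V_V", sx)] = max(0.2 * total, 1e-4)
    return out


class _ParamMap:
    """Free-vector <-> named-component mapping with constraint rules."""

    def __init__(self):
        self.rules: dict[tuple, tuple] = {}
        self.order: list[tuple] = []

    def add(self, key, kind="free", **kw):
        if key not in self.rules:
            self.order.append(key)
        self.rules[key] = (kind, kw)

    def free_keys(self):
        return [k for k in self.order if self.rules[k][0] == "free"]

    def resolve(self, theta: np.ndarray) -> dict:
        vals: dict[tuple, float] = {}
        free = dict(zip(self.free_keys(), theta))
        pending = list(self.order)
        for _ in range(4):
            rest = []
            for key in pending:
                kind, kw = self.rules[key]
                if kind == "free":
                    x = free[key]
                    vals[key] = np.tanh(x) if key[0] == "r" else np.exp(x)
                elif kind == "fixed":
                    vals[key] = kw["value"]
                elif kind == "alias":
                    if kw["target"] in vals:
                        vals[key] = vals[kw["target"]]
                    else:
                        rest.append(key)
                        continue
                elif kind == "scaled":
                    if kw["target"] in vals:
                        vals[key] = kw["factor"] * vals[kw["target"]]
                    else:
                        rest.append(key)
                        continue
            pending = rest
            if not pending:
                break
        if pending:
            raise ValueError(f"unresolvable constraint chain: {pending}")
        return vals

    def start_vector(self, starts: dict) -> np.ndarray:
        x0 = []
        for key in self.free_keys():
            if key[0] == "r":
                x0.append(np.arctanh(np.clip(starts.get(key, 0.0),
                                             -0.95, 0.95)))
            else:
                x0.append(np.log(max(starts.get(key, 1.0), 1e-8)))
        return np.array(x0)

    def bounds(self):
        return [_Z_BOUNDS if k[0] == "r" else _LOG_BOUNDS
                for k in self.free_keys()]


def _components_for(vals: dict, ct: str, sexes: list[str], vial_term: bool):
    T = len(sexes)
    G = np.zeros((T, T))
    for i, sx in enumerate(sexes):
        G[i, i] = vals[("V_L", ct, sx)]
    if T == 2:
        r = vals.get(("r", ct), 0.0)
        G[0, 1] = G[1, 0] = r * np.sqrt(G[0, 0] * G[1, 1])
    V_R = np.array([vals[("V_R", ct, sx)] for sx in sexes])
    V_V = (np.array([vals[("V_V", ct, sx)] for sx in sexes])
           if vial_term else None)
    return G, V_R, V_V


def reml_fit(records: pd.DataFrame, response: str = "lifespan_days",
             vial_term: bool = True, constraints: list | None = None,
             sexes: list[str] | None = None) -> REMLFit:
    """(Constrained) REML fit of the line/vial model, jointly over line types.

    ``records`` are individual rows (or vial-level rows for the aging
    response) with a ``chromosome_type`` column; line types enter as
    independent blocks whose parameters constraints may tie together.

    Supported constraints (list of dicts, ``type`` keyed):

    * ``x_proportion`` — female X line variance a fixed proportion ``value``
      of the female X+A total (additive-variance scale).
    * ``equal_sex_va_x`` — male and female X-linked additive variance equal
      (``mean_standardized=True`` equates CV_A instead).
    * ``equal_rmf`` — one cross-sex line correlation shared by X and A.
    * ``zero_line_variance`` — the named ``chrom``/``sex`` line variance
      pinned to zero (its cross-sex covariance with it is then zero too).
    """
    constraints = constraints or []
    if "chromosome_type" in records.columns:
        cts = sorted(records["chromosome_type"].unique())
    else:
        records = records.assign(chromosome_type="A")
        cts = ["A"]
    if sexes is None:
        sexes = sorted(records["sex"].unique())
    datasets = {}
    for ct in cts:
        d = build_collapsed(records[records["chromosome_type"] == ct],
                            response=response, sexes=sexes)
        check_identifiable(d, vial_term=vial_term)
        datasets[ct] = d

    pm = _ParamMap()
    starts: dict = {}
    for ct, d in datasets.items():
        ms = _moment_starts(d, vial_term)
        for sx in sexes:
            pm.add(("V_L", ct, sx))
            starts[("V_L", ct, sx)] = ms[("V_L", sx)]
            pm.add(("V_R", ct, sx))
            starts[("V_R", ct, sx)] = ms[("V_R", sx)]
            if vial_term:
                pm.add(("V_V", ct, sx))
                starts[("V_V", ct, sx)] = ms[("V_V", sx)]
        if len(sexes) == 2:
            pm.add(("r", ct))
            starts[("r", ct)] = 0.2

    for con in constraints:
        kind = con["type"]
        if kind == "zero_line_variance":
            key = ("V_L", con["chrom"], con["sex"])
            pm.add(key, "fixed", value=0.0)
            if len(sexes) == 2:
                pm.add(("r", con["chrom"]), "fixed", value=0.0)
        elif kind == "x_proportion":
            prop = con["value"]
            sx = con.get("sex", "F")
            pm.add(("V_L", "X", sx), "scaled", target=("V_L", "A", sx),
                   factor=prop / (1.0 - prop))
        elif kind == "equal_sex_va_x":
            factor = 2.0
            if con.get("mean_standardized"):
                sub = records[records["chromosome_type"] == "X"]
                mf = sub.loc[sub["sex"] == "F", response].mean()
                mm = sub.loc[sub["sex"] == "M", response].mean()
                factor = 2.0 * (mm / mf) ** 2
            pm.add(("V_L", "X", "M"), "scaled", target=("V_L", "X", "F"),
                   factor=factor)
        elif kind == "equal_rmf":
            pm.add(("r", "X"), "alias", target=("r", "A"))
        else:
            raise ValueError(f"unknown constraint type {kind!r}")

    packs = {ct: _get_pack(d) for ct, d in datasets.items()}

    def objective(theta):
        vals = pm.resolve(theta)
        total = 0.0
        for ct in datasets:
            G, V_R, V_V = _components_for(vals, ct, sexes, vial_term)
            total += packs[ct].loglik(G, V_R, V_V)
        return -total

    x0 = pm.start_vector(starts)
    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            bounds=pm.bounds(),
                            options={"maxiter": 300, "ftol": 1e-11,
                                     "gtol": 1e-8})
    # simplex polish: finite-difference gradients limit L-BFGS-B accuracy
    n_free = len(pm.free_keys())
    polish = optimize.minimize(objective, res.x, method="Nelder-Mead",
                               options={"xatol": 1e-9, "fatol": 1e-12,
                                        "maxfev": 400 * n_free + 400})
    if polish.fun <= res.fun:
        polish.success = polish.success or res.success
        res = polish
    vals = pm.resolve(res.x)
    components, beta = {}, {}
    for ct, d in datasets.items():
        G, V_R, V_V = _components_for(vals, ct, sexes, vial_term)
        comp = {"V_L": {sx: float(G[i, i]) for i, sx in enumerate(sexes)},
                "V_R": {sx: float(V_R[i]) for i, sx in enumerate(sexes)}}
        if vial_term:
            comp["V_V"] = {sx: float(V_V[i]) for i, sx in enumerate(sexes)}
        if len(sexes) == 2:
            comp["Cov_MF"] = float(G[0, 1])
            comp["r_MF"] = float(vals.get(("r", ct), 0.0))
        components[ct] = comp
        b = _gls_beta(d, G, V_R, V_V)
        beta[ct] = dict(zip(d.columns, map(float, b)))
    return REMLFit(components=components, beta=beta,
                   loglik=float(-res.fun), converged=bool(res.success),
                   n_free=len(pm.free_keys()), constraints=constraints,
                   message=str(res.message))


def lrt(full: REMLFit, constrained: REMLFit, df: int | None = None,
        boundary_mixture: bool = False, tol: float = 1e-4) -> dict:
    """Likelihood-ratio test of nested REML fits.

    ``X² = 2(ℓ_full − ℓ_constrained)`` referred to χ²_df (the analysis
    convention for variance components); ``boundary_mixture=True`` uses the
    conservative 0.5·χ²₀ + 0.5·χ²₁ mixture instead (df must be 1).
    """
    if df is None:
        df = full.n_free - constrained.n_free
    if df < 1:
        raise ValueError("constrained model must have fewer free parameters")
    x2 = 2.0 * (full.loglik - constrained.loglik)
    if x2 < -tol * max(1.0, abs(full.loglik)):
        raise RuntimeError(
            f"constrained fit exceeds full fit (X2 = {x2:.4g}); "
            "optimizer failure — no p-value")
    x2 = max(x2, 0.0)
    if boundary_mixture:
        if df != 1:
            raise ValueError("boundary mixture defined for df = 1")
        p = 0.5 * stats.chi2.sf(x2, 1) + (0.5 if x2 == 0 else 0.0)
    else:
        p = float(stats.chi2.sf(x2, df))
    return {"X2": float(x2), "df": int(df), "p": float(p)}


def line_variance_test(records: pd.DataFrame, chrom: str, sex: str,
                       response: str = "lifespan_days",
                       vial_term: bool = True,
                       boundary_mixture: bool = False) -> dict:
    """Univariate LRT for a single sex × line-type line variance.

    Fits the univariate line/vial model with and without the line term and
    returns the χ²₁ test (the multivariate alternative gives almost
    identical lifespan results but need not converge for aging).
    """
    sub = records[(records["chromosome_type"] == chrom)
                  & (records["sex"] == sex)]
    full = reml_fit(sub, response=response, vial_term=vial_term, sexes=[sex])
    null = reml_fit(sub, response=response, vial_term=vial_term, sexes=[sex],
                    constraints=[{"type": "zero_line_variance",
                                  "chrom": chrom, "sex": sex}])
    out = lrt(full, null, df=1, boundary_mixture=boundary_mixture)
    out["V_L"] = full.components[chrom]["V_L"][sex]
    return out
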
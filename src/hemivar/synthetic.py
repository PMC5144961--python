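"""Synthetic hemiclone-design data with the statistical structure the
downstream models assume.

Two generative paths are provided:

* Gaussian lifespans — grand mean + fixed batch effect + bivariate-normal
  line effect (shared across a line's vials, correlated across sexes) +
  vial effect + residual, truncated below at a small floor because real
  lifespans are positive.
* Demographic aging — per-vial Gompertz cohorts whose (log α, β) parameters
  carry line and vial variation on the β × 100 scale, with a strong negative
  log α–β correlation.

All randomness flows from one master seed through ``numpy`` SeedSequence
spawning, one child stream per stage, so identical seed + configuration
gives byte-identical output tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AgingParams, DesignConfig, GeneticParams
from .gompertz import MortalitySchedule, alpha_for_mean_lifespan
from . import reference

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["line_id", "chromosome_type", "sex", "batch", "vial_id",
                  "lifespan_days"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(master_seed: int, n: int) -> list[np.random.Generator]:
    """Deterministically split a master seed into independent child streams."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(master_seed).spawn(n)]


def _check_psd(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.shape != (2, 2) or not np.allclose(G, G.T):
        raise ValueError("G must be a symmetric 2x2 matrix")
    w = np.linalg.eigvalsh(G)
    if w.min() < -1e-10 * max(1.0, abs(w.max())):
        raise ValueError(
            f"G is not positive semidefinite: eigenvalue {w.min():.6g} < 0")
    return G


def _psd_factor(G: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(G)
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_line_effects(n_lines: int, G, seed) -> pd.DataFrame:
    """Draw i.i.d. bivariate-normal (female, male) line effects with covariance G."""
    G = _check_psd(G)
    rng = _rng(seed)
    z = rng.standard_normal((n_lines, 2))
    eff = z @ _psd_factor(G).T
    return pd.DataFrame({"line_id": np.arange(1, n_lines + 1),
                         "effect_F": eff[:, 0], "effect_M": eff[:, 1]})


def vial_label(chrom_type: str, line: int, sex: str, batch: int) -> str:
    return f"{chrom_type}{line:02d}_{sex}_b{batch}"


def simulate_lifespans(config: DesignConfig,
                       params: dict[str, GeneticParams],
                       seed, floor: float = 1.0) -> pd.DataFrame:
    """Simulate one full lifespan assay as a table of individual records.

    ``params`` maps chromosome type ('A'/'X') to its Gaussian components.
    Negative Gaussian draws are truncated at ``floor`` days (count logged);
    with the default study-condition variances this affects essentially no
    records.
    """
    for ct in config.chromosome_types:
        if ct not in params:
            raise ValueError(f"missing GeneticParams for chromosome type {ct!r}")
    streams = iter(spawn_rngs_keyed(seed, [
        f"{stage}:{ct}" for ct in config.chromosome_types
        for stage in ("lines", "vials", "residuals")]))
    sex_col = {"F": 0, "M": 1}
    L, B, n = (config.n_lines_per_type, config.n_batches,
               config.n_flies_per_vial)
    frames = []
    n_truncated = 0
    for ct in config.chromosome_types:
        p = params[ct]
        rng_lines, rng_vials, rng_resid = next(streams), next(streams), next(streams)
        eff = simulate_line_effects(L, p.G, rng_lines)
        eff_mat = eff[["effect_F", "effect_M"]].to_numpy()
        for sex in config.sexes:
            be = np.asarray(p.batch_effects[sex], dtype=float)
            if be.size != B:
                raise ValueError("batch_effects length must equal n_batches")
            u = eff_mat[:, sex_col[sex]]                       # (L,)
            v = rng_vials.normal(0.0, np.sqrt(p.V_V[sex]), (L, B))
            e = rng_resid.normal(0.0, np.sqrt(p.V_R[sex]), (L, B, n))
            y = (p.grand_mean[sex] + be[None, :, None]
                 + u[:, None, None] + v[:, :, None] + e).ravel()
            n_truncated += int(np.sum(y < floor))
            np.clip(y, floor, None, out=y)
            lines = np.repeat(np.arange(1, L + 1), B * n)
            batches = np.tile(np.repeat(np.arange(1, B + 1), n), L)
            line_ids = np.array([f"{ct}{i:02d}" for i in range(1, L + 1)])
            vial_ids = np.array([vial_label(ct, i, sex, b)
                                 for i in range(1, L + 1)
                                 for b in range(1, B + 1)])
            frames.append(pd.DataFrame({
                "line_id": line_ids[lines - 1],
                "chromosome_type": ct, "sex": sex, "batch": batches,
                "vial_id": np.repeat(vial_ids, n),
                "lifespan_days": y}))
    if n_truncated:
        logger.info("truncated %d negative lifespan draws at %.1f d",
                    n_truncated, floor)
    out = pd.concat(frames, ignore_index=True)
    assert len(out) == config.n_records
    return out


def spawn_rngs_keyed(master_seed, keys) -> list[np.random.Generator]:
    """One child stream per key, in key order, from a single master seed."""
    if isinstance(master_seed, np.random.Generator):
        # already a stream: split it further
        seeds = master_seed.integers(0, 2**31 - 1, size=len(keys))
        return [np.random.default_rng(int(s)) for s in seeds]
    return spawn_rngs(master_seed, len(keys))


def simulate_gompertz_cohort(alpha: float, beta: float, n: int,
                             census_interval: float, max_age: float,
                             seed, vial_id: str = "vial") -> MortalitySchedule:
    """Draw ``n`` Gompertz death ages and bin them into census intervals.

    Sampling is by inversion of S(t) = exp(−(α/β)(e^{βt} − 1)); for β < 0 a
    fraction of flies never dies (defective distribution) and is recorded as
    right-censored at ``max_age`` along with any fly outliving the assay.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    u = rng.uniform(size=n)
    if abs(beta) < 1e-8:
        t = -np.log(u) / alpha
    else:
        arg = 1.0 - (beta / alpha) * np.log(u)
        t = np.full(n, np.inf)
        ok = arg > 0
        t[ok] = np.log(arg[ok]) / beta
    boundaries = np.arange(0.0, max_age + 1e-9, census_interval)
    if boundaries[-1] < max_age - 1e-9:
        boundaries = np.append(boundaries, max_age)
    if boundaries.size < 2:
        return MortalitySchedule(vial_id, np.array([0.0]) if boundaries.size
                                 else np.array([]), np.array([], dtype=int),
                                 censored=n)
    deaths, _ = np.histogram(t[np.isfinite(t)], bins=boundaries)
    censored = n - int(deaths.sum())
    return MortalitySchedule(vial_id, boundaries, deaths, censored)


def simulate_aging_design(config: DesignConfig,
                          params: dict[str, AgingParams] | None = None,
                          seed=0, max_age: float = 150.0,
                          beta100_floor: float = 0.5,
                          mean_lifespan: dict | None = None,
                          ) -> tuple[list[MortalitySchedule], pd.DataFrame]:
    """Per-vial Gompertz cohorts for the full design, plus the generative truth.

    Per vial, the aging rate on the β × 100 scale is grand mean + line effect
    (bivariate normal across sexes) + vial deviation; log α is then drawn
    conditionally on β with correlation ``log_alpha_beta_corr``, centered so
    the sex's mean lifespan matches the lifespan study conditions.
    Returns (schedules, truth table with per-vial α and β).
    """
    if params is None:
        from .config import default_aging_params
        params = default_aging_params()
    if mean_lifespan is None:
        mean_lifespan = {ct: {s: reference.TABLE1["lifespan"][ct][s]["mean"]
                              for s in config.sexes}
                         for ct in config.chromosome_types}
    rngs = iter(spawn_rngs_keyed(seed, [
        f"{stage}:{ct}" for ct in config.chromosome_types
        for stage in ("lines", "vials", "cohorts")]))
    sex_col = {"F": 0, "M": 1}
    schedules, rows = [], []
    for ct in config.chromosome_types:
        p = params[ct]
        rng_lines, rng_vials, rng_cohorts = next(rngs), next(rngs), next(rngs)
        eff = simulate_line_effects(config.n_lines_per_type, p.line_G(),
                                    rng_lines)
        eff_mat = eff[["effect_F", "effect_M"]].to_numpy()
        for sex in config.sexes:
            beta_bar = p.beta_mean[sex]
            sd_beta100 = np.sqrt(p.V_L_beta[sex] + p.V_vial_beta[sex])
            la_bar = np.log(alpha_for_mean_lifespan(
                beta_bar / 100.0, mean_lifespan[ct][sex]))
            rho, s_la = p.log_alpha_beta_corr, p.log_alpha_sd
            for line in range(1, config.n_lines_per_type + 1):
                u = eff_mat[line - 1, sex_col[sex]]
                for batch in range(1, config.n_batches + 1):
                    b100 = beta_bar + u + rng_vials.normal(
                        0.0, np.sqrt(p.V_vial_beta[sex]))
                    b100 = max(b100, beta100_floor)
                    la = (la_bar + rho * s_la * (b100 - beta_bar) / sd_beta100
                          + np.sqrt(1 - rho**2) * s_la
                          * rng_vials.standard_normal())
                    alpha, beta = float(np.exp(la)), b100 / 100.0
                    vid = vial_label(ct, line, sex, batch)
                    schedules.append(simulate_gompertz_cohort(
                        alpha, beta, config.n_flies_per_vial,
                        config.census_interval, max_age, rng_cohorts, vid))
                    rows.append((vid, f"{ct}{line:02d}", ct, sex, batch,
                                 alpha, beta))
    truth = pd.DataFrame(rows, columns=["vial_id", "line_id",
                                        "chromosome_type", "sex", "batch",
                                        "alpha", "beta"])
    return schedules, truth


def inject_outlier_vials(records: pd.DataFrame, fraction: float,
                         shift: float, target_sex: str = "F", seed=0,
                         floor: float = 1.0,
                         genetic_outliers: bool = False,
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Contaminate a random fraction of one sex's vials with shortened lifespans.

    By default affected vials are chosen uniformly at random across lines —
    an extrinsic (e.g., disease) effect with no genetic association.  With
    ``genetic_outliers=True`` vials are instead drawn only from the
    shortest-lived 30% of lines, creating a genuine genetic association for
    power checks of the line-group comparison.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    records = records.copy()
    rng = _rng(seed)
    sex_mask = records["sex"] == target_sex
    vials = records.loc[sex_mask, "vial_id"].unique()
    if fraction == 0 or vials.size == 0:
        return records, []
    if genetic_outliers:
        line_means = (records[sex_mask].groupby("line_id")["lifespan_days"]
                      .mean().sort_values())
        k = max(1, int(np.ceil(0.3 * len(line_means))))
        short_lines = set(line_means.index[:k])
        pool = records.loc[sex_mask
                           & records["line_id"].isin(short_lines),
                           "vial_id"].unique()
    else:
        pool = vials
    n_affected = int(np.ceil(fraction * vials.size))
    n_affected = min(n_affected, pool.size)
    affected = rng.choice(pool, size=n_affected, replace=False)
    mask = records["vial_id"].isin(affected)
    records.loc[mask, "lifespan_days"] = np.clip(
        records.loc[mask, "lifespan_days"] - shift, floor, None)
    return records, sorted(affected.tolist())


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df
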
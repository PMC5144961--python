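"""Derived quantitative-genetic statistics from fitted (co)variance components.

Hemiclone lines clone a haploid chromosome set, so the among-line variance
V_L estimates half the additive genetic variance for diploid complements
(V_A = 2·V_L) — except for X-linked variance in males, where hemizygosity
makes V_A = V_L.  Further derived quantities: the phenotypic sum
V_P = V_L + V_V + V_R, the mean-standardized CV_A = √V_A / mean, the
intersexual correlation r_MF = Cov_MF / √(V_LF·V_LM), male:female variance
ratios, the X-linkage proportion V_AX / (V_AX + V_AA), and the
ratio-of-ratios (CV_AMX/CV_AFX)/(CV_AMA/CV_AFA).

Every statistic is computed per posterior sample and only then summarized;
cross-model contrasts (X vs. A chains fitted separately) pair samples by a
seeded random permutation.  Heavy-tailed ratio posteriors are summarized by
median and interquartile range rather than mean ± SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_DIPLOID = {("A", "F"): 2.0, ("A", "M"): 2.0, ("X", "F"): 2.0,
            ("X", "M"): 1.0}


def _norm_ct(chromosome_type: str) -> str:
    ct = str(chromosome_type).upper()
    if ct in ("A", "AUTOSOME", "AUTOSOMES"):
        return "A"
    if ct == "X":
        return "X"
    raise ValueError(f"unknown chromosome type {chromosome_type!r}")


def additive_variance(V_L, chromosome_type: str, sex: str):
    """V_A from the line variance: 2·V_L, except V_L itself for the male X."""
    ct = _norm_ct(chromosome_type)
    if sex not in ("F", "M"):
        raise ValueError(f"unknown sex {sex!r}")
    V_L = np.asarray(V_L, dtype=float)
    if np.any(V_L < 0):
        raise ValueError("V_L must be non-negative")
    out = _DIPLOID[(ct, sex)] * V_L
    return float(out) if out.ndim == 0 else out


def phenotypic_variance(V_L, V_V=None, V_R=0.0):
    """V_P = V_L + V_V + V_R (V_V omitted for the aging model)."""
    V_L = np.asarray(V_L, dtype=float)
    out = V_L + np.asarray(V_R, dtype=float)
    if V_V is not None:
        out = out + np.asarray(V_V, dtype=float)
    return float(out) if out.ndim == 0 else out


def cv_a(V_A, mean):
    """Coefficient of additive genetic variation √V_A / mean (mean > 0)."""
    V_A = np.asarray(V_A, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be positive for CV_A")
    if np.any(V_A < 0):
        raise ValueError("V_A must be non-negative")
    out = np.sqrt(V_A) / mean
    return float(out) if out.ndim == 0 else out


def rmf(Cov_MF, V_LF, V_LM):
    """Intersexual additive genetic correlation Cov_MF / √(V_LF·V_LM)."""
    V_LF = np.asarray(V_LF, dtype=float)
    V_LM = np.asarray(V_LM, dtype=float)
    if np.any(V_LF <= 0) or np.any(V_LM <= 0):
        raise ValueError("r_MF undefined when a line variance is zero")
    out = np.asarray(Cov_MF, dtype=float) / np.sqrt(V_LF * V_LM)
    return float(out) if out.ndim == 0 else out


def rmf_samples(Cov_MF, V_LF, V_LM, tol: float = 0.0):
    """Per-sample r_MF with zero-variance samples dropped (count returned)."""
    Cov_MF = np.asarray(Cov_MF, float)
    V_LF = np.asarray(V_LF, float)
    V_LM = np.asarray(V_LM, float)
    ok = (V_LF > tol) & (V_LM > tol)
    vals = Cov_MF[ok] / np.sqrt(V_LF[ok] * V_LM[ok])
    return vals, int((~ok).sum())


def posterior_summary(samples, skewed: bool = False) -> dict:
    """Posterior mean ± SD with 95% equal-tail CI; median + IQR when skewed."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    q025, q25, med, q75, q975 = np.percentile(x, [2.5, 25, 50, 75, 97.5])
    out = {"n": int(x.size), "mean": float(x.mean()),
           "sd": float(x.std(ddof=1)), "median": float(med),
           "q25": float(q25), "q75": float(q75),
           "ci_low": float(q025), "ci_high": float(q975),
           "skewed": bool(skewed)}
    out["estimate"] = out["median"] if skewed else out["mean"]
    out["spread"] = (out["q75"] - out["q25"]) if skewed else out["sd"]
    return out


def chain_difference(chain_a, chain_b, seed=0, permute: bool = True) -> dict:
    """Posterior of a − b for independently fitted models.

    Samples are paired by one random permutation of ``chain_b`` (the two
    chains were run separately, so any pairing is exchangeable); reports the
    element-wise differences and the fraction of differences ≥ 0.
    ``permute=False`` keeps the stored order (identity pairing).
    """
    a = np.asarray(chain_a, dtype=float)
    b = np.asarray(chain_b, dtype=float)
    rng = np.random.default_rng(seed)
    resampled = False
    if a.size != b.size:
        resampled = True
        m = max(a.size, b.size)
        if a.size < m:
            a = rng.choice(a, size=m, replace=True)
        else:
            b = rng.choice(b, size=m, replace=True)
    if permute:
        b = b[rng.permutation(b.size)]
    diff = a - b
    return {"samples": diff, "frac_ge_0": float(np.mean(diff >= 0)),
            "summary": posterior_summary(diff), "resampled": resampled}


def x_linkage_proportion(V_A_X, V_A_A) -> dict:
    """Per-sample V_AX / (V_AX + V_AA), with genome-share reference points."""
    from . import reference
    vx = np.asarray(V_A_X, dtype=float)
    va = np.asarray(V_A_A, dtype=float)
    if vx.shape != va.shape:
        raise ValueError("samples must be paired (equal length)")
    denom = vx + va
    ok = denom > 0
    props = vx[ok] / denom[ok]
    return {"samples": props, "n_dropped": int((~ok).sum()),
            "summary": posterior_summary(props),
            "reference": {"euchromatin": reference.X_FRACTION_EUCHROMATIN,
                          "genes": reference.X_FRACTION_GENES}}


def _ratio(num, den, label: str) -> dict:
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    ok = den > 0
    dropped = int((~ok).sum())
    if dropped > 0.10 * den.size:
        warnings.warn(f"{label}: {dropped} of {den.size} samples dropped "
                      "for non-positive denominator", stacklevel=3)
    vals = num[ok] / den[ok]
    return {"samples": vals, "n_dropped": dropped,
            "summary": posterior_summary(vals, skewed=True)}


def ratio_stats(V_A: dict, CV_A: dict, seed=0) -> dict:
    """Male:female ratios of V_A and CV_A per chromosome type, and the
    cross-type ratio-of-ratios (CV_AMX/CV_AFX)/(CV_AMA/CV_AFA).

    ``V_A`` and ``CV_A`` map (chromosome_type, sex) to posterior sample
    vectors; X and A models were fitted separately, so the cross-type ratio
    pairs samples through a seeded random permutation.
    """
    out = {}
    for ct in ("A", "X"):
        out[f"VA_ratio_MF_{ct}"] = _ratio(V_A[(ct, "M")], V_A[(ct, "F")],
                                          f"V_A M:F ratio ({ct})")
        out[f"CVA_ratio_MF_{ct}"] = _ratio(CV_A[(ct, "M")], CV_A[(ct, "F")],
                                           f"CV_A M:F ratio ({ct})")
    rx = out["CVA_ratio_MF_X"]["samples"]
    ra = out["CVA_ratio_MF_A"]["samples"]
    rng = np.random.default_rng(seed)
    m = min(rx.size, ra.size)
    rx = rng.choice(rx, size=m, replace=False) if rx.size > m else rx
    ra = rng.choice(ra, size=m, replace=False) if ra.size > m else ra
    out["CVA_ratio_of_ratios"] = _ratio(rx, ra[rng.permutation(m)],
                                        "CV_A ratio of ratios")
    return out


# ----------------------------------------------------------- chain -> stats

@dataclass
class DerivedStats:
    """Posterior vectors + summaries of all derived quantities for one trait."""

    trait: str
    per_cell: dict = field(default_factory=dict)   # (ct, sex) -> {name: summary}
    rmf: dict = field(default_factory=dict)        # ct -> summary
    contrasts: dict = field(default_factory=dict)  # name -> summary/dict
    samples: dict = field(default_factory=dict)    # name -> vector
    provenance: dict = field(default_factory=dict)


def derive_stats(chains: dict, trait: str = "lifespan", seed: int = 0,
                 ) -> DerivedStats:
    """Compute all derived statistics from per-line-type posterior chains.

    ``chains`` maps chromosome type ('A', 'X') to a
    :class:`~hemivar.mixed_model.PosteriorChain` (or its samples frame).
    Statistics are computed per retained sample and then summarized.
    """
    out = DerivedStats(trait=trait)
    vial = None
    V_A_samp: dict = {}
    CV_A_samp: dict = {}
    for ct, chain in chains.items():
        df = chain.samples if hasattr(chain, "samples") else chain
        vial = "V_V_F" in df.columns
        for sex in ("F", "M"):
            V_L = df[f"V_L_{sex}"].to_numpy()
            V_R = df[f"V_R_{sex}"].to_numpy()
            V_V = df[f"V_V_{sex}"].to_numpy() if vial else None
            mean = df[f"trait{sex}"].to_numpy()
            V_A = additive_variance(V_L, ct, sex)
            V_P = phenotypic_variance(V_L, V_V, V_R)
            ok = mean > 0
            CV = np.full_like(V_A, np.nan)
            CV[ok] = np.sqrt(V_A[ok]) / mean[ok]
            cell = {"mean": posterior_summary(mean),
                    "V_L": posterior_summary(V_L),
                    "V_R": posterior_summary(V_R),
                    "V_P": posterior_summary(V_P),
                    "V_A": posterior_summary(V_A),
                    "CV_A": posterior_summary(CV[ok])}
            if vial:
                cell["V_V"] = posterior_summary(V_V)
            out.per_cell[(ct, sex)] = cell
            V_A_samp[(ct, sex)] = V_A
            CV_A_samp[(ct, sex)] = CV[ok]
            out.samples[f"V_A_{ct}_{sex}"] = V_A
        r_vals, r_dropped = rmf_samples(df["Cov_MF"].to_numpy(),
                                        df["V_L_F"].to_numpy(),
                                        df["V_L_M"].to_numpy())
        out.rmf[ct] = posterior_summary(r_vals)
        out.rmf[ct]["n_dropped"] = r_dropped
        out.samples[f"rmf_{ct}"] = r_vals
        out.provenance[ct] = {
            "n_samples": len(df),
            "seed": getattr(chain, "seed", None),
        }

    if set(chains) >= {"A", "X"}:
        rng_seeds = np.random.SeedSequence(seed).spawn(4)
        for sex, ss in zip(("F", "M"), rng_seeds[:2]):
            nx = V_A_samp[("X", sex)]
            na = V_A_samp[("A", sex)]
            m = min(nx.size, na.size)
            perm = np.random.default_rng(ss).permutation(na.size)[:m]
            out.contrasts[f"x_linkage_{sex}"] = x_linkage_proportion(
                nx[:m], na[perm])
        out.contrasts["ratios"] = ratio_stats(
            V_A_samp, CV_A_samp,
            seed=int(rng_seeds[2].generate_state(1)[0] % (2**31)))
        rx, ra = out.samples["rmf_X"], out.samples["rmf_A"]
        out.contrasts["rmf_X_minus_A"] = chain_difference(
            rx, ra, seed=int(rng_seeds[3].generate_state(1)[0] % (2**31)))
    return out


def plug_in_cell(V_L_mean: float, V_V_mean: float | None, V_R_mean: float,
                 mean: float, ct: str, sex: str) -> dict:
    """Plug-in (posterior-mean) derived values, for published-table checks."""
    V_A = additive_variance(V_L_mean, ct, sex)
    return {"V_A": V_A,
            "V_P": phenotypic_variance(V_L_mean, V_V_mean, V_R_mean),
            "CV_A": cv_a(V_A, mean)}


def stats_to_report(stats: DerivedStats) -> dict:
    """JSON-serializable report of all summaries (no raw sample vectors)."""
    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()
                    if k != "samples"}
        if isinstance(obj, (np.floating, np.integer)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    return {"trait": stats.trait,
            "cells": {f"{ct}_{sex}": clean(c)
                      for (ct, sex), c in stats.per_cell.items()},
            "rmf": clean(stats.rmf),
            "contrasts": clean(stats.contrasts),
            "provenance": clean(stats.provenance)}
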
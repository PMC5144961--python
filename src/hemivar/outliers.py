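"""Outlier-vial detection and the genetic-association check.

A small group of vials with unusually short-lived females (a bimodal
per-vial mean distribution, consistent with an extrinsic cause such as
disease) is flagged by a fixed threshold on the vial mean — strictly below
51 d by default, ties kept.  Whether flagged vials track genotype is then
tested by comparing, across lines, mean female lifespan of lines without a
flagged vial against lines with one (flagged vials excluded first), using a
one-tailed pooled-variance two-sample t-test in the direction
"without > with".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLD = 51.0


def vial_summaries(records: pd.DataFrame,
                   response: str = "lifespan_days") -> pd.DataFrame:
    """Per-vial mean lifespan and fly count."""
    g = records.groupby("vial_id", sort=True)
    out = g.agg(line_id=("line_id", "first"), sex=("sex", "first"),
                batch=("batch", "first"), mean_lifespan=(response, "mean"),
                n_flies=(response, "size")).reset_index()
    if "chromosome_type" in records.columns:
        out["chromosome_type"] = g["chromosome_type"].first().to_numpy()
    return out


def detect_outlier_vials(summaries: pd.DataFrame,
                         threshold: float = DEFAULT_THRESHOLD,
                         sex_filter: str = "F",
                         bin_width: float = 2.0) -> dict:
    """Flag vials of one sex whose mean lifespan falls strictly below threshold.

    Also reports a simple bimodality diagnostic: the histogram of per-vial
    means (``bin_width``-day bins) and the emptiest bin ("dip") between the
    lower and upper modes, as a visual-threshold sanity check.
    """
    if summaries.empty:
        raise ValueError("no vial summaries provided")
    sub = summaries[summaries["sex"] == sex_filter]
    means = sub["mean_lifespan"].to_numpy()
    flagged = sorted(sub.loc[means < threshold, "vial_id"].tolist())
    diag = {}
    if means.size:
        lo = np.floor(means.min() / bin_width) * bin_width
        hi = np.ceil(means.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(means, bins=edges)
        occupied = np.flatnonzero(counts > 0)
        dip = None
        if occupied.size >= 2:
            interior = counts[occupied[0]:occupied[-1] + 1]
            j = int(np.argmin(interior)) + occupied[0]
            dip = {"bin_start": float(edges[j]), "bin_end": float(edges[j + 1]),
                   "count": int(counts[j])}
        diag = {"bin_edges": edges.tolist(), "counts": counts.tolist(),
                "dip": dip}
    return {"flagged": flagged, "threshold": float(threshold),
            "sex": sex_filter, "diagnostic": diag}


def line_group_test(line_means_without, line_means_with) -> dict:
    """One-tailed pooled-variance t-test: lines without flagged vials vs. with.

    Pooled (Student) t with df = n1 + n2 − 2; the one-tailed alternative is
    that lines *without* a flagged vial are longer-lived.  Returns t, df,
    one-tailed p and the mean difference (without − with).
    """
    a = np.asarray(line_means_without, dtype=float)
    b = np.asarray(line_means_with, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each line group needs at least 2 lines")
    res = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    return {"t": float(res.statistic), "df": int(a.size + b.size - 2),
            "p": float(res.pvalue), "mean_difference": float(a.mean() - b.mean()),
            "n_without": int(a.size), "n_with": int(b.size)}


def outlier_analysis(records: pd.DataFrame,
                     threshold: float = DEFAULT_THRESHOLD,
                     sex_filter: str = "F",
                     response: str = "lifespan_days",
                     group_by_type: bool = True) -> dict:
    """Full outlier procedure: flag vials, then test for genetic association.

    Line means are computed from the filtered sex *after removing* flagged
    vials; the t-test compares lines without vs. with a flagged vial, within
    each chromosome type and for all lines pooled.  Returns the flag report,
    the association tests, and the records with flagged vials removed.
    """
    summaries = vial_summaries(records, response=response)
    report = detect_outlier_vials(summaries, threshold=threshold,
                                  sex_filter=sex_filter)
    flagged = set(report["flagged"])
    kept = records[~records["vial_id"].isin(flagged)]
    tests = {}
    sub = summaries[summaries["sex"] == sex_filter]
    lines_with = set(sub.loc[sub["vial_id"].isin(flagged), "line_id"])
    clean = sub[~sub["vial_id"].isin(flagged)]
    line_means = clean.groupby("line_id")["mean_lifespan"].mean()
    groups = []
    if group_by_type and "chromosome_type" in summaries.columns:
        for ct, ct_sub in sub.groupby("chromosome_type"):
            groups.append((f"{ct}-lines", set(ct_sub["line_id"])))
    groups.append(("all-lines", set(sub["line_id"])))
    for label, line_set in groups:
        with_ids = sorted(line_set & lines_with)
        without_ids = sorted(line_set - lines_with)
        wm = line_means.reindex(with_ids).dropna()
        wo = line_means.reindex(without_ids).dropna()
        if len(wm) >= 2 and len(wo) >= 2:
            tests[label] = line_group_test(wo.to_numpy(), wm.to_numpy())
        else:
            tests[label] = {"skipped": "fewer than 2 lines in a group",
                            "n_without": len(wo), "n_with": len(wm)}
    return {"report": report, "tests": tests, "records_filtered": kept,
            "n_removed_vials": len(flagged),
            "n_removed_records": int(len(records) - len(kept))}
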
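"""Design matrices and sufficient statistics for the mixed models.

Fixed effects, line effects and vial effects are all constant within a vial,
so the Gaussian likelihood depends on individual flies only through each
vial's fly count, mean and within-vial sum of squares.  Collapsing to those
sufficient statistics makes both the Gibbs sampler and the REML objective
O(number of vials) per evaluation instead of O(number of flies).

The fixed-effect design follows the multi-response convention: one intercept
per trait (sex), plus centered batch dummies for batches 2..B crossed with
trait, so the intercept estimates each sex's grand mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CollapsedData:
    """Vial-level sufficient statistics plus index maps."""

    vial_id: np.ndarray          # (nv,) str
    line_id: np.ndarray          # (nv,) str
    line_idx: np.ndarray         # (nv,) int in [0, L)
    sex_idx: np.ndarray          # (nv,) int in [0, T)
    batch: np.ndarray            # (nv,) int
    n: np.ndarray                # (nv,) flies per vial
    ybar: np.ndarray             # (nv,) vial mean response
    ss: np.ndarray               # (nv,) within-vial sum of squares
    X: np.ndarray                # (nv, p) fixed-effect design (vial level)
    columns: list[str]
    lines: list[str]
    sexes: list[str]

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_traits(self) -> int:
        return len(self.sexes)

    @property
    def n_obs(self) -> int:
        return int(self.n.sum())

    def per_sex_counts(self) -> np.ndarray:
        return np.array([self.n[self.sex_idx == t].sum()
                         for t in range(self.n_traits)], dtype=float)

    def per_sex_ssw(self) -> np.ndarray:
        return np.array([self.ss[self.sex_idx == t].sum()
                         for t in range(self.n_traits)])


def collapse_records(records: pd.DataFrame,
                     response: str = "lifespan_days") -> pd.DataFrame:
    """Reduce individual records to one row per vial (n, mean, within-SS)."""
    work = records.assign(_sq=records[response] ** 2)
    g = work.groupby("vial_id", sort=True)
    out = g.agg(line_id=("line_id", "first"), sex=("sex", "first"),
                batch=("batch", "first"), n=(response, "size"),
                ybar=(response, "mean"), _sumsq=("_sq", "sum"))
    out["ss"] = np.maximum(out["_sumsq"] - out["n"] * out["ybar"] ** 2, 0.0)
    out = out.drop(columns="_sumsq")
    if "chromosome_type" in records.columns:
        out["chromosome_type"] = g["chromosome_type"].first()
    return out.reset_index()


def build_design(vials: pd.DataFrame, sexes: list[str] | None = None,
                 ) -> tuple[np.ndarray, list[str]]:
    """Vial-level fixed-effect design: per-sex intercepts + centered batch dummies.

    Dummies for batches 2..B are centered by subtracting their fly-weighted
    column mean (computed over all observations), then crossed with sex, so
    each sex's intercept is its grand mean.  Raises on rank deficiency,
    naming the collinear columns; with a single batch the dummies are
    dropped with a warning.
    """
    if sexes is None:
        sexes = sorted(vials["sex"].unique())
    n = vials["n"].to_numpy(dtype=float)
    batches = sorted(vials["batch"].unique())
    cols, names = [], []
    for s in sexes:
        cols.append((vials["sex"] == s).to_numpy(dtype=float))
        names.append(f"trait{s}")
    if len(batches) < 2:
        warnings.warn("single batch: batch dummies dropped", stacklevel=2)
    else:
        for b in batches[1:]:
            dummy = (vials["batch"] == b).to_numpy(dtype=float)
            centered = dummy - np.average(dummy, weights=n)
            for s in sexes:
                cols.append(centered * (vials["sex"] == s).to_numpy(float))
                names.append(f"trait{s}:batch{b}")
    X = np.column_stack(cols)
    Xw = X * np.sqrt(n)[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(Xw)
        bad = [names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"rank-deficient fixed-effect design; "
                         f"collinear columns: {bad}")
    return X, names


def build_collapsed(records: pd.DataFrame, response: str = "lifespan_days",
                    sexes: list[str] | None = None) -> CollapsedData:
    """Collapse records and assemble index maps + fixed-effect design."""
    vials = collapse_records(records, response)
    if sexes is None:
        sexes = sorted(vials["sex"].unique())
    lines = sorted(vials["line_id"].unique())
    line_pos = {l: i for i, l in enumerate(lines)}
    sex_pos = {s: i for i, s in enumerate(sexes)}
    X, names = build_design(vials, sexes)
    return CollapsedData(
        vial_id=vials["vial_id"].to_numpy(),
        line_id=vials["line_id"].to_numpy(),
        line_idx=vials["line_id"].map(line_pos).to_numpy(),
        sex_idx=vials["sex"].map(sex_pos).to_numpy(),
        batch=vials["batch"].to_numpy(),
        n=vials["n"].to_numpy(dtype=float),
        ybar=vials["ybar"].to_numpy(dtype=float),
        ss=vials["ss"].to_numpy(dtype=float),
        X=X, columns=names, lines=lines, sexes=list(sexes))


def check_identifiable(data: CollapsedData, vial_term: bool = True) -> None:
    """Reject designs where vial and residual variance are confounded.

    With one fly per vial (or one vial total per stratum) the vial effect is
    indistinguishable from the residual; the Gibbs sampler and REML both
    require the check to pass when a vial component is requested.
    """
    if vial_term and np.all(data.n <= 1):
        raise ValueError("non-identifiable: one fly per vial confounds vial "
                         "and residual variance; drop the vial term")
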
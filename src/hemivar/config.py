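"""Study-design and generative-parameter configuration.

The dataclasses here describe the hemiclone experiment: how many
chromosome-substitution lines of each type, how many batches and flies per
vial, and the Gaussian variance structure (line / vial / residual) that the
lifespan model assumes.  Defaults reproduce the published study conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import reference

SEXES = ("F", "M")
CHROM_TYPES = ("A", "X")


@dataclass
class DesignConfig:
    """Sampling design of the lifespan/aging assay.

    One vial of ``n_flies_per_vial`` flies per line × sex × batch, mortality
    scored every ``census_interval`` days.
    """

    n_lines_per_type: int = 40
    n_batches: int = 4
    n_flies_per_vial: int = 50
    census_interval: float = 2.0
    sexes: tuple[str, ...] = SEXES
    chromosome_types: tuple[str, ...] = CHROM_TYPES

    def __post_init__(self) -> None:
        for name in ("n_lines_per_type", "n_batches", "n_flies_per_vial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.census_interval <= 0:
            raise ValueError("census_interval must be positive")
        self.sexes = tuple(self.sexes)
        self.chromosome_types = tuple(self.chromosome_types)
        for s in self.sexes:
            if s not in SEXES:
                raise ValueError(f"unknown sex {s!r}")
        for c in self.chromosome_types:
            if c not in CHROM_TYPES:
                raise ValueError(f"unknown chromosome type {c!r}")

    @property
    def n_records(self) -> int:
        return (self.n_lines_per_type * len(self.chromosome_types)
                * len(self.sexes) * self.n_batches * self.n_flies_per_vial)


@dataclass
class GeneticParams:
    """Gaussian variance structure for one chromosome type.

    ``G`` is the 2×2 cross-sex line (co)variance matrix
    [[V_LF, Cov_MF], [Cov_MF, V_LM]] in days²; vial and residual components
    are per-sex (F, M) variances.  ``batch_effects`` are fixed deviations per
    sex that must sum to zero within each sex (the model's centered-dummy
    convention makes the intercept the grand mean).
    """

    grand_mean: dict[str, float]
    G: np.ndarray
    V_V: dict[str, float]
    V_R: dict[str, float]
    batch_effects: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (2, 2) or not np.allclose(self.G, self.G.T):
            raise ValueError("G must be a symmetric 2x2 matrix")
        w = np.linalg.eigvalsh(self.G)
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ValueError(
                f"G is not positive semidefinite (eigenvalue {w.min():.6g})")
        for s, v in self.V_V.items():
            if v < 0:
                raise ValueError(f"V_V[{s}] must be >= 0")
        for s, v in self.V_R.items():
            if v <= 0:
                raise ValueError(f"V_R[{s}] must be > 0")
        if not self.batch_effects:
            self.batch_effects = {s: np.zeros(4) for s in self.grand_mean}
        for s, b in self.batch_effects.items():
            b = np.asarray(b, dtype=float)
            if abs(b.sum()) > 1e-8 * max(1.0, np.abs(b).max()):
                raise ValueError(f"batch effects for sex {s} must sum to zero")
            self.batch_effects[s] = b

    @classmethod
    def from_components(cls, means: dict[str, float], V_L: dict[str, float],
                        r_mf: float, V_V: dict[str, float],
                        V_R: dict[str, float],
                        batch_effects: dict[str, np.ndarray] | None = None,
                        ) -> "GeneticParams":
        cov = r_mf * np.sqrt(V_L["F"] * V_L["M"])
        G = np.array([[V_L["F"], cov], [cov, V_L["M"]]])
        return cls(grand_mean=dict(means), G=G, V_V=dict(V_V), V_R=dict(V_R),
                   batch_effects=batch_effects or {})


def default_lifespan_params(batch_effects: dict[str, np.ndarray] | None = None,
                            ) -> dict[str, GeneticParams]:
    """Study-condition lifespan parameters, keyed by chromosome type.

    Batch effects default to a modest spread (±2 d) summing to zero; the
    published analysis estimated batch as fixed effects but does not report
    their magnitudes.
    """
    if batch_effects is None:
        batch_effects = {s: np.array([-2.0, -0.5, 0.5, 2.0]) for s in SEXES}
    out = {}
    for ct in CHROM_TYPES:
        t1 = reference.TABLE1["lifespan"][ct]
        out[ct] = GeneticParams.from_components(
            means={s: t1[s]["mean"] for s in SEXES},
            V_L={s: t1[s]["V_L"] for s in SEXES},
            r_mf=reference.RMF["lifespan"][ct],
            V_V={s: t1[s]["V_V"] for s in SEXES},
            V_R={s: t1[s]["V_R"] for s in SEXES},
            batch_effects={s: np.asarray(b, float).copy()
                           for s, b in batch_effects.items()},
        )
    return out


@dataclass
class AgingParams:
    """Generative parameters for the per-vial demographic aging path.

    Mean aging rates and line/vial variances are on the β × 100 scale
    (Gompertz hazard μ(t) = α·exp(βt)).  ``log_alpha_sd`` and
    ``log_alpha_beta_corr`` control the joint (log α, β) distribution across
    vials; the strong negative correlation mirrors the compensation between
    baseline mortality and aging rate seen in demographic data.
    """

    beta_mean: dict[str, float]
    V_L_beta: dict[str, float]
    r_mf: float
    V_vial_beta: dict[str, float]
    log_alpha_sd: float = 0.6
    log_alpha_beta_corr: float = -0.9

    def line_G(self) -> np.ndarray:
        cov = self.r_mf * np.sqrt(self.V_L_beta["F"] * self.V_L_beta["M"])
        return np.array([[self.V_L_beta["F"], cov],
                         [cov, self.V_L_beta["M"]]])


def default_aging_params() -> dict[str, AgingParams]:
    out = {}
    for ct in CHROM_TYPES:
        t1 = reference.TABLE1["aging"][ct]
        out[ct] = AgingParams(
            beta_mean={s: t1[s]["mean"] for s in SEXES},
            V_L_beta={s: t1[s]["V_L"] for s in SEXES},
            r_mf=reference.RMF["aging"][ct],
            V_vial_beta={s: t1[s]["V_R"] for s in SEXES},
        )
    return out


def params_to_dict(params: dict[str, GeneticParams]) -> dict:
    out = {}
    for ct, p in params.items():
        out[ct] = {
            "grand_mean": {s: float(v) for s, v in p.grand_mean.items()},
            "V_L": {s: float(p.G[i, i])
                    for i, s in enumerate(sorted(p.grand_mean))},
            "Cov_MF": float(p.G[0, 1]),
            "V_V": {s: float(v) for s, v in p.V_V.items()},
            "V_R": {s: float(v) for s, v in p.V_R.items()},
            "batch_effects": {s: [float(x) for x in b]
                              for s, b in p.batch_effects.items()},
        }
    return out


def params_from_dict(raw: dict) -> dict[str, GeneticParams]:
    out = {}
    for ct, d in raw.items():
        sexes = sorted(d["grand_mean"])
        G = np.zeros((2, 2))
        for i, s in enumerate(sexes):
            G[i, i] = d["V_L"][s]
        G[0, 1] = G[1, 0] = d.get("Cov_MF", 0.0)
        out[ct] = GeneticParams(
            grand_mean=dict(d["grand_mean"]), G=G, V_V=dict(d["V_V"]),
            V_R=dict(d["V_R"]),
            batch_effects={s: np.asarray(b, float)
                           for s, b in d.get("batch_effects", {}).items()})
    return out


def save_params(params: dict[str, GeneticParams], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def load_params(path) -> dict[str, GeneticParams]:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def design_to_dict(config: DesignConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sexes"] = list(config.sexes)
    d["chromosome_types"] = list(config.chromosome_types)
    return d


def load_design(path) -> DesignConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return DesignConfig(**raw)


def save_design(config: DesignConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(config), fh, sort_keys=False)
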
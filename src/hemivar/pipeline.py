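"""End-to-end analysis: simulate or ingest → outlier filter → lifespan model
→ per-vial Gompertz fits → aging model → derived statistics → report.

Every stage draws its randomness from a child stream spawned from one
master seed, and every artifact is written as CSV/JSON under the run's
output directory, so a run is fully reproducible from its configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfg
from . import outliers as outl
from . import quantgen
from .design import build_collapsed
from .gompertz import fit_gompertz_many, fits_to_frame, log_alpha_beta_correlation, schedules_to_frame
from .mixed_model import ChainConfig, ModelSpec, PosteriorChain, PriorSpec, gelman_rubin, run_gibbs
from .reml import reml_fit
from .synthetic import read_records, simulate_aging_design, simulate_lifespans, write_records

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulate, or ingest a data file)."""

    output_dir: str = "hemivar_run"
    master_seed: int = 0
    input_records: str | None = None
    design: cfg.DesignConfig = field(default_factory=cfg.DesignConfig)
    outlier_threshold: float = outl.DEFAULT_THRESHOLD
    skip_outliers: bool = False
    include_aging: bool = True
    paper_scale: bool = False
    n_chains: int = 2
    prior: PriorSpec = field(default_factory=PriorSpec)
    lifespan_params: dict | None = None    # chromosome type -> GeneticParams
    aging_params: dict | None = None       # chromosome type -> AgingParams
    chain_template: ChainConfig | None = None

    def chain_config(self, seed: int) -> ChainConfig:
        if self.chain_template is not None:
            t = self.chain_template
            return ChainConfig(iterations=t.iterations, burn_in=t.burn_in,
                               thin=t.thin, n_chains=self.n_chains, seed=seed)
        if self.paper_scale:
            return ChainConfig(seed=seed, n_chains=self.n_chains)
        return ChainConfig.reduced(seed=seed, n_chains=self.n_chains)


def _child_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(run: RunConfig) -> dict:
    """Execute the full analysis; returns a report dict (also written as JSON)."""
    out = Path(run.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ["sim_lifespan", "sim_aging", "chains", "derive"],
        _child_seeds(run.master_seed, 4)))
    report: dict = {"seeds": seeds, "artifacts": {}, "master_seed":
                    run.master_seed}
    stage = "simulate/ingest"
    try:
        if run.input_records:
            records = read_records(run.input_records)
        else:
            params = run.lifespan_params or cfg.default_lifespan_params()
            records = simulate_lifespans(run.design, params,
                                         seed=seeds["sim_lifespan"])
        rec_path = out / "records.csv"
        write_records(records, rec_path)
        report["artifacts"]["records"] = str(rec_path)
        report["n_records"] = int(len(records))

        stage = "outliers"
        if run.skip_outliers:
            filtered = records
            report["outliers"] = {"skipped": True}
        else:
            oa = outl.outlier_analysis(records,
                                       threshold=run.outlier_threshold)
            filtered = oa["records_filtered"]
            report["outliers"] = {
                "flagged": oa["report"]["flagged"],
                "n_removed_vials": oa["n_removed_vials"],
                "tests": oa["tests"]}
            filt_path = out / "records_filtered.csv"
            write_records(filtered, filt_path)
            report["artifacts"]["records_filtered"] = str(filt_path)

        stage = "lifespan model"
        chain_seeds = _child_seeds(seeds["chains"], 4 * run.n_chains)
        chains_by_ct: dict[str, list[PosteriorChain]] = {}
        gr_tables = []
        si = 0
        for ct in sorted(filtered["chromosome_type"].unique()):
            sub = filtered[filtered["chromosome_type"] == ct]
            data = build_collapsed(sub, response="lifespan_days")
            spec = ModelSpec(trait="lifespan", vial_term=True)
            chains = []
            for j in range(run.n_chains):
                ccfg = run.chain_config(chain_seeds[si]); si += 1
                ch = run_gibbs(spec, run.prior, ccfg, data)
                path = out / f"chain_lifespan_{ct}_{j + 1}.csv"
                ch.save(path)
                report["artifacts"][f"chain_lifespan_{ct}_{j + 1}"] = str(path)
                chains.append(ch)
            chains_by_ct[ct] = chains
            if len(chains) >= 2:
                gr = gelman_rubin(chains)
                gr.insert(0, "model", f"lifespan_{ct}")
                gr_tables.append(gr)

        stage = "gompertz fits"
        derived: dict[str, quantgen.DerivedStats] = {}
        derived["lifespan"] = quantgen.derive_stats(
            {ct: chs[0] for ct, chs in chains_by_ct.items()},
            trait="lifespan", seed=seeds["derive"])

        if run.include_aging:
            schedules, truth = simulate_aging_design(
                run.design, params=run.aging_params,
                seed=seeds["sim_aging"])
            sched_path = out / "mortality_schedules.csv"
            schedules_to_frame(schedules).to_csv(sched_path, index=False)
            fits = fit_gompertz_many(schedules)
            fits_df = fits_to_frame(fits)
            fit_path = out / "gompertz_fits.csv"
            fits_df.to_csv(fit_path, index=False)
            report["artifacts"]["gompertz_fits"] = str(fit_path)
            report["gompertz"] = {
                "n_vials": len(fits),
                "n_converged": int(fits_df["converged"].sum()),
                "log_alpha_beta": log_alpha_beta_correlation(fits)}

            stage = "aging model"
            meta = truth.set_index("vial_id")[["line_id", "chromosome_type",
                                               "sex", "batch"]]
            aging = fits_df[fits_df["converged"]].join(
                meta, on="vial_id")[["vial_id", "line_id",
                                     "chromosome_type", "sex", "batch",
                                     "beta_x100"]]
            aging_chains: dict[str, list[PosteriorChain]] = {}
            for ct in sorted(aging["chromosome_type"].unique()):
                sub = aging[aging["chromosome_type"] == ct]
                spec = ModelSpec(trait="aging", vial_term=False)
                chains = []
                for j in range(run.n_chains):
                    ccfg = run.chain_config(chain_seeds[si]); si += 1
                    ch = run_gibbs(spec, run.prior, ccfg, sub,
                                   response="beta_x100")
                    path = out / f"chain_aging_{ct}_{j + 1}.csv"
                    ch.save(path)
                    report["artifacts"][f"chain_aging_{ct}_{j + 1}"] = str(path)
                    chains.append(ch)
                aging_chains[ct] = chains
                if len(chains) >= 2:
                    gr = gelman_rubin(chains)
                    gr.insert(0, "model", f"aging_{ct}")
                    gr_tables.append(gr)
            derived["aging"] = quantgen.derive_stats(
                {ct: chs[0] for ct, chs in aging_chains.items()},
                trait="aging", seed=seeds["derive"] + 1)

        stage = "report"
        if gr_tables:
            gr_all = pd.concat(gr_tables, ignore_index=True)
            gr_path = out / "gelman_rubin.csv"
            gr_all.to_csv(gr_path, index=False)
            report["artifacts"]["gelman_rubin"] = str(gr_path)
            report["gelman_rubin_max_upper"] = float(gr_all["upper"].max())

        table = make_table1(derived)
        tab_path = out / "table1.csv"
        table.to_csv(tab_path, index=False)
        report["artifacts"]["table1"] = str(tab_path)

        report["derived"] = {t: quantgen.stats_to_report(d)
                             for t, d in derived.items()}
        rep_path = out / "report.json"
        with open(rep_path, "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        report["artifacts"]["report"] = str(rep_path)
        return report
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err


_ROWS = {"lifespan": ["mean", "V_L", "V_V", "V_R", "V_P", "V_A", "CV_A"],
         "aging": ["mean", "V_L", "V_R", "V_P", "V_A", "CV_A"]}
_CELLS = [("A", "F"), ("A", "M"), ("X", "F"), ("X", "M")]


def make_table1(derived: dict) -> pd.DataFrame:
    """Summary table: component × (chromosome type, sex), lifespan block with
    a vial-variance row, aging block without one; entries "estimate ± SE"
    with separate credible-interval columns.  Missing line types leave
    explicit gaps."""
    rows = []
    for trait, stats in derived.items():
        for quantity in _ROWS[trait]:
            row: dict = {"trait": trait, "quantity": quantity}
            for ct, sex in _CELLS:
                key, ci_key = f"{ct}-{sex}", f"{ct}-{sex}_ci"
                cell = stats.per_cell.get((ct, sex)) if stats else None
                if cell is None or quantity not in cell:
                    row[key], row[ci_key] = "", ""
                    continue
                s = cell[quantity]
                row[key] = f"{s['mean']:.2f} ± {s['sd']:.2f}"
                row[ci_key] = f"{s['ci_low']:.2f}–{s['ci_high']:.2f}"
            rows.append(row)
    return pd.DataFrame(rows)


def reml_report(records: pd.DataFrame, response: str = "lifespan_days",
                vial_term: bool = True) -> dict:
    """Unconstrained REML fit (per line type) as a JSON-friendly dict."""
    fit = reml_fit(records, response=response, vial_term=vial_term)
    return {"components": fit.components, "beta": fit.beta,
            "loglik": fit.loglik, "converged": fit.converged}
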
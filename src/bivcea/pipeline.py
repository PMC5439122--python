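"""End-to-end orchestration: data -> costing -> fits -> MCMC -> CEA.

``run_pipeline`` chains the stages, writes every result as JSON plus a
plain-text report and CE-plane figures, and maintains a manifest marking
which stages completed (partial outputs are retained on failure).
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import (
    budget_impact,
    ce_plane_summary,
    decompose_costs,
    icer_or_flag,
    plot_ce_plane,
    subgroup_analysis,
)
from .config import ModelSpec, PipelineConfig
from .costing import EventList, cost_patients, intervention_cost_per_patient, load_unit_cost_tables
from .igls import did_estimand, fit_bmlm
from .io import load_patient_table, write_json, write_patient_table, report_table
from .mcmc import sample_posterior
from .simulate import generate_dataset

__all__ = ["run_pipeline"]

log = logging.getLogger("bivcea")

STAGES = [
    "data",
    "costing",
    "crude_fit",
    "adjusted_fit",
    "mcmc",
    "ce_plane",
    "subgroups",
    "decomposition",
    "budget_impact",
    "sensitivity",
    "report",
]


def _recost(df: pd.DataFrame, events_path, tables, schedule: str) -> pd.DataFrame:
    ev_df = pd.read_csv(events_path)
    if not {"patient_id", "event_code"} <= set(ev_df.columns):
        raise ValueError("events table needs patient_id and event_code columns")
    events = [
        EventList(str(pid), list(grp["event_code"]))
        for pid, grp in ev_df.groupby("patient_id", sort=True)
    ]
    costs = cost_patients(events, tables[schedule]).set_index("patient_id")
    out = df.copy()
    keys = df.index.astype(str)
    for col in ("delivery_cost", "maternal_cost", "neonatal_cost", "total_cost"):
        out[col] = costs.loc[keys, col].to_numpy()
    return out


def _analyse(df: pd.DataFrame, config: PipelineConfig, outdir: Path, tag: str,
             manifest: dict, seed: int) -> dict:
    """Model stages on one costed dataset; returns the result dict."""
    results: dict = {}

    crude = fit_bmlm(df, ModelSpec(adjusted=False, restricted=config.model.restricted))
    results["crude"] = {"fit": crude.to_dict(), "did": did_estimand(crude).to_dict()}
    manifest[f"crude_fit{tag}"] = "complete"

    adj_spec = config.model
    adjusted = fit_bmlm(df, adj_spec)
    did_adj = did_estimand(adjusted)
    results["adjusted"] = {"fit": adjusted.to_dict(), "did": did_adj.to_dict()}
    icer = icer_or_flag(did_adj)
    results["icer"] = {"value": icer.value, "flag": icer.flag}
    manifest[f"adjusted_fit{tag}"] = "complete"

    if config.run_mcmc:
        chain = config.chain
        draws = sample_posterior(df, adj_spec, chain, init=adjusted)
        np.savetxt(
            outdir / f"posterior_draws{tag}.csv",
            draws.draws,
            delimiter=",",
            header="delta_e,delta_c",
            comments="",
        )
        write_json(draws.metadata | {"seed": chain.seed}, outdir / f"mcmc_meta{tag}.json")
        plane = ce_plane_summary(draws)
        results["ce_plane"] = plane.to_dict()
        plot_ce_plane(plane, draws, outdir / f"ce_plane{tag}.png")
        manifest[f"mcmc{tag}"] = manifest[f"ce_plane{tag}"] = "complete"

        if config.run_subgroups:
            sub = subgroup_analysis(df, adj_spec, chain)
            results["subgroups"] = {}
            for level, res in sub.items():
                entry = {
                    "n": res["n"],
                    "did": res["did"].to_dict(),
                }
                if "plane" in res:
                    entry["ce_plane"] = res["plane"].to_dict()
                    plot_ce_plane(
                        res["plane"], res.get("draws"),
                        outdir / f"ce_plane_{level}_risk{tag}.png",
                        title=f"CE plane, {level}-risk subgroup",
                    )
                results["subgroups"][level] = entry
            manifest[f"subgroups{tag}"] = "complete"
    elif config.run_subgroups:
        sub = subgroup_analysis(df, adj_spec, None)
        results["subgroups"] = {
            level: {"n": res["n"], "did": res["did"].to_dict()}
            for level, res in sub.items()
        }
        manifest[f"subgroups{tag}"] = "complete"

    if config.run_decomposition:
        decomp = decompose_costs(df, adj_spec)
        results["decomposition"] = {k: v.to_dict() for k, v in decomp.items()}
        manifest[f"decomposition{tag}"] = "complete"

    results["budget_impact"] = budget_impact(did_adj, config.cohort).to_dict()
    manifest[f"budget_impact{tag}"] = "complete"
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full economic-evaluation pipeline; returns the result
    bundle (also written under ``config.output_dir``)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {stage: "pending" for stage in STAGES}
    t0 = time.time()

    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if config.verbosity else logging.WARNING)

    bundle: dict = {
        "versions": {"bivcea": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
    }
    try:
        # --- data ---
        if config.generator is not None:
            df = generate_dataset(config.generator, seed=config.seed)
            write_patient_table(df, outdir / "patients.csv")
            log.info("generated %d patients in %d hospitals", len(df),
                     df["hospital_id"].nunique())
        else:
            df = load_patient_table(config.patient_table)
            log.info("loaded %d patients from %s", len(df), config.patient_table)
        manifest["data"] = "complete"

        # --- costing ---
        tables = None
        if config.unit_cost_table is not None:
            tables = load_unit_cost_tables(config.unit_cost_table)
            if config.events_table is not None and config.fee_schedule is not None:
                df = _recost(df, config.events_table, tables, config.fee_schedule)
        if config.intervention_program_cost > 0:
            mask = (df["group"] == "intervention") & (df["period"] == "post")
            per_patient = intervention_cost_per_patient(
                config.intervention_program_cost, int(mask.sum())
            )
            df = df.copy()
            df.loc[mask, "delivery_cost"] += per_patient
            df.loc[mask, "total_cost"] += per_patient
            bundle["intervention_cost_per_patient"] = per_patient
        manifest["costing"] = "complete"

        # --- models and decision outputs ---
        bundle["primary"] = _analyse(df, config, outdir, "", manifest, config.seed)
        if not config.run_mcmc:
            manifest["mcmc"] = manifest["ce_plane"] = "skipped"
        if not config.run_subgroups:
            manifest["subgroups"] = "skipped"
        if not config.run_decomposition:
            manifest["decomposition"] = "skipped"

        # --- fee-schedule sensitivity rerun ---
        if config.alternative_fee_schedule is not None:
            if tables is None or config.events_table is None:
                raise ValueError(
                    "fee-schedule sensitivity requires events_table and "
                    "unit_cost_table inputs"
                )
            df_alt = _recost(df, config.events_table, tables,
                             config.alternative_fee_schedule)
            bundle["sensitivity"] = _analyse(
                df_alt, config, outdir, "_alt", manifest, config.seed
            )
            manifest["sensitivity"] = "complete"
        else:
            manifest["sensitivity"] = "skipped"

        # --- report ---
        report_rows = {}
        prim = bundle["primary"]
        report_rows["all, crude"] = _did_from_dict(prim["crude"]["did"])
        report_rows["all, adjusted"] = _did_from_dict(prim["adjusted"]["did"])
        for level, entry in prim.get("subgroups", {}).items():
            report_rows[f"{level}-risk, adjusted"] = _did_from_dict(entry["did"])
        (outdir / "report.txt").write_text(report_table(report_rows) + "\n",
                                           encoding="utf-8")
        manifest["report"] = "complete"
    finally:
        manifest["elapsed_seconds"] = round(time.time() - t0, 2)
        write_json(manifest, outdir / "manifest.json")
        write_json(bundle, outdir / "results.json")
        log.removeHandler(handler)
        handler.close()
    return bundle


def _did_from_dict(d: dict):
    from .igls import DidEstimate

    return DidEstimate(
        delta_e=d["delta_e"], delta_c=d["delta_c"], se_e=d["se_e"], se_c=d["se_c"],
        ci_e=tuple(d["ci_e"]), ci_c=tuple(d["ci_c"]), p_e=d["p_e"], p_c=d["p_c"],
        cov_ec=d["cov_ec"],
    )
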
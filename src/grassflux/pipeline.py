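"""End-to-end pipeline: generate -> emissions -> balance -> preindustrial
-> rf -> attribute -> montecarlo -> report.

Each stage reads and writes tidy CSV in the run directory, so every
number in the final report is recomputable from stage files. A manifest
records the config snapshot, seeds and output digests.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from grassflux import __version__
from grassflux.attribution import attribute, managed_sparse_rf
from grassflux.balance import co2e_balance, decadal_means, managed_sparse_split
from grassflux.io_ import (
    RunManifest,
    config_objects,
    write_activity_table,
    write_flux_table,
    write_landcover_table,
)
from grassflux.preindustrial import BaselineRules, anthropogenic_fluxes, extrapolate_1750_1859
from grassflux.rf import AlbedoBookkeeping, albedo_rf, run_rf
from grassflux.synthetic import default_albedo_coefficients, generate_scenario
from grassflux.tier import emissions_table
from grassflux.uncertainty import rf_ensemble, sample_fluxes, summarize, weight_ensemble

log = logging.getLogger("grassflux.pipeline")

__all__ = ["run_pipeline", "baseline_rules_from_activity"]


def baseline_rules_from_activity(activity: pd.DataFrame) -> BaselineRules:
    """Extrapolation scalers from an ActivityTable: human-population
    index for the managed class, wild-grazer heads for the sparse one."""
    managed = activity[["region", "year", "human_pop_index"]].rename(
        columns={"human_pop_index": "value"})
    sparse = activity[["region", "year", "wild_grazer_heads"]].rename(
        columns={"wild_grazer_heads": "value"})
    return BaselineRules(managed_scaler=managed, sparse_scaler=sparse)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.time() - t0)
            return out
        return inner
    return wrap


def run_pipeline(cfg: dict, outdir) -> Path:
    """Run every stage on the configured synthetic scenario.

    Returns the output directory, containing stage CSVs, report.json
    and manifest.json. Any stage error aborts with the stage name in
    the message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario, constants, factors, params, spec = config_objects(cfg)
    manifest = RunManifest(
        config=cfg, version=__version__,
        seeds={"scenario": scenario.seed, "montecarlo": cfg["montecarlo"]["seed"]},
    )

    @_stage("generate")
    def do_generate():
        fluxes, activity, landcover = generate_scenario(scenario, factors)
        write_flux_table(fluxes, outdir / "fluxes.csv")
        write_activity_table(activity, outdir / "activity.csv")
        write_landcover_table(landcover, outdir / "landcover.csv")
        return fluxes, activity, landcover

    fluxes, activity, landcover = do_generate()

    @_stage("emissions")
    def do_emissions():
        records = emissions_table(activity, factors)
        records.to_csv(outdir / "emissions.csv", index=False)
        return records

    do_emissions()

    @_stage("balance")
    def do_balance():
        balance = co2e_balance(fluxes, constants)
        balance.to_csv(outdir / "balance.csv", index=False)
        decades = decadal_means(balance)
        decades.to_csv(outdir / "decadal_balance.csv", index=False)
        return balance, decades

    balance, decades = do_balance()

    @_stage("preindustrial")
    def do_preindustrial():
        rules = baseline_rules_from_activity(activity)
        # keep only the "model era" (>= reference year) and rebuild the
        # earlier period from the extrapolation rules, as done with real
        # land-surface-model output that starts in 1860
        modern = fluxes[fluxes["year"] >= rules.reference_year]
        early = extrapolate_1750_1859(modern, rules)
        total = pd.concat([early, modern], ignore_index=True)
        anthro = anthropogenic_fluxes(total, rules.preindustrial_year)
        write_flux_table(anthro, outdir / "anthropogenic_fluxes.csv")
        return anthro

    anthro = do_preindustrial()

    @_stage("rf")
    def do_rf():
        book = AlbedoBookkeeping(default_albedo_coefficients(scenario.regions))
        traj = run_rf(anthro, params, landcover=landcover, albedo_book=book)
        traj.to_csv(outdir / "rf.csv")
        alb_split = albedo_rf(landcover, book)
        alb_split.to_csv(outdir / "rf_albedo_split.csv")
        return traj, alb_split

    rf_traj, albedo_split = do_rf()

    eval_year = cfg["attribution"]["year"]

    @_stage("attribute")
    def do_attribute():
        table = attribute(anthro, background=None, params=params,
                          epsilon=cfg["attribution"]["epsilon"], year=eval_year)
        table.to_csv(outdir / "attribution.csv", index=False)
        alb = albedo_split.loc[eval_year]
        aggregates = managed_sparse_rf(
            table, {"managed": alb["managed"], "sparse": alb["sparse"]})
        return table, aggregates

    attribution_table, aggregates = do_attribute()

    @_stage("montecarlo")
    def do_montecarlo():
        ens = sample_fluxes(fluxes, activity, factors, spec, seed=cfg["montecarlo"]["seed"])
        weights = weight_ensemble(ens)
        rows = []
        for name, values in (
            ("co2_budget_PgC", ens.co2_budget(eval_year)),
            ("luc_PgC", ens.luc_budget(eval_year)),
            ("ch4_TgC", ens.gas_emission("ch4", eval_year)),
            ("n2o_TgN", ens.gas_emission("n2o", eval_year)),
            ("ghg_total_GtCO2e", ens.ghg_total(eval_year, constants)),
        ):
            rows.append({"quantity": name, "year": eval_year, **summarize(values, weights)})
        rf_vals = rf_ensemble(ens, params, year=eval_year)
        rows.append({"quantity": "rf_total_mWm2", "year": eval_year,
                     **summarize(rf_vals, weights)})
        summary = pd.DataFrame(rows)
        summary.to_csv(outdir / "montecarlo_summary.csv", index=False)
        return summary

    mc_summary = do_montecarlo()

    @_stage("report")
    def do_report():
        managed_bal, sparse_bal = managed_sparse_split(balance)
        at_year = balance[balance["year"] == eval_year]
        report = {
            "evaluation_year": eval_year,
            "decadal_balance_GtCO2e": decades.to_dict("records"),
            "balance_at_year_GtCO2e": {
                "managed": float(managed_bal.loc[managed_bal["year"] == eval_year, "ghg_total"].sum()),
                "sparse": float(sparse_bal.loc[sparse_bal["year"] == eval_year, "ghg_total"].sum()),
                "total": float(at_year["ghg_total"].sum()),
            },
            "rf_decomposition_mWm2": rf_traj.loc[eval_year].to_dict(),
            "rf_aggregates_mWm2": aggregates,
            "attribution": attribution_table.to_dict("records"),
            "montecarlo": mc_summary.to_dict("records"),
        }
        b = report["balance_at_year_GtCO2e"]
        if not np.isclose(b["managed"] + b["sparse"], b["total"], rtol=1e-9, atol=1e-12):
            raise ValueError("managed + sparse does not re-sum to the total balance")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        return report

    do_report()

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.record(f.name, f)
    manifest.write(outdir / "manifest.json")
    return outdir
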
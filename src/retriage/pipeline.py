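"""End-to-end orchestration: simulate, link, classify, outcomes, model,
network, optimize, report.

Each stage reads and writes documented CSV artifacts in the output
directory, so stages can be re-run individually from the command line. The
manifest returned by :func:`run_pipeline` lists every artifact with its row
count. Cross-module consistency (ledger conservation; graph edge weights vs
the rate table) is checked automatically at the end of a full run.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import (
    cohort,
    destination_optimizer,
    linkage,
    mixed_model,
    outcomes,
    synthetic_data,
    transfer_network,
)
from .hospitals import HospitalDirectory

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "link", "classify", "outcomes", "model", "network", "optimize", "report")


@dataclass
class PipelineConfig:
    outdir: str = "retriage_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    simulation: synthetic_data.SimulationConfig | None = None
    network_year: int | None = None  # default: last simulated year
    percent_decimals: int = 1

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = synthetic_data.SimulationConfig(seed=self.seed)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = synthetic_data.SimulationConfig(**sim)
        return cfg


def _path(cfg, name):
    return os.path.join(cfg.outdir, name)


def stage_simulate(cfg: PipelineConfig) -> dict:
    sim = cfg.simulation
    directory = synthetic_data.generate_hospital_directory(sim)
    ed, ip, truth = synthetic_data.generate_encounters(sim, directory)
    return synthetic_data.write_dataset(sim, directory, ed, ip, truth, cfg.outdir)


def stage_link(cfg: PipelineConfig) -> dict:
    directory = HospitalDirectory.from_csv(_path(cfg, "hospitals.csv"))
    ed = pd.read_csv(_path(cfg, "ed_encounters.csv"))
    ip = pd.read_csv(_path(cfg, "inpatient_encounters.csv"))
    ed, n_dup_ed = linkage.deduplicate_records(ed)
    ip, n_dup_ip = linkage.deduplicate_records(ip)
    cohort_pairs, under, ledger = linkage.apply_inclusion_exclusion(ed, ip, directory)
    ledger_frame = ledger.to_frame()
    log.info("deduplicated %d ED / %d inpatient duplicate rows", n_dup_ed, n_dup_ip)
    for row in ledger_frame.itertuples(index=False):
        log.info("exclusion %-40s removed %6d remaining %6d", *row)
    cohort_pairs.to_csv(_path(cfg, "cohort.csv"), index=False)
    under.to_csv(_path(cfg, "under_triaged.csv"), index=False)
    ledger_frame.to_csv(_path(cfg, "ledger.csv"), index=False)
    ip.to_csv(_path(cfg, "inpatient_deduplicated.csv"), index=False)
    return {k: _path(cfg, f"{k}.csv") for k in ("cohort", "under_triaged", "ledger")}


def stage_classify(cfg: PipelineConfig) -> dict:
    directory = HospitalDirectory.from_csv(_path(cfg, "hospitals.csv"))
    pairs = pd.read_csv(_path(cfg, "cohort.csv"))
    events = cohort.encode_covariates(cohort.label_optimality(pairs, directory))
    events.to_csv(_path(cfg, "events.csv"), index=False)
    paths = {"events": _path(cfg, "events.csv")}
    for level in cohort.AGGREGATION_LEVELS:
        table = cohort.aggregate_rates(events, directory, level)
        p = _path(cfg, f"rates_{level.lower()}.csv")
        table.to_csv(p, index=False)
        paths[f"rates_{level.lower()}"] = p
    cohort.table_one(events).to_csv(_path(cfg, "table1.csv"), index=False)
    cohort.annual_trend(events).to_csv(_path(cfg, "annual_trend.csv"), index=False)
    per_center, center_summary = cohort.center_level_summary(events, directory)
    per_center.to_csv(_path(cfg, "rates_per_center.csv"), index=False)
    center_summary.to_csv(_path(cfg, "center_summary.csv"), index=False)
    paths.update(table1=_path(cfg, "table1.csv"), center_summary=_path(cfg, "center_summary.csv"))
    return paths


def stage_outcomes(cfg: PipelineConfig) -> dict:
    directory = HospitalDirectory.from_csv(_path(cfg, "hospitals.csv"))
    events = pd.read_csv(_path(cfg, "events.csv"))
    ip = pd.read_csv(_path(cfg, "inpatient_deduplicated.csv"))
    events = outcomes.attach_hospital_course(events)
    events = outcomes.flag_readmissions(events, ip, directory)
    events.to_csv(_path(cfg, "events_with_course.csv"), index=False)
    outcomes.surgery_rate_table(events).to_csv(_path(cfg, "table2.csv"), index=False)
    contrasts = {}
    for w in outcomes.READMISSION_WINDOWS:
        contrasts[f"readmission_{w}d"] = outcomes.contrast_2x2(events, f"readmitted_{w}")
    events["_to_third_acute"] = events["disposition_group"] == "SHORT_TERM_ACUTE"
    contrasts["discharge_to_third_acute"] = outcomes.contrast_2x2(events, "_to_third_acute")
    with open(_path(cfg, "outcome_contrasts.json"), "w") as fh:
        json.dump(contrasts, fh, indent=2)
    return {"table2": _path(cfg, "table2.csv"),
            "outcome_contrasts": _path(cfg, "outcome_contrasts.json")}


def stage_model(cfg: PipelineConfig) -> dict:
    events = pd.read_csv(_path(cfg, "events.csv"))
    events["suboptimal"] = (events["optimality"] == cohort.SUBOPTIMAL).astype(int)
    fit = mixed_model.fit_suboptimality_model(events)
    fit.to_csv(_path(cfg, "model_coefficients.csv"))
    with open(_path(cfg, "model_random_effects.json"), "w") as fh:
        json.dump({"random_intercept_sd": fit.random_sd, "n_obs": fit.n_obs}, fh, indent=2)
    return {"model_coefficients": _path(cfg, "model_coefficients.csv")}


def stage_network(cfg: PipelineConfig) -> dict:
    directory = HospitalDirectory.from_csv(_path(cfg, "hospitals.csv"))
    events = pd.read_csv(_path(cfg, "events.csv"))
    year = cfg.network_year or int(events["year"].max())
    graph = transfer_network.build_transfer_graph(events, directory, year)
    transfer_network.write_graphml(graph, _path(cfg, "network.graphml"))
    transfer_network.write_geojson(graph, _path(cfg, "network.geojson"))
    if graph.number_of_nodes():
        for mode in (transfer_network.GEOGRAPHIC, transfer_network.FORCE_DIRECTED):
            pos = transfer_network.layout_graph(graph, mode, seed=cfg.seed)
            transfer_network.plot_graph(graph, pos, _path(cfg, f"network_{mode.lower()}.png"))
    return {"network": _path(cfg, "network.graphml")}


def stage_optimize(cfg: PipelineConfig) -> dict:
    directory = HospitalDirectory.from_csv(_path(cfg, "hospitals.csv"))
    events = pd.read_csv(_path(cfg, "events.csv"))
    table, summary = destination_optimizer.optimize_all(events, directory)
    table.to_csv(_path(cfg, "alternatives.csv"), index=False)
    with open(_path(cfg, "optimizer_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"alternatives": _path(cfg, "alternatives.csv"),
            "optimizer_summary": _path(cfg, "optimizer_summary.json")}


def stage_report(cfg: PipelineConfig) -> dict:
    d = cfg.percent_decimals
    events = pd.read_csv(_path(cfg, "events.csv"))
    rates_state = pd.read_csv(_path(cfg, "rates_state.csv"))
    rates_rtcc = pd.read_csv(_path(cfg, "rates_rtcc.csv"))
    center = pd.read_csv(_path(cfg, "center_summary.csv"))
    pooled = rates_state[rates_state["year"] == "ALL"].iloc[0]
    lines = [
        "# Re-triage analysis report",
        "",
        f"Re-triages: {int(pooled['n_retriage'])}; suboptimal: "
        f"{int(pooled['n_suboptimal'])} ({round(100 * pooled['rate'], d)}%).",
        "",
        "## Suboptimal re-triage rate by region (pooled)",
        "",
        "| RTCC | n re-triage | n suboptimal | rate (%) | share of state suboptimal (%) |",
        "|---|---|---|---|---|",
    ]
    pooled_rtcc = rates_rtcc[rates_rtcc["year"] == "ALL"]
    for r in pooled_rtcc.itertuples(index=False):
        lines.append(
            f"| {r.unit_id} | {r.n_retriage} | {r.n_suboptimal} | "
            f"{round(100 * r.rate, d)} | {round(100 * r.share_of_state_suboptimal, d)} |"
        )
    pooled_center = center[center["year"] == "ALL"].iloc[0]
    lines += [
        "",
        f"Sending centers with at least one suboptimal re-triage: "
        f"{round(100 * pooled_center['frac_with_any_suboptimal'], d)}% "
        f"of {int(pooled_center['n_eligible_centers'])} eligible centers.",
    ]
    opt_path = _path(cfg, "optimizer_summary.json")
    if os.path.exists(opt_path):
        with open(opt_path) as fh:
            s = json.load(fh)
        lines += [
            "",
            "## Destination optimization",
            "",
            f"Alternative level I/II destination found for "
            f"{round(100 * s['resolvable_fraction'], d)}% of suboptimal re-triages; "
            f"statewide suboptimal rate {round(100 * s['suboptimal_rate_before'], d)}% -> "
            f"{round(100 * s['suboptimal_rate_after'], d)}% after hypothetical rerouting.",
        ]
    with open(_path(cfg, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return {"report": _path(cfg, "report.md")}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "link": stage_link,
    "classify": stage_classify,
    "outcomes": stage_outcomes,
    "model": stage_model,
    "network": stage_network,
    "optimize": stage_optimize,
    "report": stage_report,
}


def _consistency_checks(cfg: PipelineConfig) -> None:
    """Cross-module checks run after a full pipeline: the ledger accounts for
    every deduplicated ED encounter, and the transfer graph's suboptimal
    edge-weight share equals the rate table's suboptimal rate for its year."""
    ledger = pd.read_csv(_path(cfg, "ledger.csv"))
    ed = pd.read_csv(_path(cfg, "ed_encounters.csv"))
    ed, _ = linkage.deduplicate_records(ed)
    n_cohort = len(pd.read_csv(_path(cfg, "cohort.csv")))
    n_under = len(pd.read_csv(_path(cfg, "under_triaged.csv")))
    assert ledger["n_removed"].sum() + n_cohort + n_under == len(ed), "ledger conservation failed"

    import networkx as nx

    graph = nx.read_graphml(_path(cfg, "network.graphml"))
    events = pd.read_csv(_path(cfg, "events.csv"))
    year = cfg.network_year or int(events["year"].max())
    ev = events[events["year"] == year]
    if len(ev):
        sub_weight = sum(
            d["weight"] for _, _, d in graph.edges(data=True)
            if d["category"] != transfer_network.CATEGORY_OPTIMAL
        )
        rate = (ev["optimality"] == cohort.SUBOPTIMAL).mean()
        assert abs(sub_weight - rate) < 1e-9, "graph weights disagree with rate table"


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages in order; returns the artifact manifest
    (stage -> {artifact name -> path}) plus row counts."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = {}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            artifacts = STAGE_FUNCS[stage](cfg)
        except Exception:
            log.error("pipeline stage %r failed", stage)
            raise
        counts = {}
        for name, path in artifacts.items():
            if str(path).endswith(".csv"):
                counts[name] = int(len(pd.read_csv(path)))
        manifest[stage] = {"artifacts": artifacts, "row_counts": counts}
    if set(cfg.stages) == set(ALL_STAGES):
        _consistency_checks(cfg)
    with open(_path(cfg, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
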
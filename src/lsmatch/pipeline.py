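"""End-to-end evaluation pipeline.

Generates a synthetic cohort, draws stratified subsamples per sample
group, refits the propensity model within every draw, applies greedy
propensity-score matching and cardinality matching at each configured
setting, pools balance diagnostics and negative-control Cox estimates
across draws per analysis cell, fits the empirical null, and reports
expected systematic error plus calibrated safety-outcome estimates.

Every random stream is derived from one master seed via named
substreams, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import balance as bal
from .calibration import (
    calibrate_estimate,
    ese_credible_interval,
    fit_null_mle,
)
from .cardinality import CMConfig, build_problem, solve_cardinality_match
from .cohort import Cohort
from .propensity import (
    extract_matching_covariates,
    fit_propensity_model,
    predict_scores,
    select_candidate_covariates,
)
from .psm import PSMatchConfig, compute_caliper, greedy_match
from .simulate import SAFETY_OUTCOME, SimConfig, draw_subsamples, generate_cohort
from .survival import build_time_at_risk, fit_cox_frame, survival_frame

log = logging.getLogger("lsmatch")

DEFAULT_SAMPLE_GROUPS = [
    {"name": "full", "fraction": 1.0, "n_draws": 1},
    {"name": "10pct", "fraction": 0.10, "n_draws": 5},
    {"name": "1pct", "fraction": 0.01, "n_draws": 50},
    {"name": "0.5pct", "fraction": 0.005, "n_draws": 100},
]
DEFAULT_METHODS = [
    {"name": "psm-0.10", "kind": "psm", "caliper_fraction": 0.10},
    {"name": "psm-0.20", "kind": "psm", "caliper_fraction": 0.20},
    {"name": "cm-fine", "kind": "cm", "balance_criterion": 0.0},
    {"name": "cm-0.01", "kind": "cm", "balance_criterion": 0.01},
    {"name": "cm-0.05", "kind": "cm", "balance_criterion": 0.05},
    {"name": "cm-0.10", "kind": "cm", "balance_criterion": 0.10},
]


def derive_seed(master_seed: int, *names) -> int:
    """Stable named substream seed below 2**31."""
    token = "/".join(str(n) for n in names)
    return (master_seed * 2654435761 + zlib.crc32(token.encode())) % (2**31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    cfg.setdefault("seed", 0)
    cfg.setdefault("simulation", {})
    cfg.setdefault("propensity", {})
    cfg["propensity"].setdefault("min_frequency", 0.001)
    cfg["propensity"].setdefault("cv_folds", 10)
    cfg.setdefault("sample_groups", DEFAULT_SAMPLE_GROUPS)
    cfg.setdefault("methods", DEFAULT_METHODS)
    cfg.setdefault("solver", {})
    cfg["solver"].setdefault("time_limit", 300.0)
    cfg["solver"].setdefault("gap_tolerance", 0.0)
    cfg.setdefault("mcmc", {})
    cfg["mcmc"].setdefault("iterations", 10_000)
    cfg["mcmc"].setdefault("burn_in", 2_000)
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    sim = dict(cfg["simulation"])
    if "prevalence_range" in sim:
        sim["prevalence_range"] = tuple(sim["prevalence_range"])
    if "index_day_range" in sim:
        sim["index_day_range"] = tuple(sim["index_day_range"])
    sim.setdefault("seed", derive_seed(cfg["seed"], "simulate"))
    return SimConfig(**sim)


def _match_one(
    draw: Cohort,
    method: dict,
    scores: pd.Series,
    matching_ids: set,
    cfg: dict,
    seed: int,
):
    if method["kind"] == "psm":
        pcfg = PSMatchConfig(
            caliper_fraction=method["caliper_fraction"], seed=seed
        )
        caliper = compute_caliper(scores, draw.arms, pcfg.caliper_fraction)
        return greedy_match(scores, draw.arms, pcfg, caliper=caliper)
    if method["kind"] == "cm":
        ccfg = CMConfig(
            balance_criterion=method["balance_criterion"],
            matching_covariate_ids=sorted(matching_ids),
            solver_time_limit=cfg["solver"]["time_limit"],
            solver_gap_tolerance=cfg["solver"]["gap_tolerance"],
            seed=seed,
        )
        problem = build_problem(draw, ccfg)
        return solve_cardinality_match(problem, ccfg, scores=scores)
    raise ValueError(f"unknown method kind {method['kind']!r}")


def run_evaluation(config, output_dir: str | None = None) -> dict:
    """Run the full evaluation grid; write a result bundle; return cells."""
    cfg = load_config(config)
    out = output_dir or cfg.get("output_dir", "lsmatch_results")
    os.makedirs(out, exist_ok=True)
    os.makedirs(os.path.join(out, "pairs"), exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

    sim_cfg = _sim_config(cfg)
    with open(os.path.join(out, "config_echo.yaml"), "w") as fh:
        yaml.safe_dump(
            {**cfg, "simulation": {**asdict(sim_cfg)}}, fh, default_flow_style=None
        )

    log.info("generating cohort: n=%d", sim_cfg.n_subjects)
    cohort = generate_cohort(sim_cfg)
    master = cfg["seed"]
    min_freq_default = cfg["propensity"]["min_frequency"]
    cv_folds = cfg["propensity"]["cv_folds"]

    balance_rows = []
    estimate_rows = []
    cells: dict[str, dict] = {}
    # stacked survival frames per (group, method, outcome)
    stacks: dict[tuple[str, str], dict[str, list]] = {}
    match_sizes: dict[tuple[str, str], list[int]] = {}
    feasibility: dict[tuple[str, str], list[bool]] = {}
    balance_reports: dict[tuple[str, str, str], list] = {}
    mcov_counts: dict[str, list[int]] = {}

    for group in cfg["sample_groups"]:
        gname = group["name"]
        if group["fraction"] >= 1.0:
            draws = [cohort]
        else:
            draws = draw_subsamples(
                cohort,
                group["fraction"],
                group["n_draws"],
                derive_seed(master, "draws", gname),
            )
        for d, draw in enumerate(draws):
            log.info("group %s draw %d: n=%d", gname, d, draw.n)
            tar = build_time_at_risk(draw, study_end_day=sim_cfg.study_end_day)
            # one propensity fit per distinct frequency threshold
            freqs = sorted(
                {m.get("min_frequency", min_freq_default) for m in cfg["methods"]}
            )
            models = {}
            for f in freqs:
                candidates = select_candidate_covariates(draw, f)
                model = fit_propensity_model(
                    draw,
                    candidates,
                    cv_folds=cv_folds,
                    seed=derive_seed(master, "ps", gname, d, f),
                )
                models[f] = (
                    candidates,
                    model,
                    predict_scores(model, draw),
                    extract_matching_covariates(model),
                )
            f0 = freqs[0]
            candidates0, _, scores0, matching0 = models[f0]
            mcov_counts.setdefault(gname, []).append(len(matching0))

            for scope, cov_ids in (
                ("matching", matching0),
                ("candidate", candidates0),
            ):
                rep = bal.balance_table(draw, None, cov_ids, scope=scope, draw_id=d)
                balance_reports.setdefault((gname, "pre-match", scope), []).append(rep)
                balance_rows.append(rep.to_frame().assign(group=gname))
            key = (gname, "pre-match")
            match_sizes.setdefault(key, []).append(draw.n)
            feasibility.setdefault(key, []).append(True)
            for oid in draw.outcome_ids:
                stacks.setdefault(key, {}).setdefault(oid, []).append(
                    survival_frame(tar, draw.arms, draw.events, oid)
                )

            for method in cfg["methods"]:
                mname = method["name"]
                f = method.get("min_frequency", min_freq_default)
                candidates, model, scores, matching = models[f]
                seed = derive_seed(master, "match", gname, d, mname)
                result = _match_one(draw, method, scores, matching, cfg, seed)
                result.to_csv(
                    os.path.join(out, "pairs", f"{gname}_{mname}_draw{d}.csv")
                )
                key = (gname, mname)
                match_sizes.setdefault(key, []).append(2 * result.n_pairs)
                feasibility.setdefault(key, []).append(result.feasible)
                if not result.feasible or result.n_pairs == 0:
                    log.warning(
                        "group %s draw %d method %s: no feasible matched sample",
                        gname,
                        d,
                        mname,
                    )
                    continue
                for scope, cov_ids in (
                    ("matching", matching),
                    ("candidate", candidates),
                ):
                    rep = bal.balance_table(
                        draw, result, cov_ids, scope=scope, draw_id=d
                    )
                    rep.method = mname  # cell name, not just "psm"/"cm"
                    balance_reports.setdefault((gname, mname, scope), []).append(rep)
                    balance_rows.append(rep.to_frame().assign(group=gname))
                matched = set(result.matched_ids.tolist())
                tar_m = tar[tar["subject_id"].isin(matched)]
                for oid in draw.outcome_ids:
                    stacks.setdefault(key, {}).setdefault(oid, []).append(
                        survival_frame(tar_m, draw.arms, draw.events, oid)
                    )

    # ------------------------------------------------------------ per cell
    mcmc = cfg["mcmc"]
    for (gname, mname), per_outcome in stacks.items():
        estimates = []
        for oid, frames in per_outcome.items():
            est = fit_cox_frame(pd.concat(frames, ignore_index=True), oid)
            estimates.append(est)
            estimate_rows.append(
                {
                    "group": gname,
                    "method": mname,
                    "outcome_id": oid,
                    "log_hr": est.log_hr,
                    "se": est.se,
                    "n_events": est.n_events,
                    "estimable": est.estimable,
                }
            )
        nc_estimates = [e for e in estimates if e.outcome_id != SAFETY_OUTCOME]
        safety = next(
            (e for e in estimates if e.outcome_id == SAFETY_OUTCOME), None
        )
        cell: dict = {
            "group": gname,
            "method": mname,
            "n_draws": len(match_sizes[(gname, mname)]),
            "average_matched_size": float(np.mean(match_sizes[(gname, mname)])),
            "all_feasible": bool(np.all(feasibility[(gname, mname)])),
            "n_infeasible_draws": int(
                len(feasibility[(gname, mname)])
                - np.sum(feasibility[(gname, mname)])
            ),
            "n_estimable_negative_controls": sum(
                e.estimable for e in nc_estimates
            ),
        }
        if gname in mcov_counts:
            cell["mean_matching_covariates"] = float(np.mean(mcov_counts[gname]))
        for scope in ("matching", "candidate"):
            reports = balance_reports.get((gname, mname, scope))
            if reports:
                summary = bal.pool_reports(reports)
                summary.pop("pooled_smds")
                cell[f"balance_{scope}"] = summary
        if sum(e.estimable for e in nc_estimates) >= 2:
            null = fit_null_mle(nc_estimates)
            ese = ese_credible_interval(
                nc_estimates,
                iterations=mcmc["iterations"],
                burn_in=mcmc["burn_in"],
                seed=derive_seed(master, "mcmc", gname, mname),
            )
            cell["null_model"] = {"mu": null.mu, "sigma": null.sigma}
            cell["ese"] = {
                "point": ese.point,
                "ci_low": ese.ci_low,
                "ci_high": ese.ci_high,
            }
            if safety is not None and safety.estimable:
                calib = calibrate_estimate(null, safety)
                z = 1.959963984540054
                cell["safety_outcome"] = {
                    "uncalibrated": {
                        "hr": float(np.exp(safety.log_hr)),
                        "ci_low": float(np.exp(safety.log_hr - z * safety.se)),
                        "ci_high": float(np.exp(safety.log_hr + z * safety.se)),
                        "se": safety.se,
                    },
                    "calibrated": {
                        "hr": float(np.exp(calib.log_hr)),
                        "ci_low": float(np.exp(calib.ci_low)),
                        "ci_high": float(np.exp(calib.ci_high)),
                        "se": calib.se,
                        "p_value": calib.p_value,
                    },
                }
        cells[f"{gname}/{mname}"] = cell

    pd.concat(balance_rows, ignore_index=True).to_csv(
        os.path.join(out, "balance.csv"), index=False
    )
    pd.DataFrame(estimate_rows).to_csv(
        os.path.join(out, "estimates.csv"), index=False
    )
    with open(os.path.join(out, "cells.json"), "w") as fh:
        json.dump(cells, fh, indent=1, default=float)
    log.info("wrote result bundle to %s", out)
    return cells


def summarize(results_dir: str) -> str:
    """Human-readable report over a completed result bundle."""
    path = os.path.join(results_dir, "cells.json")
    if not os.path.exists(path):
        raise FileNotFoundError(f"no result bundle in {results_dir!r}")
    with open(path) as fh:
        cells = json.load(fh)
    lines = [
        f"{'cell':<24}{'avg size':>10}{'max|SMD|m':>11}{'imb prop':>10}"
        f"{'ESE':>8}{'ESE 95% CrI':>18}"
    ]
    for name, cell in cells.items():
        b = cell.get("balance_matching", {})
        ese = cell.get("ese")
        lines.append(
            f"{name:<24}{cell['average_matched_size']:>10.1f}"
            f"{b.get('max_abs_smd', float('nan')):>11.3f}"
            f"{b.get('pooled_imbalanced_proportion', float('nan')):>10.3f}"
            + (
                f"{ese['point']:>8.3f}"
                f"   ({ese['ci_low']:.3f}, {ese['ci_high']:.3f})"
                if ese
                else f"{'--':>8}"
            )
        )
        so = cell.get("safety_outcome")
        if so:
            u, c = so["uncalibrated"], so["calibrated"]
            lines.append(
                f"  safety HR uncal {u['hr']:.2f} ({u['ci_low']:.2f},"
                f" {u['ci_high']:.2f}); cal {c['hr']:.2f} ({c['ci_low']:.2f},"
                f" {c['ci_high']:.2f}), p={c['p_value']:.3g}"
            )
    report = "\n".join(lines)
    with open(os.path.join(results_dir, "report.txt"), "w") as fh:
        fh.write(report + "\n")
    return report
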
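"""End-to-end pipeline: simulate -> behavior -> ephys -> crosscorr -> report.

Each stage reads/writes the interchange CSV tables, logs its parameters
and seed to stderr, and is individually re-runnable from the saved
intermediates. With a fixed seed the whole report bundle is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import behavior as bh
from . import crosscorr as cc
from . import synthetic as syn
from .config import RunConfig
from .ephys import (
    burst_index,
    classify_cell_types,
    classify_task_related,
    delta_zscore_series,
    extract_features,
    summarize_population,
    trial_firing_rates,
    validate_bimodality,
)
from .io import write_table
from .series import LongSeries

log = logging.getLogger("comprank")

__all__ = ["run_pipeline", "simulate_stage", "behavior_stage", "ephys_stage", "crosscorr_stage"]


def _stage(name: str, seed: int):
    log.info("stage=%s seed=%d", name, seed)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)


def simulate_stage(config: RunConfig, out: Path) -> dict[str, pd.DataFrame]:
    gen = config.generator
    t0 = _stage("simulate", gen.seed)
    units, truth = syn.generate_unit_population(gen)
    waveforms = syn.generate_waveform_table(gen, units)
    trials = pd.concat(
        [
            syn.generate_competition_session(gen, f"g{g}")
            for g in range(gen.n_groups)
        ],
        ignore_index=True,
    )
    spikes = syn.generate_spike_trains(gen, trials, truth, units)
    tube = pd.concat(
        [syn.generate_tube_and_warmspot(gen, f"g{g}")[0] for g in range(gen.n_groups)],
        ignore_index=True,
    )
    warmspot = pd.concat(
        [syn.generate_tube_and_warmspot(gen, f"g{g}")[1] for g in range(gen.n_groups)],
        ignore_index=True,
    )
    bundle = syn.generate_longitudinal(gen)
    tables = {
        "units": units,
        "truth": truth,
        "waveforms": waveforms,
        "trials": trials,
        "spikes": spikes,
        "tube": tube,
        "warmspot": warmspot,
        "longitudinal_rates": bundle["rates"],
    }
    series_rows = []
    for key in ("winning", "tube_time", "tube_rank"):
        s: LongSeries = bundle[key]
        for d, v in zip(s.days, s.values):
            series_rows.append({"label": s.label, "day": int(d), "value": float(v)})
    tables["behavior_series"] = pd.DataFrame(series_rows)
    for name, df in tables.items():
        write_table(df, out / f"{name}.csv")
    _done("simulate", t0)
    return tables


def behavior_stage(tables: dict, config: RunConfig, out: Path) -> dict:
    t0 = _stage("behavior", config.analysis.seed)
    rank_days = bh.tube_daily_ranks(tables["tube"])
    hierarchy = pd.DataFrame(
        [
            {
                "group_id": r.group_id,
                "day": r.day,
                "mouse_id": m,
                "rank": rank,
                "linear": r.linear,
            }
            for r in rank_days
            for m, rank in sorted(r.ranks.items())
        ]
    )
    write_table(hierarchy, out / "hierarchy.csv")

    stability = {}
    for group_id in hierarchy["group_id"].unique():
        g_days = [r for r in rank_days if r.group_id == group_id]
        stability[group_id] = bh.detect_stable_hierarchy(
            g_days, window=config.analysis.stability_window
        )

    props = pd.concat(
        [bh.winning_proportions(tables["trials"], stage) for stage in bh.STAGES],
        ignore_index=True,
    )
    write_table(props, out / "winning_proportions.csv")

    orders = bh.assign_competitive_order(tables["trials"])
    order_df = pd.DataFrame(
        [
            {
                "group_id": o.group_id,
                "mouse_id": m,
                "competitive_order": o.order[m],
                "pellet_proportion": o.pellet_proportion[m],
                "mean_latency_s": o.mean_latency_s[m],
                "tie_broken": o.tie_broken[m],
            }
            for o in orders
            for m in sorted(o.order)
        ]
    )
    write_table(order_df, out / "competitive_order.csv")

    ws = bh.warmspot_occupancy(tables["warmspot"])
    write_table(ws, out / "warmspot_order.csv")

    # tube-time inflection on the mean daily bout duration per group,
    # and competitive order vs final-day tube rank
    inflection = {}
    order_rank_rho = {}
    by_group = {o.group_id: o for o in orders}
    for group_id, block in tables["tube"].groupby("group_id"):
        daily = block.groupby("day")["duration_s"].mean().sort_index()
        series = LongSeries("tube_time", daily.index.to_numpy(), daily.to_numpy())
        inflection[group_id] = bh.tube_time_inflection(series)
        last_day = max(r.day for r in rank_days if r.group_id == group_id)
        [final_ranks] = [
            r for r in rank_days if r.group_id == group_id and r.day == last_day
        ]
        if group_id in by_group:
            order_rank_rho[group_id] = bh.order_rank_correlation(
                by_group[group_id], final_ranks
            )
    _done("behavior", t0)
    return {
        "stability_day": stability,
        "orders": orders,
        "rank_days": rank_days,
        "tube_time_inflection": inflection,
        "order_rank_rho": order_rank_rho,
    }


def ephys_stage(tables: dict, config: RunConfig, out: Path) -> dict:
    ana = config.analysis
    t0 = _stage("ephys", ana.seed)
    feats = []
    rate = config.generator.sampling_rate_hz
    for unit_id, wf in tables["waveforms"].groupby("unit_id", sort=False):
        w = wf.sort_values("sample_idx")["amplitude_uv"].to_numpy()
        f = extract_features(w, rate, unit_id=unit_id)
        feats.append(dataclasses.asdict(f))
    features = pd.DataFrame(feats)
    write_table(features, out / "unit_features.csv")

    cell_types = classify_cell_types(
        features, seed=ana.seed, n_init=ana.kmeans_n_init
    )
    bi = {
        unit_id: burst_index(
            s["spike_time_s"].to_numpy(), bin_ms=ana.bin_ms, max_lag_ms=ana.max_lag_ms
        )
        for unit_id, s in tables["spikes"].groupby("unit_id", sort=False)
        if len(s) >= 2
    }
    cell_types["burst_index"] = cell_types["unit_id"].map(bi)
    write_table(cell_types, out / "cell_types.csv")

    trials = tables["trials"]
    units = tables["units"]
    rate_frames = []
    for group_id, unit_block in units.groupby("group_id", sort=False):
        unit_ids = set(unit_block["unit_id"])
        g_spikes = tables["spikes"][tables["spikes"]["unit_id"].isin(unit_ids)]
        if g_spikes.empty:
            continue
        subj = trials[trials["group_id"] == group_id]
        # restrict to the implanted subject's perspective rows
        implanted = syn.implanted_mouse(config.generator, group_id)
        subj = subj[subj["subject_id"] == implanted]
        if subj.empty:
            continue
        rate_frames.append(
            trial_firing_rates(
                g_spikes,
                subj,
                anchor=ana.window_anchor,
                window_s=(ana.window_start_s, ana.window_end_s),
            )
        )
    rates = pd.concat(rate_frames, ignore_index=True) if rate_frames else pd.DataFrame()
    categories = classify_task_related(
        rates, alpha=ana.alpha, min_trials=ana.min_trials, test=ana.test
    )
    write_table(categories, out / "task_categories.csv")

    finite_bi = cell_types.dropna(subset=["burst_index"])
    if len(finite_bi) >= 10:
        bimodality = validate_bimodality(
            {
                t: finite_bi.loc[finite_bi["cell_type"] == t, "burst_index"].to_numpy()
                for t in ("excitatory", "inhibitory")
            },
            seed=ana.seed,
        )
    else:
        bimodality = {"passed": None, "n": int(len(finite_bi))}

    summary = summarize_population(cell_types, categories)
    (out / "population_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    dz = delta_zscore_series(tables["longitudinal_rates"], baseline_day=0)
    dz_rows = [
        {"category": cat, "day": int(d), "delta_z": float(v)}
        for cat, s in sorted(dz.items())
        for d, v in zip(s.days, s.values)
    ]
    write_table(pd.DataFrame(dz_rows), out / "delta_z.csv")
    _done("ephys", t0)
    return {
        "summary": summary,
        "delta_z": dz,
        "cell_types": cell_types,
        "categories": categories,
        "burst_bimodality": bimodality,
    }


def crosscorr_stage(tables: dict, ephys_out: dict, config: RunConfig, out: Path) -> pd.DataFrame:
    ana = config.analysis
    t0 = _stage("crosscorr", ana.seed)
    dz = ephys_out["delta_z"]
    series_df = tables["behavior_series"]
    win_rows = series_df[series_df["label"] == "winning_proportion"]
    winning = LongSeries(
        "winning_proportion",
        win_rows["day"].to_numpy(),
        win_rows["value"].to_numpy(),
    )
    pairs = [
        ("competition_dz~winning", dz["competition"], winning),
        ("competition_dz~rank_dz", dz["competition"], dz["rank"]),
    ]
    results = []
    rows = []
    for label, x, y in pairs:
        res = cc.significance_band(
            x,
            y,
            max_lag=ana.max_lag_days,
            n_perm=ana.n_perm,
            alpha=ana.alpha,
            seed=ana.seed,
        )
        results.append((label, res))
        for lag, r, p, sig in zip(res.lags, res.r, res.p_values, res.significant):
            rows.append(
                {
                    "pair": label,
                    "lag": int(lag),
                    "r": float(r),
                    "p": float(p),
                    "significant": bool(sig),
                }
            )
    write_table(pd.DataFrame(rows), out / "crosscorr.csv")
    report = cc.lag_report(results)
    write_table(report, out / "lag_report.csv")
    _done("crosscorr", t0)
    return report


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages in dependency order; return the report bundle."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = simulate_stage(config, out)
    behavior_out = behavior_stage(tables, config, out)
    ephys_out = ephys_stage(tables, config, out)
    lag_df = crosscorr_stage(tables, ephys_out, config, out)

    report = {
        "stability_day": {k: v for k, v in behavior_out["stability_day"].items()},
        "tube_time_inflection": behavior_out["tube_time_inflection"],
        "order_rank_rho": behavior_out["order_rank_rho"],
        "burst_bimodality": ephys_out["burst_bimodality"],
        "population_summary": ephys_out["summary"].to_dict(),
        "peak_lags": {
            row["pair"]: int(row["peak_lag"]) for _, row in lag_df.iterrows()
        },
        "competitive_order": {
            o.group_id: o.order for o in behavior_out["orders"]
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest = {
        "seed": config.generator.seed,
        "analysis_seed": config.analysis.seed,
        "generator": dataclasses.asdict(config.generator),
        "analysis": dataclasses.asdict(config.analysis),
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return report
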
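"""End-to-end two-period niche-shift workflow driven by one config.

Stages: synthesize (or load) the two-period landscape and checklists ->
quality-filter -> derive bioclim + prune collinear predictors -> hexagon-week
subsample and 80/20 split -> train balanced-forest replicates per period ->
predict the four model x environment suitability maps (two contemporary, one
forecast, one backcast) -> evaluate discrimination and temporal
transferability -> binarize at the max-SSS threshold and map range change ->
importance and partial dependence -> niche-overlap permutation test ->
circuit-theory connectivity change. Every random draw is seeded from the one
master seed, so a run is fully reproducible; the report is a plain dict of
numbers recomputable from config + inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Any

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

from . import checklist_prep as prep
from . import connectivity as conn
from . import env_predictors as env
from . import model_eval as ev
from . import niche_overlap as ov
from . import sdm_ensemble as sdm
from . import synthetic_data as syn

__version__ = "0.1.0"

log = logging.getLogger("nicheshift")

PERIODS = ("historic", "current")

# stable stage identifiers for seed derivation
_STAGES = (
    "landscape",
    "checklists_historic",
    "checklists_current",
    "split_historic",
    "split_current",
    "subsample_historic",
    "subsample_current",
    "train_historic",
    "train_current",
    "partial_dependence",
    "overlap",
    "nodes",
)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (< 2**31) from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31 - 1)) for name, s in zip(_STAGES, state)}


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "scenario": {
        "kind": "stable",  # or "shift"
        "driver": "bio05",
        "shift_sd": 2.0,
        "niche_height": 2.0,
        "niche_width_sd": 0.8,
        "n_checklists": 4000,  # per period
        "sampling_margin_frac": 0.2,  # effort restricted to the interior
        "landscape": {
            "grid_rows": 60,
            "grid_cols": 60,
            "cell_size": 1000.0,
            "autocorrelation_scale": 8000.0,
            "climate_change_delta": 1.0,
            "landcover_change_fraction": 0.05,
        },
        "effort": {
            "duration_rate": 3.0,
            "time_of_day_peak": 6.0,
            "time_of_day_width_hours": 6.0,
            "spatial_bias_weight": 1.0,
            "checklist_intensity": 1.0,
        },
    },
    "prep": {
        "max_duration_hours": 5.0,
        "max_distance_km": 5.0,
        "max_observers": 10,
        "presence_buffer_km": None,  # spatial retention buffer; None disables
        "hex_size_km": 2.5,
        "train_fraction": 0.8,
    },
    "predictors": {
        "corr_threshold": 0.7,
        "candidates": "bioclim+landcover+terrain",  # or explicit list
    },
    "sdm": {
        "n_replicates": 10,
        "trees_per_replicate": 500,
        "start_hour": 6.0,
        "pd_n_reference": 1000,
        "pd_n_values": 25,
    },
    "overlap": {"n_bins": 100, "n_sim": 100},
    "connectivity": {
        "buffer_km": 8.0,  # scaled down from 600 km for desk-scale rasters
        "n_nodes": 18,
        "percentile": 75.0,
        "shape_c": 8.0,
        "neighbours": 8,
    },
}


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides onto the defaults."""

    def merge(base: dict, over: dict) -> dict:
        out = dict(base)
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(out.get(k), dict):
                out[k] = merge(out[k], v)
            else:
                out[k] = v
        return out

    return merge(DEFAULT_CONFIG, overrides or {})


def _candidate_predictors(stack, spec: str | list[str]) -> list[str]:
    if isinstance(spec, list):
        return spec
    names: list[str] = []
    if "bioclim" in spec:
        names += [n for n in env.BIOCLIM_NAMES if n in stack]
    if "landcover" in spec:
        names += [n for n in stack.layer_names if n.startswith("lc_")]
    if "terrain" in spec:
        names += [n for n in ("elevation", "dist_freshwater", "dist_coast") if n in stack]
    return names


def _sampling_mask(grid, margin_frac: float) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    r0 = int(round(margin_frac * grid.nrows))
    c0 = int(round(margin_frac * grid.ncols))
    mask[r0 : grid.nrows - r0, c0 : grid.ncols - c0] = True
    return mask


def run_pipeline(config: dict | None = None, outdir: str | None = None) -> dict:
    """Execute the full workflow; returns the machine-readable run report."""
    cfg = merge_config(config)
    seeds = stage_seeds(int(cfg["seed"]))
    log.info("master seed %s; stage seeds %s", cfg["seed"], seeds)
    report: dict[str, Any] = {
        "software_version": __version__,
        "config": cfg,
        "stages_completed": [],
    }
    try:
        result = _run_stages(cfg, seeds, report, outdir)
    except Exception as exc:  # annotate which stage died
        raise RuntimeError(
            f"pipeline failed at stage {report['stages_completed'][-1] if report['stages_completed'] else 'init'}: {exc}"
        ) from exc
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(sanitize(result), fh, indent=2, sort_keys=True)
    return sanitize(result)


def _run_stages(cfg: dict, seeds: dict[str, int], report: dict, outdir: str | None) -> dict:
    sc = cfg["scenario"]
    land_cfg = syn.LandscapeConfig(seed=seeds["landscape"], **sc["landscape"])
    hist_raw, curr_raw = syn.generate_landscape(land_cfg)
    hist_env = env.with_bioclim(hist_raw)
    curr_env = env.with_bioclim(curr_raw)
    report["stages_completed"].append("landscape")

    driver = sc["driver"]
    niche_hist = syn.gaussian_response_niche(
        hist_env, driver, optimum_sd=0.0, width_sd=sc["niche_width_sd"],
        height=sc["niche_height"], period_label="historic",
    )
    shift = sc["shift_sd"] if sc["kind"] == "shift" else 0.0
    niche_curr = syn.gaussian_response_niche(
        hist_env, driver, optimum_sd=shift, width_sd=sc["niche_width_sd"],
        height=sc["niche_height"], period_label="current",
    )
    effort = syn.EffortModel(**sc["effort"])
    stacks = {"historic": hist_env, "current": curr_env}
    niches = {"historic": niche_hist, "current": niche_curr}
    mask = _sampling_mask(hist_env.grid, sc["sampling_margin_frac"])
    checklists = {
        p: syn.simulate_checklists(
            stacks[p], niches[p], effort, sc["n_checklists"], seeds[f"checklists_{p}"],
            sampling_mask=mask,
        )
        for p in PERIODS
    }
    report["stages_completed"].append("simulate")
    report["n_checklists"] = {p: len(checklists[p]) for p in PERIODS}

    pp = cfg["prep"]
    fspec = prep.FilterSpec(
        max_duration_hours=pp["max_duration_hours"],
        max_distance_km=pp["max_distance_km"],
        max_observers=pp["max_observers"],
        buffer_km=pp["presence_buffer_km"],
    )
    filtered, filter_reports = {}, {}
    for p in PERIODS:
        filtered[p], filter_reports[p] = prep.filter_checklists(checklists[p], fspec)
        log.info("%s: %d checklists after filters; dropped %s",
                 p, len(filtered[p]), filter_reports[p])
    report["filter_reports"] = filter_reports
    report["stages_completed"].append("prepare")

    # collinearity pruning on historic-period cell values of all candidates
    candidates = _candidate_predictors(hist_env, cfg["predictors"]["candidates"])
    cell_table = pd.DataFrame(
        {name: hist_env[name].ravel() for name in candidates}
    ).dropna()
    coll = env.vif_prune(cell_table, cfg["predictors"]["corr_threshold"])
    retained = coll.retained
    if driver not in retained:  # the generator's driver must stay a model input
        retained = retained + [driver]
    report["collinearity"] = coll.to_dict()
    report["retained_predictors"] = retained
    report["stages_completed"].append("predictors")

    # split before subsampling so held-out rows never enter any replicate
    sd = cfg["sdm"]
    model_tables, test_tables, train_pools = {}, {}, {}
    for p in PERIODS:
        train_pool, test_pool = prep.train_test_split(
            filtered[p], pp["train_fraction"], seeds[f"split_{p}"]
        )
        sub_seeds = np.random.SeedSequence(seeds[f"subsample_{p}"]).generate_state(
            sd["n_replicates"] + 1
        ) % (2**31 - 1)
        reps = []
        for i in range(sd["n_replicates"]):
            s = prep.spatiotemporal_subsample(train_pool, pp["hex_size_km"], int(sub_seeds[i]))
            tbl, _ = env.extract_predictors(s, stacks[p], retained)
            reps.append(tbl)
        model_tables[p] = reps
        test_sub = prep.spatiotemporal_subsample(
            test_pool, pp["hex_size_km"], int(sub_seeds[-1])
        )
        test_tables[p], _ = env.extract_predictors(test_sub, stacks[p], retained)
        train_pools[p] = train_pool
    report["n_model_rows"] = {
        p: [len(t) for t in model_tables[p]] for p in PERIODS
    }
    report["stages_completed"].append("subsample_split")

    ensembles = {
        p: sdm.train_ensemble(
            model_tables[p],
            n_replicates=sd["n_replicates"],
            trees_per_replicate=sd["trees_per_replicate"],
            seed=seeds[f"train_{p}"],
            period_label=p,
        )
        for p in PERIODS
    }
    report["stages_completed"].append("train")

    std = sdm.EffortStandard(start_hour=sd["start_hour"])
    maps = {
        (mp, ep): sdm.predict_map(ensembles[mp], stacks[ep], std)
        for mp in PERIODS
        for ep in PERIODS
    }
    report["stages_completed"].append("predict")

    metrics = {}
    thresholds = {}
    for p in PERIODS:
        other = "current" if p == "historic" else "historic"
        m = ev.transferability(ensembles[p], test_tables[p], test_tables[other])
        metrics[p] = m.to_dict()
        thresholds[p] = m.threshold
        log.info("%s model: AUC own %.3f, opposite %.3f; max-SSS threshold %.3f",
                 p, m.auc_own, m.auc_opposite, m.threshold)
    report["metrics"] = metrics
    report["stages_completed"].append("evaluate")

    cell_area = hist_env.grid.cell_area_km2
    range_change = {}
    for p in PERIODS:
        rc = ev.range_change_map(
            maps[(p, "historic")], maps[(p, "current")], thresholds[p], cell_area
        )
        range_change[f"{p}_model"] = {
            "suitable_area_km2_1979": rc.area_km2_period1,
            "suitable_area_km2_2019": rc.area_km2_period2,
            "category_counts": rc.category_counts(),
        }
    report["range_change"] = range_change
    report["stages_completed"].append("range_change")

    importance = {}
    for p in PERIODS:
        imp = sdm.gini_importance(ensembles[p])
        importance[p] = imp.to_dict(orient="records")
    report["importance"] = importance
    pd_curve = sdm.partial_dependence(
        ensembles["current"],
        driver,
        model_tables["current"][0],
        n_reference=sd["pd_n_reference"],
        n_values=sd["pd_n_values"],
        seed=seeds["partial_dependence"],
    )
    report["partial_dependence"] = {
        "predictor": pd_curve.predictor,
        "values": pd_curve.values.tolist(),
        "marginal_effect": pd_curve.marginal_effect.tolist(),
    }
    report["stages_completed"].append("explain")

    occ = {}
    for p in PERIODS:
        det = filtered[p][filtered[p]["species_detected"] == 1]
        tbl, _ = env.extract_predictors(det, stacks[p], retained)
        occ[p] = tbl[retained]
    ovl = cfg["overlap"]
    overlap = ov.similarity_test(
        occ["historic"], occ["current"], n_sim=ovl["n_sim"], seed=seeds["overlap"],
        n_bins=ovl["n_bins"],
    )
    res = overlap.to_dict()
    res["null_I_mean"] = float(np.mean(overlap.null_I))
    del res["null_I"]
    report["overlap"] = res
    lco = ov.landcover_occupancy(
        pd.concat([filtered[p] for p in PERIODS], ignore_index=True), hist_env
    )
    report["landcover_occupancy"] = lco.to_dict(orient="records")
    report["stages_completed"].append("overlap")

    cc = cfg["connectivity"]
    det_curr = filtered["current"][filtered["current"]["species_detected"] == 1]
    hull = MultiPoint(
        np.column_stack([det_curr["x"].to_numpy(), det_curr["y"].to_numpy()])
    ).convex_hull
    nodes = conn.sample_buffer_nodes(
        hull, hist_env.grid, buffer_km=cc["buffer_km"], n_nodes=cc["n_nodes"],
        seed=seeds["nodes"],
    )
    xc, yc = hist_env.grid.cell_centers()
    range_mask = shapely.contains_xy(hull, xc.ravel(), yc.ravel()).reshape(
        hist_env.grid.shape
    )
    # per-period resistance from the current-period model's predictions
    cur_maps = {}
    for ep in PERIODS:
        surface = conn.suitability_to_resistance(maps[("current", ep)], cc["shape_c"])
        cur_maps[ep] = conn.solve_pairwise_current(
            surface, nodes, neighbours=cc["neighbours"], range_mask=range_mask
        )
    change = conn.classify_connectivity_change(
        cur_maps["historic"], cur_maps["current"], cc["percentile"], range_mask
    )
    report["connectivity"] = {
        "n_nodes": len(nodes.cells),
        "category_counts": change.category_counts(),
        "current_percentile_threshold_1979": change.threshold1,
        "current_percentile_threshold_2019": change.threshold2,
    }
    report["stages_completed"].append("connectivity")
    return report


def sanitize(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return sanitize(dataclasses.asdict(obj))
    return obj
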
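"""Canned synthetic study conditions for validation experiments.

Two named scenarios mirror the scientific hypotheses the pipeline is built
to separate:

- stable: both periods share one niche (a unimodal response to a single
  climate driver); the environment may still change between periods, so
  habitat availability can move while habitat associations do not.
- shift: the niche optimum moves along the driver by a stated number of
  pooled standard deviations between periods, so the realized niche itself
  changes.

The helpers here run the checklist -> SDM -> transferability chain at a
configurable problem size and return the quantities the validation
experiments measure (forecast delta-AUC, occurrence predictor tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import checklist_prep as prep
from . import env_predictors as env
from . import model_eval as ev
from . import sdm_ensemble as sdm
from . import synthetic_data as syn

#: environmental predictors used by the scenario SDMs (mutually weakly
#: correlated; includes the niche driver bio05)
SCENARIO_PREDICTORS = [
    "bio05",
    "elevation",
    "dist_freshwater",
    "dist_coast",
    "lc_forest",
    "lc_urban",
]

DRIVER = "bio05"


@dataclass
class TwoPeriodDataset:
    """Simulated checklists and environments for both periods."""

    stacks: dict
    niches: dict
    checklists: dict  # filtered tables per period
    true_suitability: dict


def simulate_two_period_dataset(
    seed: int,
    shift_sd: float = 0.0,
    n_checklists: int = 4000,
    grid_rows: int = 50,
    grid_cols: int = 50,
    climate_change_delta: float = 1.0,
    niche_height: float = 2.0,
    niche_width_sd: float = 0.8,
) -> TwoPeriodDataset:
    """Generate and quality-filter checklists under a stable or shifted niche."""
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31 - 1)
    cfg = syn.LandscapeConfig(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        climate_change_delta=climate_change_delta,
        landcover_change_fraction=0.05,
        seed=int(ss[0]),
    )
    hist_raw, curr_raw = syn.generate_landscape(cfg)
    stacks = {"historic": env.with_bioclim(hist_raw), "current": env.with_bioclim(curr_raw)}
    niches = {
        "historic": syn.gaussian_response_niche(
            stacks["historic"], DRIVER, optimum_sd=0.0, width_sd=niche_width_sd,
            height=niche_height, period_label="historic",
        ),
        "current": syn.gaussian_response_niche(
            stacks["historic"], DRIVER, optimum_sd=shift_sd, width_sd=niche_width_sd,
            height=niche_height, period_label="current",
        ),
    }
    effort = syn.EffortModel()
    fspec = prep.FilterSpec(buffer_km=None)
    checklists, truths = {}, {}
    for i, p in enumerate(("historic", "current")):
        raw = syn.simulate_checklists(
            stacks[p], niches[p], effort, n_checklists, int(ss[1 + i])
        )
        checklists[p], _ = prep.filter_checklists(raw, fspec)
        truths[p] = syn.true_suitability(stacks[p], niches[p])
    return TwoPeriodDataset(
        stacks=stacks, niches=niches, checklists=checklists, true_suitability=truths
    )


def prepare_model_tables(
    data: TwoPeriodDataset,
    period: str,
    seed: int,
    hex_size_km: float = 2.5,
    train_fraction: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subsampled train/test model tables for one period (split drawn first
    so the held-out rows never enter training)."""
    ss = np.random.SeedSequence(seed).generate_state(3) % (2**31 - 1)
    train_pool, test_pool = prep.train_test_split(
        data.checklists[period], train_fraction, int(ss[0])
    )
    train_sub = prep.spatiotemporal_subsample(train_pool, hex_size_km, int(ss[1]))
    test_sub = prep.spatiotemporal_subsample(test_pool, hex_size_km, int(ss[2]))
    train_tbl, _ = env.extract_predictors(train_sub, data.stacks[period], SCENARIO_PREDICTORS)
    test_tbl, _ = env.extract_predictors(test_sub, data.stacks[period], SCENARIO_PREDICTORS)
    return train_tbl, test_tbl


def forecast_transferability(
    seed: int,
    shift_sd: float = 0.0,
    n_checklists: int = 4000,
    n_replicates: int = 3,
    trees_per_replicate: int = 150,
    **dataset_kwargs,
) -> ev.EvaluationMetrics:
    """Historic-model transferability to the current period (forecast).

    Returns the metrics whose delta_auc is near 0 when the niche is stable
    and negative when the niche shifted between the periods.
    """
    data = simulate_two_period_dataset(
        seed, shift_sd=shift_sd, n_checklists=n_checklists, **dataset_kwargs
    )
    ss = np.random.SeedSequence((seed, 1)).generate_state(3) % (2**31 - 1)
    train_h, test_h = prepare_model_tables(data, "historic", int(ss[0]))
    _, test_c = prepare_model_tables(data, "current", int(ss[1]))
    ensemble = sdm.train_ensemble(
        train_h,
        n_replicates=n_replicates,
        trees_per_replicate=trees_per_replicate,
        seed=int(ss[2]),
        period_label="historic",
    )
    return ev.transferability(ensemble, test_h, test_c)


def sample_occurrences(
    stack, niche, n: int, seed: int, predictors: list[str] = SCENARIO_PREDICTORS
) -> pd.DataFrame:
    """Draw n occurrence predictor rows, cells weighted by true suitability.

    This is the occurrence-level view of the checklist generative model
    (detections land in cells with probability proportional to suitability),
    used for replicated niche-overlap experiments where simulating full
    checklist tables per replicate adds nothing but runtime.
    """
    rng = np.random.default_rng(seed)
    suit = syn.true_suitability(stack, niche).ravel()
    w = np.where(np.isnan(suit), 0.0, suit)
    w = w / w.sum()
    cells = rng.choice(len(w), size=n, p=w)
    r, c = np.unravel_index(cells, stack.grid.shape)
    return pd.DataFrame({p: stack[p][r, c] for p in predictors})


def occurrence_predictor_tables(
    data: TwoPeriodDataset,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predictor values at each period's detection points (niche-overlap input)."""
    out = []
    for p in ("historic", "current"):
        det = data.checklists[p][data.checklists[p]["species_detected"] == 1]
        tbl, _ = env.extract_predictors(det, data.stacks[p], SCENARIO_PREDICTORS)
        out.append(tbl[SCENARIO_PREDICTORS])
    return out[0], out[1]
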
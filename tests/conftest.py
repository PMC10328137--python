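import numpy as np
import pandas as pd
import pytest

from nicheshift import (
    EffortModel,
    GridSpec,
    LandscapeConfig,
    generate_landscape,
    simulate_checklists,
    with_bioclim,
)
from nicheshift.synthetic_data import gaussian_response_niche, standardized_niche


@pytest.fixture(scope="session")
def small_landscape():
    """One 40x40 landscape pair with mild between-period change."""
    cfg = LandscapeConfig(
        grid_rows=40, grid_cols=40, climate_change_delta=1.0,
        landcover_change_fraction=0.05, seed=7,
    )
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def hist_env(small_landscape):
    return with_bioclim(small_landscape[0])


@pytest.fixture(scope="session")
def linear_niche(hist_env):
    """Monotone single-driver niche on maximum warm-month temperature."""
    return standardized_niche(hist_env, {"bio05": (2.0, 0.0)}, intercept=0.0)


@pytest.fixture(scope="session")
def unimodal_niche(hist_env):
    return gaussian_response_niche(hist_env, "bio05", optimum_sd=0.0, width_sd=0.8)


@pytest.fixture(scope="session")
def checklists(hist_env, linear_niche):
    return simulate_checklists(hist_env, linear_niche, EffortModel(), 3000, seed=21)


@pytest.fixture()
def toy_checklists():
    """Five-row fixture with two single-rule violations (6 h; 10 observers)."""
    return pd.DataFrame(
        {
            "checklist_id": [f"T{i}" for i in range(5)],
            "x": [500.0, 1500.0, 2500.0, 3500.0, 4500.0],
            "y": [500.0] * 5,
            "date": ["1975-06-01"] * 5,
            "start_hour": [6.0] * 5,
            "duration_hours": [1.0, 6.0, 2.0, 1.0, 3.0],
            "distance_km": [1.0, 1.0, 2.0, 1.0, 0.5],
            "n_observers": [1, 2, 3, 10, 9],
            "species_detected": [1, 0, 1, 0, 1],
            "period": ["historic"] * 5,
        }
    )


@pytest.fixture()
def unit_grid():
    return GridSpec(nrows=4, ncols=5, cell_size=1000.0)
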
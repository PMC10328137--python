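"""Two-period synthetic landscapes, true niches, and effort-biased checklists.

This module generates the ground truth the rest of the pipeline is tested
against: spatially autocorrelated monthly climate, fractional land cover,
elevation and water-distance layers for two time periods with controllable
between-period change; a known per-period suitability function; and complete
survey checklists whose detection outcome mixes that suitability with an
explicit observation-effort process (duration saturation, time-of-day peak,
spatially biased site selection). Identical seeds reproduce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, MultiLineString

from .grid import GridSpec, PredictorStack

LANDCOVER_CLASSES = ("urban", "forest", "grassland", "wetland", "cropland")

#: date ranges of the two study decades (inclusive)
PERIOD_DATES = {
    "historic": ("1970-01-01", "1979-12-31"),
    "current": ("2010-01-01", "2019-12-31"),
}

CHECKLIST_COLUMNS = [
    "checklist_id",
    "x",
    "y",
    "date",
    "start_hour",
    "duration_hours",
    "distance_km",
    "n_observers",
    "species_detected",
    "period",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic two-period landscape.

    climate_change_delta is added (degrees C) to every period-2 monthly
    temperature layer; landcover_change_fraction is the proportion of cells
    whose dominant land-cover class differs between periods.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    cell_size: float = 1000.0  # metres
    autocorrelation_scale: float = 8000.0  # metres, Gaussian smoothing length
    climate_change_delta: float = 0.0
    landcover_change_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid_rows and grid_cols must be >= 8")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.autocorrelation_scale <= 0:
            raise ValueError("autocorrelation_scale must be positive")
        if not 0.0 <= self.landcover_change_fraction <= 1.0:
            raise ValueError("landcover_change_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TrueNiche:
    """Known suitability function: logistic of a quadratic form in predictors.

    coefficients maps a predictor layer name to (linear, quadratic) weights on
    the raw layer values; suitability = logistic(intercept + sum of terms).
    """

    coefficients: dict[str, tuple[float, float]]
    intercept: float = 0.0
    period_label: str = ""


@dataclass(frozen=True)
class EffortModel:
    """Observation process: detectability and site-selection bias.

    Detectability = (1 - exp(-duration_rate * hours)) * bell(start hour),
    with the bell a Gaussian of width time_of_day_width_hours peaking at
    time_of_day_peak. spatial_bias_weight scales log-intensity of a smooth
    random oversampling field (0 = spatially uniform effort).
    """

    duration_rate: float = 3.0  # per hour; 1 h -> ~0.95 saturation
    time_of_day_peak: float = 6.0  # hours after midnight
    time_of_day_width_hours: float = 6.0
    spatial_bias_weight: float = 1.0
    checklist_intensity: float = 1.0  # expected checklists per cell per year

    def __post_init__(self) -> None:
        if self.duration_rate <= 0 or self.time_of_day_width_hours <= 0:
            raise ValueError("duration_rate and time_of_day_width_hours must be > 0")
        if self.checklist_intensity <= 0:
            raise ValueError("checklist_intensity must be > 0")

    def detectability(self, duration_hours, start_hour):
        """Detection probability multiplier in [0, 1], non-decreasing in duration."""
        dur = 1.0 - np.exp(-self.duration_rate * np.asarray(duration_hours, dtype=float))
        tod = np.exp(
            -0.5
            * ((np.asarray(start_hour, dtype=float) - self.time_of_day_peak)
               / self.time_of_day_width_hours) ** 2
        )
        return dur * tod


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Standardized Gaussian random field: smoothed white noise, mean 0, SD 1."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / sd if sd > 0 else z


def _freshwater_lines(rng: np.random.Generator, grid: GridSpec, n_lines: int = 3) -> MultiLineString:
    """Seeded random polylines (rivers) crossing the grid west to east."""
    xmin, ymin, xmax, ymax = grid.extent
    lines = []
    for _ in range(n_lines):
        n_pts = 12
        xs = np.linspace(xmin, xmax, n_pts)
        y = rng.uniform(ymin + 0.15 * (ymax - ymin), ymax - 0.05 * (ymax - ymin))
        ys = np.clip(
            y + np.cumsum(rng.normal(0, 0.04 * (ymax - ymin), n_pts)),
            ymin, ymax,
        )
        lines.append(LineString(np.column_stack([xs, ys])))
    return MultiLineString(lines)


def generate_landscape(config: LandscapeConfig) -> tuple[PredictorStack, PredictorStack]:
    """Build co-registered (historic, current) predictor stacks.

    Each stack holds tmin_01..tmin_12, tmax_01..tmax_12, prec_01..prec_12,
    lc_<class> fractional covers (summing to 1 per cell), elevation,
    dist_freshwater and dist_coast (km). The current stack equals the historic
    one plus the configured temperature delta and dominant-land-cover churn.
    """
    rng = np.random.default_rng(config.seed)
    grid = GridSpec(config.grid_rows, config.grid_cols, config.cell_size)
    shape = grid.shape
    sigma = config.autocorrelation_scale / config.cell_size

    # spatial temperature pattern: south-north gradient + autocorrelated field
    yc = np.linspace(0.0, 1.0, config.grid_rows)[:, None] * np.ones(shape)
    t_pattern = -6.0 * yc + 3.0 * _smooth_field(rng, shape, sigma)
    diurnal = 8.0 + 2.0 * _smooth_field(rng, shape, sigma)  # tmax - tmin spread
    season = 10.0 * np.cos(2 * np.pi * (np.arange(12) - 6) / 12.0)  # peak in July

    layers: dict[str, np.ndarray] = {}
    for m in range(12):
        tavg = 15.0 + season[m] + t_pattern
        layers[f"tmin_{m + 1:02d}"] = tavg - diurnal / 2.0
        layers[f"tmax_{m + 1:02d}"] = tavg + diurnal / 2.0
    prec_pattern = _smooth_field(rng, shape, sigma)
    prec_season = 1.0 + 0.5 * np.sin(2 * np.pi * np.arange(12) / 12.0)
    for m in range(12):
        layers[f"prec_{m + 1:02d}"] = 60.0 * prec_season[m] * np.exp(0.6 * prec_pattern)

    # fractional land cover via softmax over per-class random fields
    scores = np.stack([_smooth_field(rng, shape, sigma) for _ in LANDCOVER_CLASSES])
    exps = np.exp(2.0 * scores)
    fracs = exps / exps.sum(axis=0)
    for i, cls in enumerate(LANDCOVER_CLASSES):
        layers[f"lc_{cls}"] = fracs[i]

    elev = _smooth_field(rng, shape, sigma)
    layers["elevation"] = 800.0 + 400.0 * elev

    # coastline = southern grid edge; freshwater = seeded random polylines
    xmin, ymin, xmax, _ = grid.extent
    coast = LineString([(xmin, ymin), (xmax, ymin)])
    rivers = _freshwater_lines(rng, grid)
    xc, ycoord = grid.cell_centers()
    pts = shapely.points(np.column_stack([xc.ravel(), ycoord.ravel()]))
    layers["dist_freshwater"] = (shapely.distance(pts, rivers).reshape(shape) / 1000.0)
    layers["dist_coast"] = (shapely.distance(pts, coast).reshape(shape) / 1000.0)

    historic = PredictorStack(
        grid=grid,
        layers=layers,
        period_label="historic",
        features={"freshwater": rivers, "coastline": coast},
    )

    current = historic.copy()
    current.period_label = "current"
    current.features = dict(historic.features)
    for m in range(12):
        current.layers[f"tmin_{m + 1:02d}"] = layers[f"tmin_{m + 1:02d}"] + config.climate_change_delta
        current.layers[f"tmax_{m + 1:02d}"] = layers[f"tmax_{m + 1:02d}"] + config.climate_change_delta

    n_change = int(round(config.landcover_change_fraction * grid.nrows * grid.ncols))
    if n_change > 0:
        flat = rng.choice(grid.nrows * grid.ncols, size=n_change, replace=False)
        rows, cols = np.unravel_index(flat, shape)
        frac_stack = np.stack([current.layers[f"lc_{c}"] for c in LANDCOVER_CLASSES])
        for r, c in zip(rows, cols):
            cell = frac_stack[:, r, c]
            dom = int(np.argmax(cell))
            others = [i for i in range(len(LANDCOVER_CLASSES)) if i != dom]
            new = int(rng.choice(others))
            cell[dom], cell[new] = cell[new], cell[dom]
            frac_stack[:, r, c] = cell
        for i, cls in enumerate(LANDCOVER_CLASSES):
            current.layers[f"lc_{cls}"] = frac_stack[i]

    return historic, current


def true_suitability(stack: PredictorStack, niche: TrueNiche) -> np.ndarray:
    """Per-cell logistic(intercept + sum of linear and quadratic terms)."""
    eta = np.full(stack.grid.shape, niche.intercept, dtype=float)
    for name, (lin, quad) in niche.coefficients.items():
        if name not in stack:
            raise KeyError(f"niche references predictor {name!r} missing from stack")
        x = stack[name]
        eta = eta + lin * x + quad * x * x
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def standardized_niche(
    stack: PredictorStack,
    terms: dict[str, tuple[float, float]],
    intercept: float = 0.0,
    period_label: str = "",
) -> TrueNiche:
    """Build a TrueNiche whose coefficients act on z-scored predictor values.

    terms gives (linear, quadratic) weights on z = (x - mean)/sd, with the
    mean/sd taken from the supplied stack; the returned niche carries the
    equivalent raw-scale coefficients so true_suitability needs no scaler.
    """
    coefs: dict[str, tuple[float, float]] = {}
    icpt = float(intercept)
    for name, (lin, quad) in terms.items():
        x = stack[name]
        m = float(np.nanmean(x))
        s = float(np.nanstd(x))
        if s == 0:
            raise ValueError(f"predictor {name!r} is constant; cannot standardize")
        raw_quad = quad / s**2
        raw_lin = lin / s - 2.0 * quad * m / s**2
        icpt += quad * m**2 / s**2 - lin * m / s
        coefs[name] = (raw_lin, raw_quad)
    return TrueNiche(coefficients=coefs, intercept=icpt, period_label=period_label)


def gaussian_response_niche(
    stack: PredictorStack,
    predictor: str,
    optimum_sd: float = 0.0,
    width_sd: float = 1.0,
    height: float = 2.0,
    period_label: str = "",
) -> TrueNiche:
    """Unimodal niche on one predictor: logistic(height - ((z - mu)/w)^2).

    mu = optimum_sd and w = width_sd are on the z-score scale of the supplied
    stack, so "shift the optimum by 2 SD" is optimum_sd=2. Peak suitability is
    logistic(height).
    """
    a = 1.0 / width_sd**2
    # height - a (z - mu)^2  =  (height - a mu^2) + 2 a mu z - a z^2
    return standardized_niche(
        stack,
        {predictor: (2.0 * a * optimum_sd, -a)},
        intercept=height - a * optimum_sd**2,
        period_label=period_label,
    )


def simulate_checklists(
    stack: PredictorStack,
    niche: TrueNiche,
    effort: EffortModel,
    n_checklists: int | None,
    seed: int,
    sampling_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate complete checklists with effort covariates and detections.

    Locations are drawn with site-selection bias exp(spatial_bias_weight * z)
    over a seeded smooth field z; detection ~ Bernoulli(true suitability at
    the cell times the effort detectability). n_checklists=None draws the
    count as Poisson(checklist_intensity * n_cells * 10 years). An optional
    boolean sampling_mask restricts survey sites to True cells (e.g. the
    interior of a study region), emulating unvisited margins.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    n_cells = grid.nrows * grid.ncols
    if n_checklists is None:
        n_checklists = int(rng.poisson(effort.checklist_intensity * n_cells * 10))
    if n_checklists < 1:
        raise ValueError("n_checklists must be >= 1")

    suit = true_suitability(stack, niche)

    bias = _smooth_field(rng, grid.shape, max(grid.nrows, grid.ncols) / 8.0)
    w = np.exp(effort.spatial_bias_weight * bias).ravel()
    if sampling_mask is not None:
        if sampling_mask.shape != grid.shape:
            raise ValueError("sampling_mask shape does not match the grid")
        w = w * sampling_mask.ravel()
        if w.sum() == 0:
            raise ValueError("sampling_mask leaves no cells to survey")
    w /= w.sum()
    cells = rng.choice(n_cells, size=n_checklists, p=w)
    row, col = np.unravel_index(cells, grid.shape)
    x = grid.x0 + (col + rng.uniform(0, 1, n_checklists)) * grid.cell_size
    y = grid.y0 + (row + rng.uniform(0, 1, n_checklists)) * grid.cell_size

    period = stack.period_label or "historic"
    start, end = PERIOD_DATES[period]
    day_span = (pd.Timestamp(end) - pd.Timestamp(start)).days + 1
    dates = pd.Timestamp(start) + pd.to_timedelta(
        rng.integers(0, day_span, n_checklists), unit="D"
    )

    start_hour = rng.uniform(4.0, 20.0, n_checklists)
    duration = np.clip(rng.exponential(1.5, n_checklists), 0.05, 8.0)
    distance = np.clip(rng.exponential(2.0, n_checklists), 0.0, 12.0)
    observers = np.minimum(rng.geometric(0.45, n_checklists), 12)

    p = suit[row, col] * effort.detectability(duration, start_hour)
    detected = (rng.uniform(0, 1, n_checklists) < p).astype(int)

    return pd.DataFrame(
        {
            "checklist_id": [f"{period[:1].upper()}{i:07d}" for i in range(n_checklists)],
            "x": x,
            "y": y,
            "date": dates.strftime("%Y-%m-%d"),
            "start_hour": start_hour,
            "duration_hours": duration,
            "distance_km": distance,
            "n_observers": observers,
            "species_detected": detected,
            "period": period,
        }
    )
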
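"""Bioclimatic variables, water distances, collinearity pruning, extraction.

The 19 bioclim variables (BIO1-BIO19) summarize 12 monthly minimum/maximum
temperature and precipitation layers into annual means, extremes, seasonality,
and quarter aggregates. Quarters are runs of 3 consecutive calendar months
with December-January wraparound; ties between equally wet/warm quarters go to
the earliest start month. Precipitation seasonality (BIO15) is the coefficient
of variation of monthly precipitation + 1 (sample SD), matching the convention
of the widely used biovars implementation. All layer math propagates NaN.

Collinearity pruning follows the pairwise-correlation / variance-inflation
rule: while any retained pair is correlated beyond the threshold, the member
of the worst pair with the greater VIF is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grid import PredictorStack

BIOCLIM_NAMES = tuple(f"bio{i:02d}" for i in range(1, 20))

EFFORT_COLUMNS = ["day_of_year", "start_hour", "duration_hours", "distance_km", "n_observers"]


def _quarter_windows(n: int = 12) -> np.ndarray:
    """Index array (12, 3): all 3-consecutive-month windows with wraparound."""
    return np.array([[(m + k) % n for k in range(3)] for m in range(n)])


def compute_bioclim(
    tmin: np.ndarray, tmax: np.ndarray, prec: np.ndarray
) -> dict[str, np.ndarray]:
    """Derive BIO1-BIO19 from stacked monthly layers of shape (12, ...).

    Temperatures in degrees C, precipitation in mm. Returns a dict keyed
    bio01..bio19.
    """
    for name, arr in (("tmin", tmin), ("tmax", tmax), ("prec", prec)):
        arr = np.asarray(arr)
        if arr.shape[0] != 12:
            raise ValueError(f"{name} must stack 12 monthly layers, got {arr.shape[0]}")
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    prec = np.asarray(prec, dtype=float)

    tavg = (tmin + tmax) / 2.0
    win = _quarter_windows()
    # quarter aggregates: (12, ...) per starting month
    q_tavg = tavg[win].mean(axis=1)
    q_prec = prec[win].sum(axis=1)

    # argmax/argmin pick the earliest start month on ties
    wettest = np.argmax(q_prec, axis=0)
    driest = np.argmin(q_prec, axis=0)
    warmest = np.argmax(q_tavg, axis=0)
    coldest = np.argmin(q_tavg, axis=0)

    def take(q: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(q, idx[None], axis=0)[0]

    out: dict[str, np.ndarray] = {}
    out["bio01"] = tavg.mean(axis=0)
    out["bio02"] = (tmax - tmin).mean(axis=0)
    out["bio04"] = 100.0 * tavg.std(axis=0, ddof=1)
    out["bio05"] = tmax.max(axis=0)
    out["bio06"] = tmin.min(axis=0)
    out["bio07"] = out["bio05"] - out["bio06"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["bio03"] = np.where(
            out["bio07"] != 0, 100.0 * out["bio02"] / out["bio07"], np.nan
        )
    out["bio08"] = take(q_tavg, wettest)
    out["bio09"] = take(q_tavg, driest)
    out["bio10"] = take(q_tavg, warmest)
    out["bio11"] = take(q_tavg, coldest)
    out["bio12"] = prec.sum(axis=0)
    out["bio13"] = prec.max(axis=0)
    out["bio14"] = prec.min(axis=0)
    p1 = prec + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["bio15"] = 100.0 * p1.std(axis=0, ddof=1) / p1.mean(axis=0)
    out["bio16"] = take(q_prec, wettest)
    out["bio17"] = take(q_prec, driest)
    out["bio18"] = take(q_prec, warmest)
    out["bio19"] = take(q_prec, coldest)
    return out


def with_bioclim(stack: PredictorStack) -> PredictorStack:
    """Return a copy of the stack with bio01..bio19 layers added."""
    missing = [
        f"{v}_{m:02d}"
        for v in ("tmin", "tmax", "prec")
        for m in range(1, 13)
        if f"{v}_{m:02d}" not in stack
    ]
    if missing:
        raise KeyError(f"stack is missing monthly layers: {missing[:3]}...")
    tmin = np.stack([stack[f"tmin_{m:02d}"] for m in range(1, 13)])
    tmax = np.stack([stack[f"tmax_{m:02d}"] for m in range(1, 13)])
    prec = np.stack([stack[f"prec_{m:02d}"] for m in range(1, 13)])
    out = stack.copy()
    for name, arr in compute_bioclim(tmin, tmax, prec).items():
        out.add(name, arr)
    return out


def distance_to_water(points_xy: np.ndarray, freshwater, coastline) -> tuple[np.ndarray, np.ndarray]:
    """Planar distances (km) from points (n, 2) in metres to the nearest
    freshwater feature and, separately, the nearest coastline feature."""
    for name, geom in (("freshwater", freshwater), ("coastline", coastline)):
        if geom is None or shapely.is_empty(geom):
            raise ValueError(f"{name} feature set is empty")
    pts = shapely.points(np.asarray(points_xy, dtype=float))
    return (
        shapely.distance(pts, freshwater) / 1000.0,
        shapely.distance(pts, coastline) / 1000.0,
    )


@dataclass
class CollinearityReport:
    """Outcome of iterative correlation/VIF pruning."""

    retained: list[str]
    dropped: list[dict] = field(default_factory=list)  # name, vif, partner, corr

    def to_dict(self) -> dict:
        return {"retained": self.retained, "dropped": self.dropped}


def _vif(df: pd.DataFrame, name: str) -> float:
    """Variance inflation factor of one column regressed on the others."""
    others = [c for c in df.columns if c != name]
    if not others:
        return 1.0
    X = np.column_stack([np.ones(len(df)), df[others].to_numpy()])
    y = df[name].to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_prune(predictors: pd.DataFrame, corr_threshold: float = 0.7) -> CollinearityReport:
    """Iteratively drop the higher-VIF member of the most correlated pair
    until no retained pair has |Pearson r| > corr_threshold."""
    if predictors.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if len(predictors) < predictors.shape[1] + 2:
        raise ValueError("need at least p + 2 rows")
    retained = list(predictors.columns)
    dropped: list[dict] = []
    while len(retained) > 1:
        corr = predictors[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= corr_threshold:
            break
        a, b = retained[i], retained[j]
        sub = predictors[retained]
        vif_a, vif_b = _vif(sub, a), _vif(sub, b)
        loser, loser_vif, partner = (
            (a, vif_a, b) if vif_a >= vif_b else (b, vif_b, a)
        )
        dropped.append(
            {
                "name": loser,
                "vif": None if np.isinf(loser_vif) else float(loser_vif),
                "partner": partner,
                "corr": float(corr[i, j]),
            }
        )
        retained.remove(loser)
    return CollinearityReport(retained=retained, dropped=dropped)


def extract_predictors(
    checklists: pd.DataFrame,
    stack: PredictorStack,
    predictors: list[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Attach predictor values at each checklist's cell plus effort covariates.

    Returns (model table, n_excluded); rows falling outside the grid extent or
    on a nodata cell are excluded and counted, never silently filled.
    """
    if predictors is None:
        predictors = stack.layer_names
    missing = [p for p in predictors if p not in stack]
    if missing:
        raise KeyError(f"stack is missing predictor layers: {missing}")
    row, col = stack.grid.cell_of(checklists["x"].to_numpy(), checklists["y"].to_numpy())
    ok = (row >= 0) & (col >= 0)
    vals = {}
    r, c = row[ok], col[ok]
    for p in predictors:
        vals[p] = stack[p][r, c]
    tbl = pd.DataFrame(vals)
    nod = tbl.isna().any(axis=1).to_numpy()
    sub = checklists[ok].reset_index(drop=True)
    tbl = tbl[~nod].reset_index(drop=True)
    sub = sub[~nod].reset_index(drop=True)
    tbl["day_of_year"] = pd.to_datetime(sub["date"]).dt.dayofyear.to_numpy()
    for covar in ("start_hour", "duration_hours", "distance_km", "n_observers"):
        tbl[covar] = sub[covar].to_numpy()
    tbl["species_detected"] = sub["species_detected"].to_numpy()
    n_excluded = int((~ok).sum() + nod.sum())
    return tbl, n_excluded
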
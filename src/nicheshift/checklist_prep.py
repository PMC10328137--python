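"""Checklist quality filtering, spatiotemporal subsampling, and partitioning.

Complete checklists are the observation unit: a non-detection on a complete
checklist is treated as an inferred absence. Filtering keeps short, local,
small-party surveys (duration < 5 h, distance < 5 km, fewer than 10
observers), drops presences outside a plausible range polygon, and restricts
the dataset to checklists within a buffer of the surviving presences.
Subsampling keeps at most one presence and one absence per hexagon-week to
damp spatial and temporal effort clumping before model fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class FilterSpec:
    """Quality-filter bounds. "Less than" bounds are strict."""

    max_duration_hours: float = 5.0
    max_distance_km: float = 5.0
    max_observers: int = 10  # strictly fewer than this many
    range_polygon: Polygon | None = None
    buffer_km: float | None = 600.0

    def __post_init__(self) -> None:
        if self.max_duration_hours <= 0 or self.max_distance_km <= 0 or self.max_observers <= 0:
            raise ValueError("filter bounds must be positive")


def filter_checklists(
    table: pd.DataFrame, spec: FilterSpec = FilterSpec()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply quality filters; returns (filtered table, drop report).

    Rules, applied in order: duration < max_duration_hours, distance <
    max_distance_km, observers < max_observers; detections outside
    range_polygon dropped; finally only checklists within buffer_km of a
    surviving presence are kept. The report counts rows dropped per rule.
    """
    if table.empty:
        raise ValueError("checklist table is empty")
    report: dict[str, int] = {}
    df = table

    keep = df["duration_hours"] < spec.max_duration_hours
    report["duration"] = int((~keep).sum())
    df = df[keep]

    keep = df["distance_km"] < spec.max_distance_km
    report["distance"] = int((~keep).sum())
    df = df[keep]

    keep = df["n_observers"] < spec.max_observers
    report["observers"] = int((~keep).sum())
    df = df[keep]

    if spec.range_polygon is not None and not df.empty:
        pts = shapely.points(np.column_stack([df["x"].to_numpy(), df["y"].to_numpy()]))
        inside = shapely.intersects(spec.range_polygon, pts)
        drop = (df["species_detected"].to_numpy() == 1) & ~inside
        report["presence_outside_range"] = int(drop.sum())
        df = df[~drop]
    else:
        report["presence_outside_range"] = 0

    if spec.buffer_km is not None and not df.empty:
        pres = df[df["species_detected"] == 1]
        if len(pres) == 0:
            report["outside_presence_buffer"] = 0
        else:
            pres_pts = shapely.multipoints(
                np.column_stack([pres["x"].to_numpy(), pres["y"].to_numpy()])
            )
            pts = shapely.points(np.column_stack([df["x"].to_numpy(), df["y"].to_numpy()]))
            d = shapely.distance(pts, pres_pts) / 1000.0
            keep = d <= spec.buffer_km
            report["outside_presence_buffer"] = int((~keep).sum())
            df = df[keep]
    else:
        report["outside_presence_buffer"] = 0

    if df.empty:
        import warnings

        warnings.warn("all checklists removed by filters", stacklevel=2)
    return df.reset_index(drop=True), report


def hex_index(x: np.ndarray, y: np.ndarray, size_km: float = 2.5) -> tuple[np.ndarray, np.ndarray]:
    """Axial (q, r) indices of flat-topped hexagons containing points (metres).

    size_km is the hexagon's short diagonal (width across flats); the
    circumradius is size_km/sqrt(3). The grid is anchored at the coordinate
    origin.
    """
    R = size_km * 1000.0 / SQRT3
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    qf = (2.0 / 3.0) * x / R
    rf = (-1.0 / 3.0 * x + SQRT3 / 3.0 * y) / R
    # cube rounding
    sf = -qf - rf
    q = np.rint(qf)
    r = np.rint(rf)
    s = np.rint(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(int), r.astype(int)


def spatiotemporal_subsample(
    table: pd.DataFrame, hex_size_km: float = 2.5, seed: int = 0
) -> pd.DataFrame:
    """Keep at most one presence and one absence per (hexagon, ISO week).

    Candidates within a stratum are chosen uniformly at random with the given
    seed; rows are ordered by checklist_id before drawing so the selection is
    independent of input row order.
    """
    if table.empty:
        return table.copy()
    df = table.sort_values("checklist_id", kind="mergesort").reset_index(drop=True)
    q, r = hex_index(df["x"].to_numpy(), df["y"].to_numpy(), hex_size_km)
    iso = pd.to_datetime(df["date"]).dt.isocalendar()
    strata = pd.DataFrame(
        {
            "q": q,
            "r": r,
            "iso_year": iso["year"].to_numpy(),
            "iso_week": iso["week"].to_numpy(),
            "det": df["species_detected"].to_numpy(),
        }
    )
    rng = np.random.default_rng(seed)
    # one uniform draw per row; the min-key row per (stratum, class) survives
    strata["key"] = rng.uniform(size=len(df))
    grp = strata.groupby(["q", "r", "iso_year", "iso_week", "det"], sort=True)
    winners = grp["key"].idxmin().to_numpy()
    out = df.loc[np.sort(winners)]
    return out.reset_index(drop=True)


def train_test_split(
    table: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test partition stratified by detection outcome.

    The overall train size is round(train_fraction * n), allocated across the
    two classes by largest remainder so both partitions keep presences.
    """
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 checklists to split")
    det = table["species_detected"].to_numpy()
    n_pres = int((det == 1).sum())
    n_abs = n - n_pres
    if n_pres < 2 or n_abs < 2:
        raise ValueError(
            f"too few rows to stratify: {n_pres} presences, {n_abs} absences "
            "(need at least 2 of each)"
        )
    k_total = int(round(train_fraction * n))
    # largest-remainder allocation of train slots to the two classes
    quota = {1: train_fraction * n_pres, 0: train_fraction * n_abs}
    k = {c: int(math.floor(quota[c])) for c in quota}
    rem = k_total - sum(k.values())
    for c in sorted(quota, key=lambda c: quota[c] - k[c], reverse=True)[:rem]:
        k[c] += 1
    for c, n_c in ((1, n_pres), (0, n_abs)):
        k[c] = min(max(k[c], 1), n_c - 1)  # both partitions see both classes

    rng = np.random.default_rng(seed)
    train_idx = []
    for c, n_c in ((1, n_pres), (0, n_abs)):
        idx = np.flatnonzero(det == c)
        train_idx.append(rng.choice(idx, size=k[c], replace=False))
    train_idx = np.sort(np.concatenate(train_idx))
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return (
        table.iloc[mask].reset_index(drop=True),
        table.iloc[~mask].reset_index(drop=True),
    )
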
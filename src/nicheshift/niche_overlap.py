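"""Land-cover occupancy and ordination-based niche-similarity testing.

The realized niche of each period is summarized as a normalized occurrence
density over a 100x100 binning of the first two principal components of the
environmental predictors at occurrence points (PCA fit once on both periods
pooled, predictors z-scored). Overlap between the two period densities is
Warren's I (a Hellinger-distance statistic in [0, 1]; 1 = identical niches),
compared against a null built by randomly reassigning occurrences to the two
periods. Cells of environmental space not sampled by both periods are masked
before comparison so non-analog environments cannot drive the statistic.

Densities are raw binned frequencies, not kernel-smoothed; a Gaussian kernel
option exists but is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .grid import PredictorStack
from .synthetic_data import LANDCOVER_CLASSES


def landcover_occupancy(
    checklists: pd.DataFrame, stack: PredictorStack
) -> pd.DataFrame:
    """Per-period proportion of detections on each dominant land-cover class.

    Returns one row per (period, class) with the detection fraction, plus the
    per-period count of classes holding at least one detection.
    """
    det = checklists[checklists["species_detected"] == 1]
    fracs = np.stack([stack[f"lc_{c}"] for c in LANDCOVER_CLASSES])
    dominant = np.argmax(fracs, axis=0)
    rows = []
    for period, grp in det.groupby("period"):
        r, c = stack.grid.cell_of(grp["x"].to_numpy(), grp["y"].to_numpy())
        ok = (r >= 0) & (c >= 0)
        classes = dominant[r[ok], c[ok]]
        n = len(classes)
        n_classes = len(np.unique(classes))
        for i, cls in enumerate(LANDCOVER_CLASSES):
            rows.append(
                {
                    "period": period,
                    "landcover": cls,
                    "proportion": float((classes == i).sum()) / n if n else np.nan,
                    "n_detections": n,
                    "n_classes_occupied": n_classes,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EnvSpace:
    """Two-dimensional ordination of pooled occurrence environments."""

    scaler: StandardScaler
    pca: PCA
    predictor_names: list[str]
    scores: np.ndarray  # (n, 2) PC1/PC2 scores of the pooled occurrences
    periods: np.ndarray  # period label per pooled occurrence
    explained_variance_ratio: np.ndarray


def build_env_space(occurrences_by_period: dict[str, pd.DataFrame]) -> EnvSpace:
    """Fit the pooled, z-scored PCA and score every occurrence.

    occurrences_by_period maps a period label to a table of predictor values
    at that period's occurrence points. Constant predictors are dropped with
    a warning before the fit.
    """
    labels, frames = zip(*sorted(occurrences_by_period.items()))
    pooled = pd.concat(frames, ignore_index=True)
    names = list(pooled.columns)
    const = [c for c in names if pooled[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant predictors before PCA: {const}", stacklevel=2)
        names = [c for c in names if c not in const]
    if len(pooled) < len(names):
        raise ValueError("need at least as many pooled occurrences as predictors")
    X = pooled[names].to_numpy(dtype=float)
    scaler = StandardScaler().fit(X)
    pca = PCA().fit(scaler.transform(X))
    scores = pca.transform(scaler.transform(X))[:, :2]
    periods = np.concatenate([np.repeat(lab, len(f)) for lab, f in zip(labels, frames)])
    return EnvSpace(
        scaler=scaler,
        pca=pca,
        predictor_names=names,
        scores=scores,
        periods=periods,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class OccupancyGrid:
    """Normalized occurrence density over binned PC1 x PC2 space."""

    density: np.ndarray  # (n_bins, n_bins), sums to 1 over unmasked cells
    mask: np.ndarray  # True where the cell is analog (sampled by both periods)
    edges1: np.ndarray = field(repr=False, default=None)
    edges2: np.ndarray = field(repr=False, default=None)


def _raw_grid(scores: np.ndarray, edges1: np.ndarray, edges2: np.ndarray) -> np.ndarray:
    h, _, _ = np.histogram2d(scores[:, 0], scores[:, 1], bins=[edges1, edges2])
    return h


def occupancy_pair(
    scores1: np.ndarray,
    scores2: np.ndarray,
    n_bins: int = 100,
    smooth_sigma_bins: float = 0.0,
) -> tuple[OccupancyGrid, OccupancyGrid]:
    """Build the two periods' occupancy grids over the pooled score range.

    The analog mask keeps cells whose PC1 and PC2 midpoints fall inside the
    observed score range of each period separately (range-box criterion);
    both densities are renormalized after masking. smooth_sigma_bins > 0
    applies optional Gaussian kernel smoothing before normalization.
    """
    if len(scores1) == 0 or len(scores2) == 0:
        raise ValueError("both periods need at least one occurrence")
    pooled = np.vstack([scores1, scores2])
    edges1 = np.linspace(pooled[:, 0].min(), pooled[:, 0].max(), n_bins + 1)
    edges2 = np.linspace(pooled[:, 1].min(), pooled[:, 1].max(), n_bins + 1)
    mid1 = (edges1[:-1] + edges1[1:]) / 2.0
    mid2 = (edges2[:-1] + edges2[1:]) / 2.0
    mask = np.ones((n_bins, n_bins), dtype=bool)
    for s in (scores1, scores2):
        in1 = (mid1 >= s[:, 0].min()) & (mid1 <= s[:, 0].max())
        in2 = (mid2 >= s[:, 1].min()) & (mid2 <= s[:, 1].max())
        mask &= in1[:, None] & in2[None, :]
    grids = []
    for s in (scores1, scores2):
        h = _raw_grid(s, edges1, edges2)
        if smooth_sigma_bins > 0:
            h = gaussian_filter(h, sigma=smooth_sigma_bins)
        h = np.where(mask, h, 0.0)
        tot = h.sum()
        if tot == 0:
            raise ValueError("a period has no occurrences left after analog masking")
        grids.append(
            OccupancyGrid(density=h / tot, mask=mask, edges1=edges1, edges2=edges2)
        )
    return grids[0], grids[1]


def _check_pair(p1: OccupancyGrid, p2: OccupancyGrid) -> None:
    if p1.density.shape != p2.density.shape:
        raise ValueError("occupancy grids differ in shape")
    if not np.array_equal(p1.mask, p2.mask):
        raise ValueError("occupancy grids carry different analog masks")


def warrens_I(p1: OccupancyGrid, p2: OccupancyGrid) -> float:
    """I = 1 - 1/2 * sum (sqrt(p1) - sqrt(p2))^2; 1 = identical densities."""
    _check_pair(p1, p2)
    d = np.sqrt(p1.density) - np.sqrt(p2.density)
    return float(np.clip(1.0 - 0.5 * np.sum(d * d), 0.0, 1.0))


def schoeners_D(p1: OccupancyGrid, p2: OccupancyGrid) -> float:
    """D = 1 - 1/2 * sum |p1 - p2|."""
    _check_pair(p1, p2)
    return float(np.clip(1.0 - 0.5 * np.abs(p1.density - p2.density).sum(), 0.0, 1.0))


@dataclass
class OverlapResult:
    observed_I: float
    observed_D: float
    null_I: np.ndarray
    p_value: float
    n_sim: int

    def to_dict(self) -> dict:
        return {
            "observed_I": self.observed_I,
            "observed_D": self.observed_D,
            "p_value": self.p_value,
            "n_sim": self.n_sim,
            "null_I": [float(v) for v in self.null_I],
        }


def similarity_test(
    occ1: pd.DataFrame,
    occ2: pd.DataFrame,
    n_sim: int = 100,
    seed: int = 0,
    n_bins: int = 100,
    smooth_sigma_bins: float = 0.0,
) -> OverlapResult:
    """Permutation test of niche similarity between two occurrence sets.

    occ1/occ2 are tables of predictor values at each period's occurrence
    points. The ordination is fit on the pool (invariant under relabeling);
    each simulation randomly reassigns occurrences to two groups of the
    original sizes and recomputes Warren's I. Low observed I relative to the
    null indicates a niche shift; p = (1 + #{I_sim <= I_obs}) / (n_sim + 1).
    """
    if len(occ1) == 0 or len(occ2) == 0:
        raise ValueError("both periods need occurrences")
    space = build_env_space({"period1": occ1, "period2": occ2})
    n1 = len(occ1)
    scores = space.scores
    g1, g2 = occupancy_pair(scores[:n1], scores[n1:], n_bins, smooth_sigma_bins)
    obs_I = warrens_I(g1, g2)
    obs_D = schoeners_D(g1, g2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_sim)
    # canonical row order makes the null sample invariant to how the input
    # rows happened to be ordered within each period
    pooled_sorted = scores[np.lexsort((scores[:, 1], scores[:, 0]))]
    idx = np.arange(len(scores))
    for s in range(n_sim):
        perm = rng.permutation(idx)
        a, b = pooled_sorted[perm[:n1]], pooled_sorted[perm[n1:]]
        ga, gb = occupancy_pair(a, b, n_bins, smooth_sigma_bins)
        null[s] = warrens_I(ga, gb)
    p = (1.0 + np.sum(null <= obs_I)) / (n_sim + 1.0)
    return OverlapResult(
        observed_I=obs_I, observed_D=obs_D, null_I=null, p_value=float(p), n_sim=n_sim
    )
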
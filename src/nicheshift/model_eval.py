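"""Discrimination metrics, thresholding, transferability, range change.

AUC is the probability that a random presence outscores a random absence
(ties counted half); Cohen's kappa is chance-corrected agreement of the
thresholded prediction with the labels. Suitability maps are binarized at
the cut maximizing sensitivity + specificity (max-SSS), and temporal
transferability is the change in AUC/kappa when a model is scored on the
held-out data of the period it was not trained on (opposite minus own).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .sdm_ensemble import SDMEnsemble, SuitabilityMap

RANGE_CHANGE_CATEGORIES = ("stable-unsuitable", "lost", "gained", "stable-suitable")


def _check_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class")
    return labels


def auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney formulation)."""
    labels = _check_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cohens_kappa(scores, labels, threshold: float) -> float:
    """Kappa of the classification score >= threshold against the labels.

    Degenerate tables with chance agreement 1 return 0 by convention.
    """
    labels = _check_classes(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    if pred.min() == pred.max() and (pred == labels).all():
        warnings.warn("degenerate confusion table (chance agreement 1); kappa set to 0",
                      stacklevel=2)
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = cohen_kappa_score(labels, pred, labels=[0, 1])
    return 0.0 if np.isnan(k) else float(k)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float


def max_sss_threshold(scores, labels) -> ThresholdResult:
    """Cut maximizing sensitivity + specificity.

    Candidates are the observed score values (classification is score >= t);
    ties broken toward the smallest such threshold.
    """
    labels = _check_classes(labels)
    scores = np.asarray(scores, dtype=float)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    cands = np.unique(scores)
    # sens(t) = P(pos >= t), spec(t) = P(neg < t)
    sens = 1.0 - np.searchsorted(pos, cands, side="left") / len(pos)
    spec = np.searchsorted(neg, cands, side="left") / len(neg)
    total = sens + spec
    best = int(np.argmax(total))  # argmax takes the first (smallest) maximizer
    return ThresholdResult(
        threshold=float(cands[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


@dataclass(frozen=True)
class EvaluationMetrics:
    """Own- and opposite-period discrimination with transferability deltas."""

    auc_own: float
    kappa_own: float
    auc_opposite: float
    kappa_opposite: float
    threshold: float
    delta_auc: float  # opposite - own
    delta_kappa: float

    def to_dict(self) -> dict:
        return {
            "auc_own": self.auc_own,
            "kappa_own": self.kappa_own,
            "auc_opposite": self.auc_opposite,
            "kappa_opposite": self.kappa_opposite,
            "threshold": self.threshold,
            "delta_auc": self.delta_auc,
            "delta_kappa": self.delta_kappa,
        }


def transferability(
    ensemble: SDMEnsemble, own_test, opposite_test
) -> EvaluationMetrics:
    """Score held-out data from the model's own period and the opposite
    period; kappa uses the model's own max-SSS threshold for both."""
    s_own = ensemble.predict_table(own_test)
    y_own = own_test["species_detected"].to_numpy(dtype=int)
    s_opp = ensemble.predict_table(opposite_test)
    y_opp = opposite_test["species_detected"].to_numpy(dtype=int)
    thr = max_sss_threshold(s_own, y_own).threshold
    a_own = auc(s_own, y_own)
    a_opp = auc(s_opp, y_opp)
    k_own = cohens_kappa(s_own, y_own, thr)
    k_opp = cohens_kappa(s_opp, y_opp, thr)
    return EvaluationMetrics(
        auc_own=a_own,
        kappa_own=k_own,
        auc_opposite=a_opp,
        kappa_opposite=k_opp,
        threshold=thr,
        delta_auc=a_opp - a_own,
        delta_kappa=k_opp - k_own,
    )


@dataclass
class RangeChangeMap:
    """Four-way suitable/unsuitable transition classification of two maps."""

    categories: np.ndarray  # int codes indexing RANGE_CHANGE_CATEGORIES; -1 nodata
    area_km2_period1: float
    area_km2_period2: float

    def category_counts(self) -> dict[str, int]:
        return {
            name: int((self.categories == code).sum())
            for code, name in enumerate(RANGE_CHANGE_CATEGORIES)
        }


def range_change_map(
    map1: SuitabilityMap, map2: SuitabilityMap, threshold: float, cell_area_km2: float
) -> RangeChangeMap:
    """Binarize both maps at the threshold (score >= t suitable) and classify
    each cell as stable-unsuitable, lost, gained, or stable-suitable."""
    if map1.values.shape != map2.values.shape:
        raise ValueError("maps are not co-registered")
    v1, v2 = map1.values, map2.values
    nodata = np.isnan(v1) | np.isnan(v2)
    s1 = v1 >= threshold
    s2 = v2 >= threshold
    codes = (s1.astype(int) * 1 + s2.astype(int) * 2).astype(int)
    # 0: neither, 1: only period1 (lost), 2: only period2 (gained), 3: both
    codes[nodata] = -1
    return RangeChangeMap(
        categories=codes,
        area_km2_period1=float(s1[~nodata].sum()) * cell_area_km2,
        area_km2_period2=float(s2[~nodata].sum()) * cell_area_km2,
    )
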
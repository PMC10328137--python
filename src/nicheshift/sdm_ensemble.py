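"""Balanced tree-ensemble species distribution models.

The SDM is a balanced random forest: a bagged ensemble of classification
trees in which every tree's bootstrap draws presences and absences in equal
number, so the severe class imbalance of checklist data cannot dominate the
vote. The ensemble score is the fraction of trees voting presence, read as a
continuous habitat-suitability metric in [0, 1]. Model replicates (default
10) capture stochasticity in subsampling, data splitting and balanced
bootstrapping; maps report the across-replicate mean.

Map predictions standardize the observation-effort covariates (date, start
time, duration, distance, party size) to fixed values so the surface reflects
habitat, not effort. Habitat-association summaries are the per-predictor
share of total Gini impurity decrease and partial-dependence curves over a
random reference set of checklists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .grid import PredictorStack

LABEL_COLUMN = "species_detected"


@dataclass(frozen=True)
class EffortStandard:
    """Fixed effort covariates used for map prediction.

    Defaults: April 1 (day 91), survey start chosen per species to maximize
    encounter rate (5 or 6 AM presets), one hour, one km, one observer.
    """

    day_of_year: int = 91
    start_hour: float = 6.0
    duration_hours: float = 1.0
    distance_km: float = 1.0
    n_observers: int = 1

    def as_dict(self) -> dict[str, float]:
        return {
            "day_of_year": self.day_of_year,
            "start_hour": self.start_hour,
            "duration_hours": self.duration_hours,
            "distance_km": self.distance_km,
            "n_observers": self.n_observers,
        }


class BalancedRandomForest:
    """Bagged classification trees with equal-count class bootstraps.

    Each tree is fit on a bootstrap containing n_presence draws (with
    replacement) from each class. Score = fraction of trees voting presence.
    """

    def __init__(
        self,
        n_trees: int = 500,
        max_features: str | int = "sqrt",
        min_samples_leaf: int = 1,
        random_state: int = 0,
    ) -> None:
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.trees_: list[DecisionTreeClassifier] = []
        self.n_features_: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        pres = np.flatnonzero(y == 1)
        absn = np.flatnonzero(y == 0)
        if len(pres) == 0 or len(absn) == 0:
            raise ValueError("training data must contain both classes")
        self.n_features_ = X.shape[1]
        k = len(pres)  # absences matched to presence frequency
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        for _ in range(self.n_trees):
            idx = np.concatenate(
                [rng.choice(pres, size=k, replace=True), rng.choice(absn, size=k, replace=True)]
            )
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros(len(X))
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes / len(self.trees_)

    def bootstrap_class_counts(self) -> list[tuple[int, int]]:
        """(n_presence, n_absence) inside each tree's training sample."""
        out = []
        for tree in self.trees_:
            # class counts at the root node of the fitted tree
            counts = tree.tree_.value[0, 0] * tree.tree_.weighted_n_node_samples[0]
            n0, n1 = counts if tree.classes_[0] == 0 else counts[::-1]
            out.append((int(round(n1)), int(round(n0))))
        return out


@dataclass
class SDMEnsemble:
    """Replicated balanced-forest SDM for one time period."""

    replicates: list[BalancedRandomForest]
    predictor_names: list[str]
    period_label: str = ""
    manifests: list[dict] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        """Mean score over replicates for rows of a model table."""
        X = table[self.predictor_names].to_numpy(dtype=float)
        return np.mean([m.predict_score(X) for m in self.replicates], axis=0)


@dataclass
class SuitabilityMap:
    """Per-cell suitability in [0, 1] with prediction provenance."""

    values: np.ndarray
    grid: object
    model_period: str
    env_period: str

    @property
    def provenance(self) -> str:
        if self.model_period == self.env_period:
            return "contemporary"
        if self.model_period == "historic":
            return "forecast"
        return "backcast"


def train_ensemble(
    model_tables: pd.DataFrame | Sequence[pd.DataFrame],
    n_replicates: int = 10,
    trees_per_replicate: int = 500,
    seed: int = 0,
    predictor_names: list[str] | None = None,
    period_label: str = "",
) -> SDMEnsemble:
    """Train the replicate forests.

    model_tables may be one table (all replicates resample it) or one table
    per replicate (when subsampling and splitting were re-drawn upstream for
    each replicate). Replicate seeds derive deterministically from the master
    seed.
    """
    if isinstance(model_tables, pd.DataFrame):
        tables = [model_tables] * n_replicates
    else:
        tables = list(model_tables)
        if len(tables) != n_replicates:
            raise ValueError("need one model table per replicate")
    if predictor_names is None:
        predictor_names = [c for c in tables[0].columns if c != LABEL_COLUMN]
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    replicates, manifests = [], []
    for rep, (tbl, s) in enumerate(zip(tables, seeds)):
        X = tbl[predictor_names].to_numpy(dtype=float)
        y = tbl[LABEL_COLUMN].to_numpy(dtype=int)
        model = BalancedRandomForest(n_trees=trees_per_replicate, random_state=int(s))
        model.fit(X, y)
        replicates.append(model)
        manifests.append(
            {"replicate": rep, "seed": int(s), "n_train": len(tbl), "n_presence": int(y.sum())}
        )
    return SDMEnsemble(
        replicates=replicates,
        predictor_names=list(predictor_names),
        period_label=period_label,
        manifests=manifests,
    )


def predict_map(
    ensemble: SDMEnsemble, stack: PredictorStack, effort: EffortStandard = EffortStandard()
) -> SuitabilityMap:
    """Mean-over-replicates suitability surface at standardized effort.

    Environmental predictors come from the stack cell-wise; effort covariates
    are fixed to the standard. Nodata cells stay nodata.
    """
    effort_vals = effort.as_dict()
    nr, nc = stack.grid.shape
    n = nr * nc
    cols = []
    for name in ensemble.predictor_names:
        if name in effort_vals:
            cols.append(np.full(n, effort_vals[name]))
        elif name in stack:
            cols.append(stack[name].ravel())
        else:
            raise KeyError(f"stack is missing predictor layer {name!r}")
    X = np.column_stack(cols)
    valid = ~np.isnan(X).any(axis=1)
    out = np.full(n, np.nan)
    if valid.any():
        out[valid] = np.mean(
            [m.predict_score(X[valid]) for m in ensemble.replicates], axis=0
        )
    return SuitabilityMap(
        values=out.reshape(nr, nc),
        grid=stack.grid,
        model_period=ensemble.period_label,
        env_period=stack.period_label,
    )


def save_ensemble(ensemble: SDMEnsemble, directory: str) -> None:
    """Write a versioned on-disk bundle: manifest JSON + one blob per replicate."""
    import json
    import os

    import joblib

    os.makedirs(directory, exist_ok=True)
    manifest = {
        "format_version": 1,
        "predictor_names": ensemble.predictor_names,
        "period_label": ensemble.period_label,
        "n_replicates": ensemble.n_replicates,
        "replicate_manifests": ensemble.manifests,
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for i, model in enumerate(ensemble.replicates):
        joblib.dump(model, os.path.join(directory, f"replicate_{i:02d}.joblib"))


def load_ensemble(directory: str) -> SDMEnsemble:
    import json
    import os

    import joblib

    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    replicates = [
        joblib.load(os.path.join(directory, f"replicate_{i:02d}.joblib"))
        for i in range(manifest["n_replicates"])
    ]
    return SDMEnsemble(
        replicates=replicates,
        predictor_names=manifest["predictor_names"],
        period_label=manifest["period_label"],
        manifests=manifest["replicate_manifests"],
    )


def gini_importance(ensemble: SDMEnsemble) -> pd.DataFrame:
    """Per-predictor share (%) of total Gini impurity decrease.

    Impurity decreases are summed over all splits and trees within a
    replicate, normalized to percent of the replicate total, then averaged
    across replicates (SD reported).
    """
    shares = np.zeros((ensemble.n_replicates, len(ensemble.predictor_names)))
    for i, model in enumerate(ensemble.replicates):
        total = np.zeros(len(ensemble.predictor_names))
        for tree in model.trees_:
            total += tree.tree_.compute_feature_importances(normalize=False)
        shares[i] = 100.0 * total / total.sum()
    return pd.DataFrame(
        {
            "predictor": ensemble.predictor_names,
            "importance_pct": shares.mean(axis=0),
            "importance_sd": shares.std(axis=0, ddof=0),
        }
    ).sort_values("importance_pct", ascending=False, ignore_index=True)


@dataclass
class PartialDependenceCurve:
    """Suitability averaged over reference checklists as one predictor varies."""

    predictor: str
    values: np.ndarray  # evaluation grid over the observed range
    mean_suitability: np.ndarray
    marginal_effect: np.ndarray  # mean curve minus its minimum
    replicate_sd: np.ndarray


def partial_dependence(
    ensemble: SDMEnsemble,
    predictor: str,
    reference_table: pd.DataFrame,
    n_reference: int = 1000,
    n_values: int = 25,
    seed: int = 0,
) -> PartialDependenceCurve:
    """Partial dependence over n_values evenly spaced points spanning the
    predictor's observed range, averaged across n_reference randomly drawn
    checklists (one shared draw for all replicates)."""
    if predictor not in ensemble.predictor_names:
        raise KeyError(f"{predictor!r} is not a model predictor")
    obs = reference_table[predictor].to_numpy(dtype=float)
    lo, hi = float(np.nanmin(obs)), float(np.nanmax(obs))
    if lo == hi:
        raise ValueError(f"predictor {predictor!r} is constant; partial dependence undefined")
    rng = np.random.default_rng(seed)
    take = min(n_reference, len(reference_table))
    ref = reference_table.iloc[
        np.sort(rng.choice(len(reference_table), size=take, replace=False))
    ]
    X = ref[ensemble.predictor_names].to_numpy(dtype=float).copy()
    j = ensemble.predictor_names.index(predictor)
    grid = np.linspace(lo, hi, n_values)
    curves = np.zeros((ensemble.n_replicates, n_values))
    for v, val in enumerate(grid):
        X[:, j] = val
        for i, model in enumerate(ensemble.replicates):
            curves[i, v] = model.predict_score(X).mean()
    mean_curve = curves.mean(axis=0)
    return PartialDependenceCurve(
        predictor=predictor,
        values=grid,
        mean_suitability=mean_curve,
        marginal_effect=mean_curve - mean_curve.min(),
        replicate_sd=curves.std(axis=0, ddof=0),
    )
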
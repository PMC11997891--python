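"""Random-forest pixel classifiers: detailed, rapid, and importance ranking.

Two classifier configurations mirror the two use cases of IR-based tissue
screening:

* the **detailed** model (50 trees) discriminates all seven tissue classes
  (benign, cancer, PanIN, inflammation, fiber, blood, necrosis);
* the **rapid** model (25 trees) collapses the task to pathology
  (cancer + PanIN) vs fiber vs benign and is meant to run on a small
  feature subset, selected by the importance ranking of a 100-tree
  **importance** model, so that a discrete-frequency instrument needs to
  measure only a handful of bands.

Training pixels are balanced by per-class downsampling to the smallest
class; tree hyperparameters beyond the tree count are the scikit-learn
ensemble defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cube_io import CLASS_NAMES, CODE_TO_NAME, LABEL_CODES, HyperCube, RegionTable
from .metrics import build_feature_table

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "RAPID_CODES",
    "DEFAULT_TREES",
    "train",
    "predict_image",
    "rank_metrics",
    "metric_count_sweep",
    "SweepResult",
]

DEFAULT_TREES = {"detailed": 50, "rapid": 25, "importance": 100}

#: label codes used in rapid-model prediction masks
RAPID_CODES = {"benign": 1, "pathology": 2, "fiber": 3}
RAPID_CODE_TO_NAME = {v: k for k, v in RAPID_CODES.items()}

#: default mapping of detailed classes onto rapid classes; classes absent
#: from the map (blood, inflammation, necrosis) are excluded from rapid
#: training and validation
DEFAULT_RAPID_MAP = {
    "benign": "benign",
    "fiber": "fiber",
    "cancer": "pathology",
    "PanIN": "pathology",
}


@dataclass
class ModelSpec:
    mode: str = "detailed"
    n_trees: int | None = None
    class_map: dict[str, str] | None = None
    feature_subset: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in DEFAULT_TREES:
            raise ValueError(f"mode must be one of {sorted(DEFAULT_TREES)}")
        if self.n_trees is None:
            self.n_trees = DEFAULT_TREES[self.mode]
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.class_map is None and self.mode == "rapid":
            self.class_map = dict(DEFAULT_RAPID_MAP)


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: RandomForestClassifier
    classes_: list[str]
    feature_names: list[str]
    importances: dict[str, float] = field(default_factory=dict)

    @property
    def class_codes(self) -> dict[str, int]:
        if self.spec.mode == "rapid" and set(self.classes_) <= set(RAPID_CODES):
            return {c: RAPID_CODES[c] for c in self.classes_}
        return {c: LABEL_CODES[c] for c in self.classes_}


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("mouse_id", "row", "col", "label")]


def _map_labels(labels: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map label codes to training class names; returns (names, keep mask)."""
    names = np.array([CODE_TO_NAME.get(int(v), "?") for v in labels])
    if spec.mode == "rapid" and spec.class_map is not None:
        mapped = np.array([spec.class_map.get(n, "") for n in names])
        return mapped, mapped != ""
    keep = np.array([n in CLASS_NAMES for n in names])
    return names, keep


def _balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-class downsampling to the smallest class, order-stable."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def train(table: pd.DataFrame, spec: ModelSpec) -> TrainedModel:
    """Fit a random forest on a labeled feature table.

    Labels (the integer code column) are mapped to class names — through
    ``spec.class_map`` for the rapid mode, which drops unmapped classes —
    and the training set is balanced by downsampling before fitting.
    Deterministic for a fixed seed.
    """
    feats = _feature_columns(table)
    if spec.feature_subset is not None:
        unknown = [f for f in spec.feature_subset if f not in feats]
        if unknown:
            raise ValueError(f"unknown features in feature_subset: {unknown}")
        feats = list(spec.feature_subset)
    X = table[feats].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature table contains NaN")
    y, keep = _map_labels(table["label"].to_numpy(), spec)
    X, y = X[keep], y[keep]
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes after label mapping")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xBA1A]))
    sel = _balanced_indices(y, rng)
    est = RandomForestClassifier(
        n_estimators=spec.n_trees,
        random_state=spec.seed % (2**31),
        n_jobs=1,
    )
    est.fit(X[sel], y[sel])
    importances = dict(zip(feats, est.feature_importances_))
    return TrainedModel(spec, est, list(est.classes_), feats, importances)


def predict_table(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Predicted class names for the rows of a feature table."""
    have = _feature_columns(table)
    missing = [f for f in model.feature_names if f not in have]
    if missing:
        raise ValueError(f"feature table missing columns: {missing[:5]}")
    X = table[model.feature_names].to_numpy(dtype=np.float64)
    return model.estimator.predict(X)


def predict_image(
    model: TrainedModel, cube: HyperCube, region_table: RegionTable
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every tissue pixel of a cube.

    Returns ``(mask, proba)``: an H x W label-code mask (background stays 0)
    and an H x W x n_classes probability array ordered like
    ``model.classes_``.
    """
    feats = build_feature_table(cube, None, region_table)
    H, W = cube.data.shape[:2]
    out = np.zeros((H, W), dtype=np.int16)
    proba = np.zeros((H, W, len(model.classes_)))
    if len(feats) == 0:
        return out, proba
    X = feats[model.feature_names].to_numpy(dtype=np.float64)
    pred = model.estimator.predict(X)
    prob = model.estimator.predict_proba(X)
    codes = model.class_codes
    r = feats["row"].to_numpy(int)
    c = feats["col"].to_numpy(int)
    out[r, c] = np.array([codes[p] for p in pred], dtype=np.int16)
    proba[r, c, :] = prob
    return out, proba


def rank_metrics(table: pd.DataFrame, spec: ModelSpec | None = None) -> list[str]:
    """Metric names ordered by importance, descending; ties keep column order.

    Trains the 100-tree importance model (rapid class mapping) and sorts by
    Gini importance.
    """
    if spec is None:
        spec = ModelSpec(mode="importance")
    # the importance model maps labels like the rapid model it feeds
    eff = ModelSpec(
        mode="rapid",
        n_trees=spec.n_trees,
        class_map=spec.class_map or dict(DEFAULT_RAPID_MAP),
        feature_subset=spec.feature_subset,
        seed=spec.seed,
    )
    model = train(table, eff)
    names = model.feature_names
    imp = np.array([model.importances[n] for n in names])
    order = np.argsort(-imp, kind="stable")
    return [names[i] for i in order]


@dataclass
class SweepResult:
    counts: list[int]
    accuracies: list[float]
    chosen_k: int
    chosen_metrics: list[str]


def metric_count_sweep(
    table: pd.DataFrame,
    ranked_metrics: list[str],
    counts: list[int],
    seed: int = 0,
    tolerance: float = 0.005,
) -> SweepResult:
    """Rapid-model leave-one-mouse-out accuracy as a function of feature count.

    For each ``k`` in *counts* a 25-tree rapid model is trained on the top-k
    ranked metrics in every leave-one-mouse-out fold and the pooled held-out
    accuracy recorded.  The chosen ``k`` is the smallest count whose
    accuracy is within *tolerance* (0.5 accuracy points by default) of the
    curve's maximum — best performance at low feature count.
    """
    if len(counts) == 0:
        raise ValueError("counts must be nonempty")
    n_total = len(ranked_metrics)
    for k in counts:
        if not (1 <= k <= n_total):
            raise ValueError(f"count {k} outside [1, {n_total}]")
    mice = table["mouse_id"].unique()
    accuracies = []
    for k in counts:
        subset = ranked_metrics[:k]
        correct = 0
        total = 0
        for mouse in mice:
            tr = table[table["mouse_id"] != mouse]
            te = table[table["mouse_id"] == mouse]
            spec = ModelSpec(mode="rapid", feature_subset=subset, seed=seed)
            model = train(tr, spec)
            y_true, keep = _map_labels(te["label"].to_numpy(), spec)
            if not keep.any():
                continue
            pred = predict_table(model, te[keep])
            correct += int((pred == y_true[keep]).sum())
            total += int(keep.sum())
        accuracies.append(correct / total if total else float("nan"))
    best = max(accuracies)
    chosen_k = next(k for k, a in zip(counts, accuracies) if a >= best - tolerance)
    return SweepResult(list(counts), accuracies, chosen_k, ranked_metrics[:chosen_k])
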
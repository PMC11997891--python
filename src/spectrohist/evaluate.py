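"""Leave-one-mouse-out validation and tissue-level screening metrics.

Validation runs at two levels.  At the **pixel** level, predictions pooled
over all leave-one-mouse-out (LOMO) folds feed a confusion matrix with
per-class true-positive rates.  At the **tissue** level, a specimen is
called pathological when the number of pixels the rapid model assigns to
the pathology class — after a majority (modal) spatial filter — exceeds a
threshold; sweeping the threshold over the per-mouse counts yields an ROC
curve, its trapezoidal AUC (equal to the Mann-Whitney statistic with
half-credit for ties) and a Hanley-McNeil standard error.  The operating
threshold is taken from the healthy control group's count distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .cube_io import CLASS_NAMES, LABEL_CODES
from .metrics import build_feature_table, default_region_table, exclude_edge_pixels
from .mnf import mnf_denoise
from .models import (
    DEFAULT_RAPID_MAP,
    RAPID_CODES,
    ModelSpec,
    TrainedModel,
    _map_labels,
    predict_image,
    predict_table,
    rank_metrics,
    train,
)
from .phantom import Cohort

__all__ = [
    "ConfusionMatrix",
    "TissueRoc",
    "EvalReport",
    "lomo_folds",
    "pixel_confusion",
    "majority_filter",
    "tissue_roc",
    "auc_se",
    "run_full_evaluation",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = truth, columns = predicted."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be n x n for n classes")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        t = self.total
        return float(np.trace(self.counts) / t) if t else float("nan")

    @property
    def tpr(self) -> dict[str, float]:
        """Per-class true-positive rate (row-normalized diagonal)."""
        out = {}
        for i, c in enumerate(self.classes):
            row = self.counts[i].sum()
            out[c] = float(self.counts[i, i] / row) if row else float("nan")
        return out

    def row_normalized(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, self.counts / rows, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def lomo_folds(cohort: Cohort) -> list[tuple[list[str], str]]:
    """Leave-one-mouse-out folds: one (train ids, test id) pair per mouse."""
    ids = [m.mouse_id for m in cohort.mice]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mouse_id")
    if len(ids) < 2:
        raise ValueError("need at least 2 mice")
    return [([i for i in ids if i != test], test) for test in ids]


def pixel_confusion(
    truth: np.ndarray, predicted: np.ndarray, classes: list[str]
) -> ConfusionMatrix:
    """Confusion matrix over class-name vectors (edge-excluded pixels only)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index:
            raise ValueError(f"truth label {t!r} outside class set")
        if p not in index:
            raise ValueError(f"predicted label {p!r} outside class set")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes, counts)


@njit(cache=True)
def _majority_kernel(mask: np.ndarray, window: int, n_codes: int) -> np.ndarray:
    H, W = mask.shape
    out = mask.copy()
    r = window // 2
    counts = np.zeros(n_codes, np.int64)
    for i in range(H):
        for j in range(W):
            center = mask[i, j]
            if center == 0:
                continue
            counts[:] = 0
            for a in range(max(0, i - r), min(H, i + r + 1)):
                for b in range(max(0, j - r), min(W, j + r + 1)):
                    v = mask[a, b]
                    if v > 0:
                        counts[v] += 1
            best = 0
            best_n = 0
            tie = False
            for v in range(1, n_codes):
                if counts[v] > best_n:
                    best_n = counts[v]
                    best = v
                    tie = False
                elif counts[v] == best_n and counts[v] > 0:
                    tie = True
            out[i, j] = center if tie else best
    return out


def majority_filter(mask: np.ndarray, window: int = 5) -> np.ndarray:
    """Modal-label smoothing of a prediction mask.

    Each tissue pixel takes the modal label of its ``window x window``
    neighborhood restricted to tissue; ties keep the center pixel's label;
    background (0) never votes and is never overwritten.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    mask = np.asarray(mask)
    if mask.min() < 0:
        raise ValueError("labels must be nonnegative")
    n_codes = int(mask.max()) + 1
    return _majority_kernel(mask.astype(np.int64), window, max(n_codes, 2)).astype(
        mask.dtype
    )


@dataclass
class TissueRoc:
    """Threshold sweep over per-mouse pathology pixel counts."""

    mouse_ids: list[str]
    counts: np.ndarray
    truth: list[str]  # "healthy" / "pathological" per mouse
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float
    chosen_threshold: float


def tissue_roc(
    counts: dict[str, int],
    truth: dict[str, str],
) -> TissueRoc:
    """ROC over the rule "pathological iff pathology-pixel count > threshold".

    Thresholds sweep the distinct counts (plus sentinels at both ends); AUC
    is the trapezoid under the (fpr, tpr) path, identical to the
    Mann-Whitney statistic U/(n1*n2) counting ties as one half.  The
    operating threshold is the maximum count observed in the healthy
    (control) group.
    """
    ids = sorted(counts)
    if set(ids) != set(truth):
        raise ValueError("counts and truth must cover the same mice")
    y = np.array([truth[i] == "pathological" for i in ids])
    x = np.array([float(counts[i]) for i in ids])
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one healthy and one pathological mouse")
    uniq = np.unique(x)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])  # high -> low sweep below
    fpr = []
    tpr = []
    for t in thresholds[::-1]:
        called = x > t
        tpr.append((called & y).sum() / n_pos)
        fpr.append((called & ~y).sum() / n_neg)
    fpr = np.array(fpr)
    tpr = np.array(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    se = auc_se(auc, n_neg, n_pos)
    chosen = float(x[~y].max())
    return TissueRoc(ids, x, [truth[i] for i in ids], thresholds[::-1], fpr, tpr,
                     auc, se, chosen)


def auc_se(auc: float, n_healthy: int, n_pathological: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate.

    With A the AUC, Q1 = A/(2-A), Q2 = 2A^2/(1+A):
    se = sqrt([A(1-A) + (n_p-1)(Q1-A^2) + (n_h-1)(Q2-A^2)] / (n_h*n_p)).
    """
    if not (0.0 <= auc <= 1.0):
        raise ValueError("auc must be in [0, 1]")
    if n_healthy < 1 or n_pathological < 1:
        raise ValueError("group sizes must be >= 1")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (n_pathological - 1) * (q1 - a * a)
        + (n_healthy - 1) * (q2 - a * a)
    ) / (n_healthy * n_pathological)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class EvalReport:
    confusion_detailed: ConfusionMatrix
    confusion_rapid: ConfusionMatrix
    roc: TissueRoc
    per_fold_detailed: list[ConfusionMatrix] = field(default_factory=list)
    sweep: object | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "detailed": {
                "classes": self.confusion_detailed.classes,
                "counts": self.confusion_detailed.counts.tolist(),
                "accuracy": self.confusion_detailed.accuracy,
                "tpr": self.confusion_detailed.tpr,
            },
            "rapid": {
                "classes": self.confusion_rapid.classes,
                "counts": self.confusion_rapid.counts.tolist(),
                "accuracy": self.confusion_rapid.accuracy,
                "tpr": self.confusion_rapid.tpr,
            },
            "tissue_roc": {
                "mouse_ids": self.roc.mouse_ids,
                "counts": self.roc.counts.tolist(),
                "truth": self.roc.truth,
                "fpr": self.roc.fpr.tolist(),
                "tpr": self.roc.tpr.tolist(),
                "auc": self.roc.auc,
                "se": self.roc.se,
                "chosen_threshold": self.roc.chosen_threshold,
            },
            "meta": self.meta,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_full_evaluation(
    cohort: Cohort,
    detailed_spec: ModelSpec | None = None,
    rapid_spec: ModelSpec | None = None,
    region_table=None,
    mnf_k: int = 20,
    majority_window: int = 5,
    n_top_metrics: int = 6,
    seed: int = 0,
) -> EvalReport:
    """End-to-end LOMO evaluation of a cohort.

    Per mouse: MNF denoising (``mnf_k`` components) then feature extraction.
    Per fold: the detailed 7-class model is trained on the 18 other mice and
    scored on the held-out mouse's interior pixels; the importance model
    ranks the metrics, the rapid model retrains on the ``n_top_metrics``
    best and predicts the full tissue map of the held-out mouse, which is
    majority-filtered and reduced to its pathology pixel count.  Counts over
    all mice feed the tissue-level ROC.
    """
    if region_table is None:
        region_table = default_region_table()
    if detailed_spec is None:
        detailed_spec = ModelSpec(mode="detailed", seed=seed)
    if rapid_spec is None:
        rapid_spec = ModelSpec(mode="rapid", seed=seed)

    tables = {}
    denoised = {}
    interiors = {}
    for m in cohort.mice:
        cube = mnf_denoise(m.cube, k=mnf_k)
        denoised[m.mouse_id] = cube
        interior = exclude_edge_pixels(m.labels, cube.tissue_mask)
        interiors[m.mouse_id] = interior
        t = build_feature_table(cube, m.labels, region_table)
        inter = interior[t["row"].to_numpy(int), t["col"].to_numpy(int)]
        t = t.assign(_interior=inter)
        tables[m.mouse_id] = t
    all_rows = pd.concat(tables.values(), ignore_index=True)
    train_rows = all_rows[all_rows["_interior"]].drop(columns="_interior")

    folds = lomo_folds(cohort)
    det_classes = list(CLASS_NAMES)
    rapid_classes = sorted(set(DEFAULT_RAPID_MAP.values()) | {"benign", "fiber"})
    det_true: list[str] = []
    det_pred: list[str] = []
    rap_true: list[str] = []
    rap_pred: list[str] = []
    per_fold = []
    path_counts: dict[str, int] = {}
    mice_by_id = {m.mouse_id: m for m in cohort.mice}
    for train_ids, test_id in folds:
        tr = train_rows[train_rows["mouse_id"] != test_id]
        te = train_rows[train_rows["mouse_id"] == test_id]

        det = train(tr, detailed_spec)
        t_names, keep = _map_labels(te["label"].to_numpy(), detailed_spec)
        pred = predict_table(det, te[keep])
        det_true.extend(t_names[keep])
        det_pred.extend(pred)
        per_fold.append(pixel_confusion(t_names[keep], pred, det_classes))

        ranked = rank_metrics(tr, ModelSpec(mode="importance", seed=seed))
        top = ranked[:n_top_metrics]
        rspec = ModelSpec(mode="rapid", n_trees=rapid_spec.n_trees,
                          class_map=rapid_spec.class_map, feature_subset=top,
                          seed=seed)
        rap = train(tr, rspec)
        r_names, r_keep = _map_labels(te["label"].to_numpy(), rspec)
        rpred = predict_table(rap, te[r_keep])
        rap_true.extend(r_names[r_keep])
        rap_pred.extend(rpred)

        mask, _ = predict_image(rap, denoised[test_id], region_table)
        filtered = majority_filter(mask, window=majority_window)
        path_counts[test_id] = int((filtered == RAPID_CODES["pathology"]).sum())

    confusion_detailed = pixel_confusion(
        np.array(det_true), np.array(det_pred), det_classes
    )
    confusion_rapid = pixel_confusion(
        np.array(rap_true), np.array(rap_pred), rapid_classes
    )
    roc = tissue_roc(path_counts, cohort.tissue_truth)
    meta = {
        "mnf_k": mnf_k,
        "majority_window": majority_window,
        "n_top_metrics": n_top_metrics,
        "seed": seed,
        "n_mice": len(cohort.mice),
        "n_regions": len(region_table),
        "pathology_pixel_counts": path_counts,
    }
    return EvalReport(confusion_detailed, confusion_rapid, roc, per_fold, None, meta)
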
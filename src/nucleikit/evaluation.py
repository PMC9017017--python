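"""Metrics and protocols: Dice, MSE, peak detection, cell matching, P/R/F1,
one-vs-rest ROC-AUC, bottleneck features and the k-fold split.

Cell-level detection scoring follows the standard protocol for point
annotations: predicted centers are assigned one-to-one to ground-truth
centers by optimal bipartite matching under a distance gate, and the
assignment counts give precision = TP/(TP+FP), recall = TP/(TP+FN) and
F1 = 2PR/(P+R).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .datapipe import DensityTarget, PointSet
from .nn import Tensor, no_grad


# ---------------------------------------------------------------------------
# mask / surface metrics
# ---------------------------------------------------------------------------

def _as_binary(mask) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary (values in {0, 1})")
    return m.astype(bool)


def dice_coefficient(gt, sr) -> float:
    """2|GT ∩ SR| / (|GT| + |SR|); two empty masks score 1 by convention."""
    gt, sr = _as_binary(gt), _as_binary(sr)
    if gt.shape != sr.shape:
        raise ValueError("mask shapes differ")
    total = int(gt.sum()) + int(sr.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((gt & sr).sum()) / total


def mean_squared_error(y, yhat) -> float:
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("array shapes differ")
    return float(np.mean((y - yhat) ** 2))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN)


def detect_peaks(density: DensityTarget | np.ndarray, threshold: float = 0.5,
                 min_separation: int = 0) -> PointSet:
    """Threshold the surface and reduce each connected component to its
    intensity-weighted centroid; components closer than ``min_separation``
    are merged before the centroid is taken."""
    surface = density.surface if isinstance(density, DensityTarget) else \
        np.asarray(density, dtype=np.float32)
    if not np.all(np.isfinite(surface)):
        raise ValueError("density surface contains non-finite values")
    fg = surface > threshold
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return PointSet.empty()
    ids = list(range(1, n + 1))
    centroids = np.array(ndimage.center_of_mass(surface, labels, ids))
    groups = [[i] for i in ids]
    if min_separation > 0:
        merged = True
        while merged and len(groups) > 1:
            merged = False
            d = cdist(centroids, centroids)
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] < min_separation:
                groups[i] += groups[j]
                del groups[j]
                centroids = np.array([
                    np.average(np.argwhere(np.isin(labels, g)), axis=0,
                               weights=surface[np.isin(labels, g)])
                    for g in groups])
                merged = True
    coords = np.rint(centroids).astype(int)
    coords = np.unique(coords, axis=0)
    return PointSet(coords)


def match_detections(pred: PointSet, gt: PointSet, radius: float = 6.0
                     ) -> DetectionCounts:
    """Optimal one-to-one assignment within ``radius`` pixels.

    Maximizes the number of matches and, among maximal matchings, minimizes
    total distance (Hungarian algorithm with a prohibitive cost for pairs
    beyond the gate)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    npred, ngt = len(pred), len(gt)
    if npred == 0 or ngt == 0:
        return DetectionCounts(0, npred, ngt)
    d = cdist(pred.coords.astype(float), gt.coords.astype(float))
    big = 1e9
    cost = np.where(d <= radius, d, big)
    rows, cols = linear_sum_assignment(cost)
    tp = int((d[rows, cols] <= radius).sum())
    return DetectionCounts(tp, npred - tp, ngt - tp)


def precision_recall_f1(c: DetectionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); all 1 when nothing was there to find and
    nothing was predicted, otherwise 0/0 ratios resolve to 0."""
    if c.TP == c.FP == c.FN == 0:
        return 1.0, 1.0, 1.0
    precision = c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


# ---------------------------------------------------------------------------
# classification metrics and features
# ---------------------------------------------------------------------------

def roc_auc_macro(scores, labels) -> float:
    """Macro-averaged one-vs-rest ROC-AUC over the classes present in
    ``labels``; absent classes are skipped with a warning."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_samples, n_classes)")
    aucs = []
    for k in range(scores.shape[1]):
        mask = labels == k
        if mask.all() or not mask.any():
            warnings.warn(f"class {k} absent from labels; skipped in macro AUC")
            continue
        aucs.append(roc_auc_score(mask.astype(int), scores[:, k]))
    if not aucs:
        raise ValueError("no class with both positive and negative samples")
    return float(np.mean(aucs))


def extract_bottleneck_features(model, samples, batch_size: int = 64) -> np.ndarray:
    """Spatially averaged activations of the final pre-head block: (n, F)."""
    if not hasattr(model, "features"):
        raise TypeError("model does not expose a pre-head feature block")
    arr = np.asarray(samples, dtype=np.float32)
    model.eval()
    out = []
    with no_grad():
        for i in range(0, len(arr), batch_size):
            out.append(model.features(Tensor(arr[i:i + batch_size])).data)
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray


@dataclass
class FoldReport:
    """Per-fold metric values with their mean and sample standard deviation."""

    metric: str
    values: list

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def __repr__(self):
        return (f"FoldReport({self.metric}: {self.mean:.4f} ± {self.std:.4f} "
                f"over {len(self.values)} folds)")


def kfold_split(n: int, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Shuffled k-fold partition of ``range(n)``; fold sizes differ by <= 1."""
    if k <= 1:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError("need at least k samples")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [FoldSplit(tr, te) for tr, te in kf.split(np.arange(n))]
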
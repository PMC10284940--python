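"""Random-forest fiber/particle classification on shape features f1-f6.

A single shape descriptor (e.g. an aspect-ratio threshold) cannot match
the expert notion of "fiber", especially for curved fibers; six features
together can.  A forest is trained on a labelled contour set (expert
labels in practice; the synthetic labelled set from :mod:`.synthgen`
for the model shipped with the package) and applied to every detected
object.  Fibers are exempted from de-agglomeration downstream and their
length is reported from the skeleton rather than the Feret diameter.

The trained model is serialized to a portable JSON of tree arrays
(children, split feature, threshold, leaf votes) with a fixed feature
order, so a loaded model predicts identically on any platform without
unpickling anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .shape_morphology import ShapeFeatures

__all__ = [
    "LabeledContourSet",
    "ClassifierModel",
    "train_classifier",
    "predict_shape_class",
    "save_model",
    "load_model",
]

FEATURE_ORDER = ("f1", "f2", "f3", "f4", "f5", "f6")
CLASSES = ("fiber", "particle")  # fixed label order; index 0 = fiber
MODEL_VERSION = "fragscan-forest-1"


@dataclass
class LabeledContourSet:
    """Training data: feature matrix (n, 6) in f1..f6 order plus labels."""

    features: np.ndarray
    labels: np.ndarray  # array of 'fiber'/'particle' strings
    provenance: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_ORDER):
            raise ValueError("features must be (n, 6) in f1..f6 order")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features/labels length mismatch")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("training data must contain both classes")


@dataclass
class ClassifierModel:
    """A serialized forest: per-tree node arrays + metadata.

    ``trees`` is a list of dicts with keys ``children_left``,
    ``children_right``, ``feature``, ``threshold`` and ``vote`` (the
    class index predicted at each node when it is a leaf).
    """

    trees: List[dict]
    seed: int
    feature_order: Tuple[str, ...] = FEATURE_ORDER
    classes: Tuple[str, ...] = CLASSES
    version: str = MODEL_VERSION
    oob_fiber_recall: Optional[float] = None
    _sklearn: Optional[RandomForestClassifier] = field(default=None, repr=False, compare=False)

    def predict_proba_fiber(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting 'fiber' for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_order):
            raise ValueError("feature-order mismatch")
        if self._sklearn is not None:
            cls = list(self._sklearn.classes_)
            return self._sklearn.predict_proba(X)[:, cls.index("fiber")]
        votes = np.zeros(X.shape[0])
        for tree in self.trees:
            votes += _tree_votes(tree, X) == self.classes.index("fiber")
        return votes / len(self.trees)


def _tree_votes(tree: dict, X: np.ndarray) -> np.ndarray:
    left = np.asarray(tree["children_left"])
    right = np.asarray(tree["children_right"])
    feat = np.asarray(tree["feature"])
    thr = np.asarray(tree["threshold"])
    vote = np.asarray(tree["vote"])
    node = np.zeros(X.shape[0], dtype=int)
    active = left[node] >= 0
    while np.any(active):
        idx = np.nonzero(active)[0]
        nd = node[idx]
        go_left = X[idx, feat[nd]] <= thr[nd]
        node[idx] = np.where(go_left, left[nd], right[nd])
        active = left[node] >= 0
    return vote[node]


def train_classifier(data: LabeledContourSet, n_trees: int = 200, seed: int = 42) -> ClassifierModel:
    """Fit a class-balanced random forest on f1..f6.

    Out-of-bag scoring is enabled, and the out-of-bag fiber recall is
    stored on the model as a training diagnostic.  Training is fully
    reproducible under ``seed``.
    """
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        class_weight="balanced",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(data.features, data.labels)
    cls = list(rf.classes_)
    fiber_col = cls.index("fiber")
    oob = rf.oob_decision_function_
    is_fiber = data.labels == "fiber"
    with np.errstate(invalid="ignore"):
        oob_pred_fiber = np.nan_to_num(oob[:, fiber_col]) > 0.5
    recall = float(np.mean(oob_pred_fiber[is_fiber])) if is_fiber.any() else float("nan")
    trees = [_export_tree(est, cls) for est in rf.estimators_]
    return ClassifierModel(trees=trees, seed=seed, oob_fiber_recall=recall, _sklearn=rf)


def _export_tree(estimator, sklearn_classes: List[str]) -> dict:
    t = estimator.tree_
    # map the per-leaf class distribution to a vote in our fixed class order
    counts = t.value[:, 0, :]
    winners = np.asarray(sklearn_classes)[np.argmax(counts, axis=1)]
    vote = np.array([CLASSES.index(w) for w in winners], dtype=int)
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "vote": vote.tolist(),
    }


def predict_shape_class(features: ShapeFeatures | np.ndarray, model: ClassifierModel) -> Tuple[str, float]:
    """Majority vote over the forest; class = 'fiber' iff P(fiber) > 0.5."""
    x = features.as_array() if isinstance(features, ShapeFeatures) else np.asarray(features, dtype=float)
    p_fiber = float(model.predict_proba_fiber(x.reshape(1, -1))[0])
    return ("fiber" if p_fiber > 0.5 else "particle", p_fiber)


def save_model(model: ClassifierModel, path: str | Path) -> None:
    payload = {
        "version": model.version,
        "seed": model.seed,
        "feature_order": list(model.feature_order),
        "classes": list(model.classes),
        "oob_fiber_recall": model.oob_fiber_recall,
        "trees": model.trees,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')!r}")
    return ClassifierModel(
        trees=payload["trees"],
        seed=payload["seed"],
        feature_order=tuple(payload["feature_order"]),
        classes=tuple(payload["classes"]),
        version=payload["version"],
        oob_fiber_recall=payload.get("oob_fiber_recall"),
    )
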
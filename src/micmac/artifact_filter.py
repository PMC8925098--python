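"""Artifact removal: volume gate, stack-border gate, and a boosted-tree gate.

Segmentation of thick post-mortem tissue produces three artifact families:
debris and staining specks far smaller than a cell, merged accumulations of
several cells far larger than one, and cells truncated by the acquisition
border. The first two are caught by an inclusive volume window (default
48,000–216,000 µm³); truncations by the fraction of the cell's exposed
surface lying on the six stack boundary planes (removed when strictly above
7.5%). A supervised AdaBoost classifier over the morphology features is an
optional third gate for artifact shapes the heuristics miss; it requires
manually labelled examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .segmentation import LabelVolume

__all__ = [
    "CellMask",
    "ArtifactClassifier",
    "measure_cell",
    "measure_all_cells",
    "volume_gate",
    "border_gate",
    "train_artifact_classifier",
    "apply_classifier",
    "VOLUME_GATE_UM3",
    "BORDER_FRACTION_MAX",
]

#: Inclusive cell-volume window in µm³ separating single cells from debris
#: and merged accumulations.
VOLUME_GATE_UM3 = (48_000.0, 216_000.0)

#: Cells with a border-surface share strictly above this are truncated.
BORDER_FRACTION_MAX = 0.075


@dataclass(eq=False)
class CellMask:
    """Geometry of one segmented object.

    ``face_area`` counts exposed voxel faces (6-neighbourhood) in µm² and is
    the denominator of the border fraction — faces are exactly defined at
    the stack boundary. ``mesh_area`` is the smooth isosurface estimate used
    for shape features; voxel-face counting overestimates smooth surfaces by
    a substantial constant factor, so the two are kept separate.
    """

    label: int
    voxels: np.ndarray  # (n, 3) int voxel coordinates (z, y, x)
    volume: float  # µm³
    mesh_area: float  # µm²
    face_area: float  # µm²
    border_area: float  # µm²
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    voxel_size: tuple[float, float, float]

    @property
    def border_fraction(self) -> float:
        if self.face_area <= 0:
            raise ValueError(f"cell {self.label}: zero exposed surface")
        return self.border_area / self.face_area


def _face_areas(voxel_size) -> tuple[float, float, float]:
    """Area of one voxel face normal to z, y, x respectively."""
    dz, dy, dx = voxel_size
    return (dy * dx, dz * dx, dz * dy)


def _mesh_area(mask: np.ndarray, voxel_size) -> float:
    """Isosurface area (µm²) of a binary mask via marching cubes."""
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(voxel_size))
    return float(measure.mesh_surface_area(verts, faces))


def measure_cell(label_volume: LabelVolume, label: int) -> CellMask:
    """Measure volume and surface areas of one labeled object.

    Raises ``KeyError`` if the label is absent. The border area sums the
    areas of voxel faces lying on the six stack boundary planes; those faces
    also count as exposed in ``face_area``.
    """
    labels = label_volume.labels
    mask = labels == label
    if not mask.any():
        raise KeyError(f"label {label} not present in volume")
    voxel_size = label_volume.voxel_size
    coords = np.argwhere(mask)
    zmin, ymin, xmin = coords.min(axis=0)
    zmax, ymax, xmax = coords.max(axis=0)
    # crop with a 1-voxel margin so exposure checks see the background
    lo = np.maximum([zmin - 1, ymin - 1, xmin - 1], 0)
    hi = np.minimum([zmax + 2, ymax + 2, xmax + 2], mask.shape)
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]

    areas = _face_areas(voxel_size)
    face_area = 0.0
    border_area = 0.0
    for axis, a in enumerate(areas):
        # exposed faces in -axis and +axis directions, counted on the full grid
        padded = np.pad(mask, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
        lo_nb = np.take(padded, range(0, mask.shape[axis]), axis=axis)
        hi_nb = np.take(padded, range(2, mask.shape[axis] + 2), axis=axis)
        face_area += a * float(np.count_nonzero(mask & ~lo_nb))
        face_area += a * float(np.count_nonzero(mask & ~hi_nb))
        border_area += a * float(np.count_nonzero(np.take(mask, 0, axis=axis)))
        border_area += a * float(np.count_nonzero(np.take(mask, -1, axis=axis)))

    voxel_volume = float(np.prod(voxel_size))
    return CellMask(
        label=int(label),
        voxels=coords,
        volume=float(coords.shape[0]) * voxel_volume,
        mesh_area=_mesh_area(sub, voxel_size),
        face_area=face_area,
        border_area=border_area,
        bbox=((int(zmin), int(zmax)), (int(ymin), int(ymax)), (int(xmin), int(xmax))),
        voxel_size=voxel_size,
    )


def measure_all_cells(label_volume: LabelVolume) -> list[CellMask]:
    return [measure_cell(label_volume, lab) for lab in range(1, label_volume.n_labels + 1)]


def volume_gate(
    cells: list[CellMask],
    vmin: float = VOLUME_GATE_UM3[0],
    vmax: float = VOLUME_GATE_UM3[1],
) -> list[CellMask]:
    """Keep cells whose volume lies in the closed interval [vmin, vmax] µm³."""
    if vmin > vmax:
        raise ValueError(f"vmin {vmin} exceeds vmax {vmax}")
    return [c for c in cells if vmin <= c.volume <= vmax]


def border_gate(cells: list[CellMask], max_fraction: float = BORDER_FRACTION_MAX) -> list[CellMask]:
    """Remove cells whose border-surface share is strictly above the cap."""
    return [c for c in cells if c.border_fraction <= max_fraction]


def _export_tree(tree) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value[:, 0, :].tolist(),
    }


def _predict_tree(tree: dict, X: np.ndarray) -> np.ndarray:
    """Class index predicted by an exported tree for each row of X."""
    out = np.empty(X.shape[0], dtype=np.intp)
    left = tree["children_left"]
    right = tree["children_right"]
    feat = tree["feature"]
    thr = tree["threshold"]
    value = tree["value"]
    for i, row in enumerate(X):
        node = 0
        while left[node] != -1:
            node = left[node] if row[feat[node]] <= thr[node] else right[node]
        out[i] = int(np.argmax(value[node]))
    return out


@dataclass
class ArtifactClassifier:
    """SAMME-boosted decision trees flagging artifact morphologies.

    Holds either a fitted sklearn ensemble or, after a JSON round-trip, the
    exported trees and stage weights from which predictions are recomputed
    directly. ``cv_accuracy`` is the k-fold cross-validated accuracy reported
    at training time.
    """

    feature_names: list[str]
    seed: int
    k: int
    cv_accuracy: float
    classes: list[int]
    trees: list[dict] = field(default_factory=list)
    stage_weights: list[float] = field(default_factory=list)
    _model: AdaBoostClassifier | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary artifact flags for rows of X (1 = artifact)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.zeros(0, dtype=int)
        if self._model is not None:
            return self._model.predict(X).astype(int)
        # SAMME vote from exported trees
        n_classes = len(self.classes)
        votes = np.zeros((X.shape[0], n_classes))
        for tree, w in zip(self.trees, self.stage_weights):
            pred = _predict_tree(tree, X)
            votes[np.arange(X.shape[0]), pred] += w
        return np.asarray(self.classes)[np.argmax(votes, axis=1)]

    def score(self, X: np.ndarray) -> np.ndarray:
        """Artifact score in [0, 1] (weighted vote share for class 1)."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            return np.zeros(0)
        if self._model is not None:
            return self._model.predict_proba(X)[:, -1]
        votes = np.zeros((X.shape[0], len(self.classes)))
        for tree, w in zip(self.trees, self.stage_weights):
            pred = _predict_tree(tree, X)
            votes[np.arange(X.shape[0]), pred] += w
        total = votes.sum(axis=1)
        total[total == 0] = 1.0
        return votes[:, -1] / total

    def to_json(self, path: str | Path) -> None:
        if self._model is not None and not self.trees:
            self.trees = [_export_tree(e) for e in self._model.estimators_]
            self.stage_weights = [float(w) for w in self._model.estimator_weights_]
        payload = {
            "feature_names": self.feature_names,
            "seed": self.seed,
            "k": self.k,
            "cv_accuracy": self.cv_accuracy,
            "classes": self.classes,
            "trees": self.trees,
            "stage_weights": self.stage_weights,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArtifactClassifier":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def train_artifact_classifier(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
    n_estimators: int = 100,
    max_depth: int = 2,
) -> ArtifactClassifier:
    """Fit the boosted-tree artifact classifier with k-fold validation.

    Labels are binary (1 = artifact) from manual annotation. Raises
    ``ValueError`` when only one class is present.
    """
    X = np.asarray(feature_matrix, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2D")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    base = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    model = AdaBoostClassifier(estimator=base, n_estimators=n_estimators, random_state=seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cv_acc = float(cross_val_score(model, X, y, cv=cv, scoring="accuracy").mean())
    model.fit(X, y)
    return ArtifactClassifier(
        feature_names=list(feature_names),
        seed=seed,
        k=k,
        cv_accuracy=cv_acc,
        classes=[int(c) for c in classes],
        _model=model,
    )


def apply_classifier(classifier: ArtifactClassifier, feature_matrix: np.ndarray) -> np.ndarray:
    """Binary artifact flags; raises on feature-count mismatch."""
    return classifier.predict(np.asarray(feature_matrix, dtype=np.float64))
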
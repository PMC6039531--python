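"""Three-class patch classification and heatmap assembly.

The classification stage is a contract, not one fixed model: anything with
a ``predict_proba(patches) -> (n, 3)`` method over [0, 1]-scaled RGB
patches, rows summing to one in the fixed class order (tumor,
non-malignant, white), can drive the pipeline.  The default is
:class:`ReferenceClassifier`, a multinomial logistic regression on a small
set of color/texture summaries — deterministic, CPU-cheap, and separable on
the synthetic textures.  A deep network trained on annotated patches slots
into the same contract; its training-harness settings (batch size 32,
learning rate 1e-4, momentum 0.9, early stop after 10 stagnant epochs) are
carried in :data:`DEEP_BACKEND_DEFAULTS` for such backends and are unused
by the reference classifier.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from ._constants import CLASS_NAMES, N_CLASSES, WHITE
from .tiling import PatchGrid

__all__ = [
    "DEEP_BACKEND_DEFAULTS",
    "patch_summary_features",
    "ReferenceClassifier",
    "fit_reference_classifier",
    "assemble_probability_map",
    "label_map_from_probs",
    "evaluate_accuracy",
]

#: Hyperparameters for optional deep-learning backends (kept as config
#: keys so a network-based classifier can be dropped in unchanged).
DEEP_BACKEND_DEFAULTS = {
    "batch_size": 32,
    "learning_rate": 1e-4,
    "momentum": 0.9,
    "max_epochs": 50,
    "early_stop_patience": 10,
}


def _check_patches(patches: np.ndarray) -> np.ndarray:
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 4 or patches.shape[-1] != 3:
        raise ValueError(
            "patches must be a (n, height, width, 3) array scaled to [0, 1]"
        )
    return patches


def patch_summary_features(patches: np.ndarray) -> np.ndarray:
    """Summary features of [0, 1]-scaled RGB patches.

    Per patch: overall mean intensity, the three channel means, intensity
    standard deviation, dark-pixel fraction (< 0.5, a blob-density
    statistic), and blue-minus-red balance.
    """
    patches = _check_patches(patches)
    gray = patches.mean(axis=-1)
    chan = patches.mean(axis=(1, 2))  # (n, 3)
    return np.column_stack(
        [
            gray.mean(axis=(1, 2)),
            chan,
            gray.std(axis=(1, 2)),
            (gray < 0.5).mean(axis=(1, 2)),
            chan[:, 2] - chan[:, 0],
        ]
    )


class ReferenceClassifier:
    """Multinomial logistic regression on patch summary features.

    Satisfies the classifier contract: probability rows sum to one, output
    is deterministic for a fixed fitted state, and each row depends only on
    its own patch (batch-order independence).
    """

    def __init__(self):
        self._pipe = make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000)
        )
        self.classes_ = None

    def fit(self, patches: np.ndarray, labels: np.ndarray):
        labels = np.asarray(labels, dtype=int)
        present = np.unique(labels)
        if len(present) < N_CLASSES:
            missing = sorted(set(range(N_CLASSES)) - set(present.tolist()))
            raise ValueError(
                "training data must contain every class; missing "
                + ", ".join(CLASS_NAMES[m] for m in missing)
            )
        self._pipe.fit(patch_summary_features(patches), labels)
        self.classes_ = self._pipe.classes_
        return self

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("classifier is not fitted")
        raw = self._pipe.predict_proba(patch_summary_features(patches))
        # place columns in the fixed (tumor, non_malignant, white) order
        out = np.zeros((raw.shape[0], N_CLASSES))
        for k, cls in enumerate(self.classes_):
            out[:, int(cls)] = raw[:, k]
        return out

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(patches), axis=1)


def fit_reference_classifier(patches: np.ndarray, labels: np.ndarray) -> ReferenceClassifier:
    """Fit the reference classifier; requires at least one example of each
    of the three classes."""
    return ReferenceClassifier().fit(patches, labels)


def assemble_probability_map(grid: PatchGrid, predictions: np.ndarray) -> np.ndarray:
    """Arrange per-patch predictions into a class-probability heatmap.

    ``predictions`` holds one probability row per tissue cell of the grid,
    in row-major cell order.  Non-tissue cells are assigned (0, 0, 1):
    white with certainty, since only tissue windows are ever classified.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    n_tissue = int(grid.tissue.sum())
    if n_tissue == 0 and predictions.size == 0:
        predictions = predictions.reshape(0, N_CLASSES)
    if predictions.shape != (n_tissue, N_CLASSES):
        raise ValueError(
            f"expected {n_tissue} predictions of {N_CLASSES} classes, "
            f"got array of shape {predictions.shape}"
        )
    prob = np.zeros((grid.n_rows, grid.n_cols, N_CLASSES))
    prob[..., WHITE] = 1.0
    prob[grid.tissue] = predictions
    return prob


def label_map_from_probs(prob_map: np.ndarray) -> np.ndarray:
    """Argmax class per cell; ties resolve by the fixed class priority
    tumor > non-malignant > white (the class-order argmax)."""
    prob_map = np.asarray(prob_map)
    if prob_map.ndim != 3 or prob_map.shape[-1] != N_CLASSES:
        raise ValueError("probability map must have shape (rows, cols, 3)")
    return np.argmax(prob_map, axis=-1).astype(np.int8)


def evaluate_accuracy(predicted, true):
    """Overall accuracy, per-class accuracy, and the confusion matrix.

    The confusion matrix is indexed [true, predicted] in the fixed class
    order; row sums equal the true class counts.
    """
    predicted = np.asarray(predicted).ravel()
    true = np.asarray(true).ravel()
    if predicted.size == 0:
        raise ValueError("empty input")
    if predicted.size != true.size:
        raise ValueError("length mismatch")
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(confusion, (true, predicted), 1)
    overall = float(np.trace(confusion) / confusion.sum())
    per_class = {}
    for k, name in enumerate(CLASS_NAMES):
        n_k = confusion[k].sum()
        per_class[name] = float(confusion[k, k] / n_k) if n_k else float("nan")
    return overall, per_class, confusion
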
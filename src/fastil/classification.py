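"""Stage 2 — tissue-class assignment and prognostic filtering.

The classifier is a pluggable contract: anything with a
``classify(patch_rgb, *, x0=0, y0=0) -> (label, scores)`` method works, where
``scores`` is a per-class probability dict summing to 1. Three reference
implementations ship here:

* :class:`OracleClassifier` reads the synthetic ground truth and returns the
  majority region class under the patch (the labeling rule used for real
  training patches: the predominant tissue component names the patch).
* :class:`HeuristicClassifier` is a rule-based stand-in using nuclear blob
  density and composition — a fixture-scale reference, not a CNN surrogate.
* :class:`ConstantClassifier` for degenerate tests.

Only tumor and stroma patches are prognostically relevant (they carry the
infiltrate); :func:`filter_prognostic` drops the rest.
"""

from __future__ import annotations

from typing import Optional, Protocol, Sequence

import numpy as np
from skimage.color import rgb2hed
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .config import (
    HeuristicClassifierParams,
    PROGNOSTIC_CLASSES,
    TISSUE_CLASSES,
)
from .image_io import PatchRecord, SlideHandle, read_region

__all__ = [
    "PatchClassifier",
    "OracleClassifier",
    "HeuristicClassifier",
    "ConstantClassifier",
    "classify_patches",
    "filter_prognostic",
    "balance_test_set",
    "balanced_subsample",
    "evaluate_classifier",
]

#: Tie-break priority for majority voting (first wins).
_CLASS_PRIORITY = TISSUE_CLASSES  # tumor > stroma > necrosis > normal


class PatchClassifier(Protocol):
    """Contract for patch classifiers.

    Implementations must be deterministic for a fixed patch and state.
    ``x0``/``y0`` give the patch's level-0 origin for implementations that
    need slide context (the oracle); pixel-based classifiers ignore them.
    """

    def classify(
        self, patch_rgb: np.ndarray, *, x0: int = 0, y0: int = 0
    ) -> tuple[str, dict[str, float]]: ...


def _one_hot(label: str) -> dict[str, float]:
    return {c: (1.0 if c == label else 0.0) for c in TISSUE_CLASSES}


class OracleClassifier:
    """Labels a patch with the majority ground-truth class under it.

    Votes are counted on the ground-truth region map (mask scale); ties and
    the all-background degenerate case resolve by the fixed priority
    tumor > stroma > necrosis > normal.
    """

    def __init__(self, ground_truth):
        self.gt = ground_truth

    def classify(self, patch_rgb, *, x0: int = 0, y0: int = 0):
        ds = self.gt.downsample
        size = patch_rgb.shape[0]
        r0, r1 = y0 // ds, max(y0 // ds + 1, (y0 + size) // ds)
        c0, c1 = x0 // ds, max(x0 // ds + 1, (x0 + size) // ds)
        block = self.gt.region_map[r0:r1, c0:c1]
        counts = {
            cls: int((block == code).sum())
            for code, cls in enumerate(TISSUE_CLASSES, start=1)
        }
        best = max(counts.values())
        if best == 0:
            label = "normal"  # pure-background patch: no tissue to vote
        else:
            label = next(c for c in _CLASS_PRIORITY if counts[c] == best)
        return label, _one_hot(label)


class ConstantClassifier:
    """Always returns the same label (degenerate-case testing)."""

    def __init__(self, label: str):
        if label not in TISSUE_CLASSES:
            raise ValueError(f"unknown label {label!r}")
        self.label = label

    def classify(self, patch_rgb, *, x0: int = 0, y0: int = 0):
        return self.label, _one_hot(self.label)


class HeuristicClassifier:
    """Rule-based reference classifier on nuclear-blob features.

    Features per patch: density of hematoxylin-positive blobs (per mm²),
    mean hematoxylin optical density, and the fraction of small
    (lymphocyte-sized) blobs. Rules: nearly acellular patches are necrosis;
    a high hematoxylin mean marks dense tumor cellularity; otherwise a
    substantial small-blob fraction indicates lymphocyte-rich stroma, else
    normal tissue. Thresholds live in
    :class:`~fastil.config.HeuristicClassifierParams` and were calibrated on
    the synthetic generator's default palette.
    """

    def __init__(
        self,
        mpp: float,
        params: HeuristicClassifierParams = HeuristicClassifierParams(),
    ):
        if mpp <= 0:
            raise ValueError("mpp must be positive")
        self.mpp = mpp
        self.params = params

    def _features(self, patch_rgb: np.ndarray) -> tuple[float, float, float]:
        p = self.params
        hed = rgb2hed(np.asarray(patch_rgb, dtype=np.float64) / 255.0)
        h_mean = float(hed[..., 0].mean())
        blobs = cc_label(hed[..., 0] > p.h_blob_threshold, connectivity=2)
        areas = np.array(
            [r.area for r in regionprops(blobs) if r.area >= p.min_blob_area]
        )
        area_mm2 = patch_rgb.shape[0] * patch_rgb.shape[1] * (self.mpp / 1000.0) ** 2
        density = len(areas) / area_mm2
        small_frac = (
            float((areas <= p.small_blob_area_max).mean()) if len(areas) else 0.0
        )
        return density, h_mean, small_frac

    def classify(self, patch_rgb, *, x0: int = 0, y0: int = 0):
        p = self.params
        density, h_mean, small_frac = self._features(patch_rgb)
        if density < p.necrosis_blob_density_max:
            label = "necrosis"
        elif h_mean >= p.tumor_h_mean_min:
            label = "tumor"
        elif small_frac >= p.stroma_small_blob_fraction_min:
            label = "stroma"
        else:
            label = "normal"
        return label, _one_hot(label)


def classify_patches(
    records: Sequence[PatchRecord],
    slide: SlideHandle,
    classifier: PatchClassifier,
) -> list[PatchRecord]:
    """Label every record; input order is preserved.

    A classifier failure is re-raised naming the offending patch.
    """
    out: list[PatchRecord] = []
    for rec in records:
        patch = read_region(slide, rec.x, rec.y, rec.patch_size, rec.patch_size)
        try:
            label, scores = classifier.classify(patch, x0=rec.x, y0=rec.y)
        except Exception as exc:
            raise RuntimeError(
                f"classifier failed on patch (x={rec.x}, y={rec.y}): {exc}"
            ) from exc
        out.append(rec.with_updates(label=label, scores=scores))
    return out


def filter_prognostic(records: Sequence[PatchRecord]) -> list[PatchRecord]:
    """Keep exactly the tumor and stroma patches (order preserved)."""
    for rec in records:
        if rec.label is None:
            raise ValueError(
                f"unlabeled record at (x={rec.x}, y={rec.y}); run classify_patches first"
            )
    return [r for r in records if r.label in PROGNOSTIC_CLASSES]


def balance_test_set(per_class_counts: dict[str, int]) -> int:
    """Target per-class count for a balanced test set: the minimum count."""
    if not per_class_counts:
        raise ValueError("per_class_counts is empty")
    return min(per_class_counts.values())


def balanced_subsample(
    labels: Sequence[str], seed: int = 0
) -> list[int]:
    """Indices of a class-balanced subset, clipped to the rarest class.

    Sampling within each class is uniform without replacement under ``seed``;
    returned indices are sorted (original order preserved).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("labels is empty")
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    target = balance_test_set({c: len(ix) for c, ix in by_class.items()})
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cls in sorted(by_class):
        ix = by_class[cls]
        pick = rng.choice(len(ix), size=target, replace=False)
        chosen.extend(ix[k] for k in pick)
    return sorted(chosen)


def evaluate_classifier(
    true_labels: Sequence[str], predicted_scores: Sequence[dict[str, float]]
) -> dict:
    """Accuracy, one-vs-rest AUCs, macro AUC, and the confusion matrix.

    ``predicted_scores`` are per-class probability dicts; the predicted label
    is the argmax (ties by class priority). Confusion-matrix rows are true
    classes in the canonical order. Per-class AUC is reported as NaN when a
    class has no positives or no negatives.
    """
    from sklearn.metrics import confusion_matrix, roc_auc_score

    if len(true_labels) != len(predicted_scores):
        raise ValueError("true_labels and predicted_scores length mismatch")
    classes = list(TISSUE_CLASSES)
    score_mat = np.array(
        [[s.get(c, 0.0) for c in classes] for s in predicted_scores], dtype=float
    )
    pred_labels = [
        # np.argmax ties -> lowest index = priority order
        classes[int(np.argmax(row))]
        for row in score_mat
    ]
    true_arr = np.asarray(true_labels)
    accuracy = float(np.mean(true_arr == np.asarray(pred_labels)))
    per_class_auc: dict[str, float] = {}
    for k, c in enumerate(classes):
        pos = true_arr == c
        if pos.all() or not pos.any():
            per_class_auc[c] = float("nan")
        else:
            per_class_auc[c] = float(roc_auc_score(pos, score_mat[:, k]))
    finite = [v for v in per_class_auc.values() if np.isfinite(v)]
    macro_auc = float(np.mean(finite)) if finite else float("nan")
    cm = confusion_matrix(true_arr, pred_labels, labels=classes)
    return {
        "accuracy": accuracy,
        "per_class_auc": per_class_auc,
        "macro_auc": macro_auc,
        "confusion_matrix": cm,
        "classes": classes,
    }
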
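"""Presegmentation preprocessing and ICDR grading evaluation.

Preprocessing mirrors the classifier input convention: crop the black
border around the retina, superimpose the color-coded lesion mask on the
feature image, and resize (area-based) to a fixed square input.

Grading follows the five-level ICDR scale. The rule-based grader maps a
lesion mask to a level from the most advanced lesion present: NV or PC
give level 4, IRMA level 3, HEM level 2, MA level 1, otherwise 0. Hard
exudates and cotton wool spots are segmented but do not raise the grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import roc_auc_score

from .labels import DEFAULT_PALETTE, LESION_CLASSES, LesionClass, validate_mask

N_LEVELS = 5


@dataclass(frozen=True)
class GradeRecord:
    """One graded image: reference level plus optional prediction."""

    image_id: str
    patient_id: str
    grade: int
    predicted: int | None = None
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.grade <= 4:
            raise ValueError(f"grade must be in 0..4, got {self.grade}")
        if self.predicted is not None and not 0 <= self.predicted <= 4:
            raise ValueError(f"predicted grade must be in 0..4, got {self.predicted}")
        if self.scores is not None:
            s = np.asarray(self.scores, dtype=float)
            if s.shape != (N_LEVELS,) or (s < 0).any() or abs(s.sum() - 1) > 1e-6:
                raise ValueError("scores must be 5 nonnegative values summing to 1")


# ---------------------------------------------------------------------------
# preprocessing


def border_bbox(image: np.ndarray, threshold: int = 10) -> tuple[int, int, int, int]:
    """Tight bounding box (r0, r1, c0, c1), half-open, of pixels whose
    maximum channel intensity exceeds *threshold*."""
    arr = np.asarray(image)
    bright = (arr.max(axis=2) if arr.ndim == 3 else arr) > threshold
    if not bright.any():
        raise ValueError("image is entirely dark; nothing to crop to")
    rows = np.flatnonzero(bright.any(axis=1))
    cols = np.flatnonzero(bright.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def crop_border(image: np.ndarray, threshold: int = 10) -> np.ndarray:
    """Crop the dark frame around the retina. Idempotent."""
    r0, r1, c0, c1 = border_bbox(image, threshold)
    return image[r0:r1, c0:c1]


def superimpose(
    image: np.ndarray,
    mask: np.ndarray,
    palette: Mapping[int, tuple[int, int, int]] = DEFAULT_PALETTE,
    alpha: float = 1.0,
) -> np.ndarray:
    """Paint lesion pixels with their palette color on a copy of *image*.

    ``alpha=1`` replaces the pixel outright (the default); lower values
    blend. Background and optic-disc pixels are never touched.
    """
    mask = validate_mask(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape[:2]}, mask {mask.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    out = image.copy()
    for cls in LESION_CLASSES:
        sel = mask == int(cls)
        if not sel.any():
            continue
        color = np.asarray(palette[int(cls)], dtype=float)
        if alpha >= 1.0:
            out[sel] = color.astype(out.dtype)
        else:
            blended = (1 - alpha) * image[sel].astype(float) + alpha * color
            out[sel] = np.round(blended).astype(out.dtype)
    return out


def downsample(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Deterministic area-based resampling to ``(width, height)``.

    Aspect ratio is not preserved: the image is resized to the target
    square (or rectangle) outright, matching a fixed network input size.
    """
    tw, th = target
    if tw < 8 or th < 8:
        raise ValueError("target size must be at least 8x8")
    arr = np.asarray(image)
    if arr.shape[:2] == (th, tw):
        return arr.copy()
    pil = Image.fromarray(arr)
    return np.asarray(pil.resize((tw, th), resample=Image.Resampling.BOX))


def preprocess(
    image: np.ndarray,
    mask: np.ndarray,
    size: int = 598,
    palette: Mapping[int, tuple[int, int, int]] = DEFAULT_PALETTE,
    alpha: float = 1.0,
    threshold: int = 10,
) -> np.ndarray:
    """Border crop, mask superimposition and resize, in that order."""
    r0, r1, c0, c1 = border_bbox(image, threshold)
    marked = superimpose(image[r0:r1, c0:c1], mask[r0:r1, c0:c1], palette, alpha)
    return downsample(marked, (size, size))


# ---------------------------------------------------------------------------
# rule-based grading


def rule_grade(mask: np.ndarray) -> int:
    """ICDR level implied by the most advanced lesion class in the mask."""
    present = set(np.unique(validate_mask(mask)).tolist())
    if int(LesionClass.NV) in present or int(LesionClass.PC) in present:
        return 4
    if int(LesionClass.IRMA) in present:
        return 3
    if int(LesionClass.HEM) in present:
        return 2
    if int(LesionClass.MA) in present:
        return 1
    return 0


def grade_scores(level: int, concentration: float = 2.0) -> tuple[float, ...]:
    """Soft per-level scores for a hard grade, peaked at the grade and
    decaying with squared ordinal distance (for ROC computations)."""
    if not 0 <= level <= 4:
        raise ValueError(f"level must be in 0..4, got {level}")
    raw = np.exp(-concentration * (np.arange(N_LEVELS) - level) ** 2)
    return tuple(raw / raw.sum())


# ---------------------------------------------------------------------------
# grading metrics


def grading_confusion(
    pred_levels: Sequence[int], ref_levels: Sequence[int]
) -> np.ndarray:
    """5x5 confusion matrix; entry (i, j) counts images with reference
    level i predicted as level j."""
    pred = np.asarray(pred_levels)
    ref = np.asarray(ref_levels)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("pred_levels and ref_levels must be aligned 1-D sequences")
    for name, arr in (("pred", pred), ("ref", ref)):
        if arr.size and (arr.min() < 0 or arr.max() > 4):
            raise ValueError(f"{name} levels out of range 0..4")
    conf = np.zeros((N_LEVELS, N_LEVELS), dtype=int)
    np.add.at(conf, (ref, pred), 1)
    return conf


def per_class_accuracy(conf: np.ndarray) -> tuple[np.ndarray, float, list[int]]:
    """Per-level accuracy (diagonal over row sum), its unweighted mean over
    nonempty levels, and the list of empty (excluded) levels."""
    conf = np.asarray(conf)
    if conf.size == 0 or conf.sum() == 0:
        raise ValueError("empty confusion matrix")
    row_sums = conf.sum(axis=1)
    acc = np.full(conf.shape[0], np.nan)
    nonzero = row_sums > 0
    acc[nonzero] = np.diag(conf)[nonzero] / row_sums[nonzero]
    excluded = np.flatnonzero(~nonzero).tolist()
    return acc, float(np.nanmean(acc)), excluded


def quadratic_weighted_kappa(conf: np.ndarray) -> float:
    """Quadratically weighted kappa of a k x k confusion matrix.

    ``kappa = 1 - sum(w * O) / sum(w * E)`` with weights
    ``w[i, j] = (i - j)^2 / (k - 1)^2``, O the observed counts and E the
    outer product of the marginals scaled to the same total. Returns NaN
    for degenerate marginals (all mass in a single row and column).
    """
    o = np.asarray(conf, dtype=float)
    total = o.sum()
    if total <= 0:
        raise ValueError("confusion matrix has no observations")
    k = o.shape[0]
    idx = np.arange(k)
    w = (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / total
    we = float((w * e).sum())
    if we == 0:
        return float("nan")
    return 1.0 - float((w * o).sum()) / we


def macro_auc(scores: Sequence[Sequence[float]], ref_levels: Sequence[int]) -> float:
    """One-vs-rest ROC AUC averaged (unweighted) over the levels present
    in the reference. Ties are handled by midranks."""
    s = np.asarray(scores, dtype=float)
    ref = np.asarray(ref_levels)
    if s.ndim != 2 or s.shape[1] != N_LEVELS or s.shape[0] != ref.shape[0]:
        raise ValueError("scores must be (n_images, 5) aligned with ref_levels")
    present = np.unique(ref)
    if present.size < 2:
        raise ValueError("need at least 2 distinct reference levels for AUC")
    aucs = [roc_auc_score(ref == lvl, s[:, lvl]) for lvl in present]
    return float(np.mean(aucs))


def grading_report(
    pred_levels: Sequence[int],
    ref_levels: Sequence[int],
    scores: Sequence[Sequence[float]] | None = None,
) -> dict:
    """All grading metrics in one machine-readable dict."""
    conf = grading_confusion(pred_levels, ref_levels)
    acc, mean_acc, excluded = per_class_accuracy(conf)
    report = {
        "per_class_accuracy": [None if np.isnan(a) else float(a) for a in acc],
        "mean_per_class_accuracy": mean_acc,
        "excluded_levels": excluded,
        "quadratic_weighted_kappa": quadratic_weighted_kappa(conf),
        "confusion": conf.tolist(),
    }
    if scores is not None:
        report["macro_auc"] = macro_auc(scores, ref_levels)
    return report


def confusion_frame(conf: np.ndarray) -> pd.DataFrame:
    """Confusion matrix as a labelled table (rows = reference level)."""
    labels = [f"level_{i}" for i in range(N_LEVELS)]
    return pd.DataFrame(conf, index=labels, columns=labels)
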
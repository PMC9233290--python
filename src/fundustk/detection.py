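"""Component-level and image-level lesion detection evaluation.

The unit of evaluation is a connected component of a single lesion class.
A predicted component counts as a true positive when at least one of its
pixels overlaps a reference pixel of the same class; otherwise it is a
false positive. A reference component that no same-class predicted pixel
touches is a false negative. Matching is therefore one-to-many: one
predicted component may mark several reference components as detected.
Precision is computed over predicted components, recall over reference
components.

Optic-disc pixels are treated as background throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import (
    BACKGROUND,
    LESION_CLASSES,
    LesionClass,
    class_name,
    validate_mask,
)

Connectivity = Literal[4, 8]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def _structure(connectivity: Connectivity) -> np.ndarray:
    try:
        return _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity!r}") from None


@dataclass(frozen=True)
class LesionComponent:
    """One connected region of a single lesion class."""

    cls: LesionClass
    component_id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col), lexicographically sorted

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or not len(self.pixels):
            raise ValueError("pixels must be a nonempty (n, 2) coordinate array")

    @property
    def pixel_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.pixels.tolist()))

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class ClassCounts:
    """Detection tallies for one class.

    ``tp``/``fp`` are counted over predicted components, ``fn`` over
    reference components. ``ref_tp`` is the number of reference components
    touched by a same-class prediction; at image level ``ref_tp == tp``.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    ref_tp: int = 0

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        return ClassCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.ref_tp + other.ref_tp,
        )


@dataclass(frozen=True)
class DetectionCounts:
    level: Literal["lesion", "image"]
    per_class: Mapping[LesionClass, ClassCounts]

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        if self.level != other.level:
            raise ValueError("cannot add counts from different levels")
        return DetectionCounts(
            self.level,
            {cls: self.per_class[cls] + other.per_class[cls] for cls in LESION_CLASSES},
        )


@dataclass(frozen=True)
class MetricTable:
    """Per-class precision/recall/F1 plus unweighted means.

    Undefined entries (e.g. precision with no predicted components) are
    ``None`` and excluded from the mean; the affected classes are listed in
    ``undefined``.
    """

    precision: Mapping[LesionClass, float | None]
    recall: Mapping[LesionClass, float | None]
    f1: Mapping[LesionClass, float | None]
    undefined: tuple[LesionClass, ...] = ()

    @staticmethod
    def _mean(values: Mapping[LesionClass, float | None]) -> float | None:
        defined = [v for v in values.values() if v is not None]
        return float(np.mean(defined)) if defined else None

    @property
    def mean_precision(self) -> float | None:
        return self._mean(self.precision)

    @property
    def mean_recall(self) -> float | None:
        return self._mean(self.recall)

    @property
    def mean_f1(self) -> float | None:
        return self._mean(self.f1)

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like the published per-class metric tables:
        rows Precision/Recall/F1, columns MA..NV plus Mean."""
        cols = [class_name(c) for c in LESION_CLASSES] + ["Mean"]
        rows = {}
        for name, values, mean in (
            ("Precision", self.precision, self.mean_precision),
            ("Recall", self.recall, self.mean_recall),
            ("F1", self.f1, self.mean_f1),
        ):
            rows[name] = [values[c] for c in LESION_CLASSES] + [mean]
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def extract_components(
    mask: np.ndarray, connectivity: Connectivity = 8
) -> list[LesionComponent]:
    """Split a label mask into per-class connected components.

    Background and optic disc yield no components. Components are returned
    in deterministic order: by class (tie-break order), then by the
    labelling order of ``scipy.ndimage.label`` within the class.
    """
    mask = validate_mask(mask)
    structure = _structure(connectivity)
    out: list[LesionComponent] = []
    for cls in LESION_CLASSES:
        labeled, n = ndimage.label(mask == int(cls), structure=structure)
        if not n:
            continue
        rows, cols = np.nonzero(labeled)
        ids = labeled[rows, cols]
        order = np.lexsort((cols, rows, ids))
        rows, cols, ids = rows[order], cols[order], ids[order]
        bounds = np.searchsorted(ids, np.arange(1, n + 2))
        for i in range(n):
            lo, hi = bounds[i], bounds[i + 1]
            coords = np.stack([rows[lo:hi], cols[lo:hi]], axis=1)
            out.append(LesionComponent(cls=cls, component_id=i + 1, pixels=coords))
    return out


def _check_shapes(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = validate_mask(pred)
    ref = validate_mask(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    return pred, ref


def match_lesions(
    pred: np.ndarray, ref: np.ndarray, connectivity: Connectivity = 8
) -> DetectionCounts:
    """Lesion-level matching of predicted against reference components.

    One pixel of same-class overlap suffices for a match.
    """
    pred, ref = _check_shapes(pred, ref)
    structure = _structure(connectivity)
    per_class: dict[LesionClass, ClassCounts] = {}
    for cls in LESION_CLASSES:
        p_bin = pred == int(cls)
        r_bin = ref == int(cls)
        p_lab, n_p = ndimage.label(p_bin, structure=structure)
        r_lab, n_r = ndimage.label(r_bin, structure=structure)
        matched_pred = np.unique(p_lab[r_bin & (p_lab > 0)])
        matched_ref = np.unique(r_lab[p_bin & (r_lab > 0)])
        tp = int(matched_pred.size)
        ref_tp = int(matched_ref.size)
        per_class[cls] = ClassCounts(tp=tp, fp=n_p - tp, fn=n_r - ref_tp, ref_tp=ref_tp)
    return DetectionCounts(level="lesion", per_class=per_class)


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den else None


def detection_metrics(counts: DetectionCounts) -> MetricTable:
    """Precision, recall and F1 per class, with unweighted means.

    ``precision = tp / (tp + fp)`` over predicted components and
    ``recall = ref_tp / (ref_tp + fn)`` over reference components. A class
    with no predicted (or no reference) components has undefined precision
    (recall); such classes are flagged and excluded from the means.
    """
    precision: dict[LesionClass, float | None] = {}
    recall: dict[LesionClass, float | None] = {}
    f1: dict[LesionClass, float | None] = {}
    undefined: list[LesionClass] = []
    for cls in LESION_CLASSES:
        c = counts.per_class[cls]
        p = _safe_div(c.tp, c.tp + c.fp)
        r = _safe_div(c.ref_tp, c.ref_tp + c.fn)
        precision[cls] = p
        recall[cls] = r
        if p is None or r is None:
            f1[cls] = None
            undefined.append(cls)
        else:
            f1[cls] = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return MetricTable(precision, recall, f1, tuple(undefined))


def metric_table(
    precision: Mapping[LesionClass, float] | None = None,
    recall: Mapping[LesionClass, float] | None = None,
    f1: Mapping[LesionClass, float] | None = None,
) -> MetricTable:
    """Build a :class:`MetricTable` directly from per-class metric values
    (e.g. published table rows) so the same mean aggregation applies."""
    empty: dict[LesionClass, float | None] = {cls: None for cls in LESION_CLASSES}
    return MetricTable(
        precision=dict(precision) if precision else dict(empty),
        recall=dict(recall) if recall else dict(empty),
        f1=dict(f1) if f1 else dict(empty),
    )


def adjusted_precision(
    pred: np.ndarray, ref: np.ndarray, connectivity: Connectivity = 8
) -> dict[LesionClass, float | None]:
    """Class-agnostic precision: a predicted component is a true positive
    if it overlaps a reference lesion pixel of *any* class."""
    pred, ref = _check_shapes(pred, ref)
    structure = _structure(connectivity)
    any_lesion = np.isin(ref, [int(c) for c in LESION_CLASSES])
    out: dict[LesionClass, float | None] = {}
    for cls in LESION_CLASSES:
        p_lab, n_p = ndimage.label(pred == int(cls), structure=structure)
        tp = int(np.unique(p_lab[any_lesion & (p_lab > 0)]).size)
        out[cls] = _safe_div(tp, n_p)
    return out


def image_level_detection(
    preds: Sequence[np.ndarray], refs: Sequence[np.ndarray]
) -> tuple[DetectionCounts, MetricTable]:
    """Image-level detection: per class, an image is a TP if both masks
    contain the class, an FP if only the prediction does, an FN if only
    the reference does; otherwise it contributes nothing."""
    if len(preds) != len(refs):
        raise ValueError(f"got {len(preds)} predictions but {len(refs)} references")
    tallies = {cls: [0, 0, 0] for cls in LESION_CLASSES}  # tp, fp, fn
    for pred, ref in zip(preds, refs):
        pred, ref = _check_shapes(pred, ref)
        p_present = set(np.unique(pred).tolist())
        r_present = set(np.unique(ref).tolist())
        for cls in LESION_CLASSES:
            in_p, in_r = int(cls) in p_present, int(cls) in r_present
            if in_p and in_r:
                tallies[cls][0] += 1
            elif in_p:
                tallies[cls][1] += 1
            elif in_r:
                tallies[cls][2] += 1
    counts = DetectionCounts(
        level="image",
        per_class={
            cls: ClassCounts(tp=t, fp=f, fn=n, ref_tp=t)
            for cls, (t, f, n) in tallies.items()
        },
    )
    return counts, detection_metrics(counts)


_CONF_COLS = [class_name(c) for c in LESION_CLASSES] + ["BG"]


def fp_confusion(
    pred: np.ndarray, ref: np.ndarray, connectivity: Connectivity = 8
) -> pd.DataFrame:
    """Attribute every predicted component to the reference content it sits on.

    Rows are predicted classes, columns the lesion classes plus BG. A
    component with same-class overlap lands on the diagonal (these cells
    equal the lesion-level true positives); otherwise it is attributed to
    the reference lesion class with the largest pixel overlap, ties broken
    by the fixed class order; with no lesion overlap at all it counts as BG.
    Optic-disc pixels count as background.
    """
    pred, ref = _check_shapes(pred, ref)
    structure = _structure(connectivity)
    table = pd.DataFrame(
        0, index=[class_name(c) for c in LESION_CLASSES], columns=_CONF_COLS, dtype=int
    )
    n_labels = max(int(c) for c in LESION_CLASSES) + 1
    for cls in LESION_CLASSES:
        p_lab, n_p = ndimage.label(pred == int(cls), structure=structure)
        if not n_p:
            continue
        nz = p_lab > 0
        # overlap[i, v] = pixels of component i lying on reference label v
        flat = (p_lab[nz].astype(np.int64) - 1) * n_labels + ref[nz]
        overlap = np.bincount(flat, minlength=n_p * n_labels).reshape(n_p, n_labels)
        for i in range(n_p):
            if overlap[i, int(cls)] > 0:
                table.loc[class_name(cls), class_name(cls)] += 1
                continue
            best: LesionClass | None = None
            best_n = 0
            for other in LESION_CLASSES:
                n_ov = overlap[i, int(other)]
                if n_ov > best_n:
                    best, best_n = other, n_ov
            if best is None:
                table.loc[class_name(cls), "BG"] += 1
            else:
                table.loc[class_name(cls), class_name(best)] += 1
    return table


def sum_confusions(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise sum of confusion tables with identical shape."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to sum")
    out = tables[0].copy()
    for t in tables[1:]:
        out += t
    return out


def image_fp_cooccurrence(
    preds: Sequence[np.ndarray], refs: Sequence[np.ndarray]
) -> pd.DataFrame:
    """Break image-level false positives down by reference co-occurrence.

    Rows are predicted classes. The ``TP`` column counts correctly detected
    images. For each image-level false positive, the row gains one count in
    the column of every lesion class present in that image's reference, or
    in ``NA`` if the reference contains no lesions at all.
    """
    if len(preds) != len(refs):
        raise ValueError(f"got {len(preds)} predictions but {len(refs)} references")
    cols = ["TP"] + [class_name(c) for c in LESION_CLASSES] + ["NA"]
    table = pd.DataFrame(
        0, index=[class_name(c) for c in LESION_CLASSES], columns=cols, dtype=int
    )
    for pred, ref in zip(preds, refs):
        pred, ref = _check_shapes(pred, ref)
        p_present = set(np.unique(pred).tolist())
        r_present = set(np.unique(ref).tolist())
        ref_classes = [c for c in LESION_CLASSES if int(c) in r_present]
        for cls in LESION_CLASSES:
            if int(cls) not in p_present:
                continue
            row = class_name(cls)
            if int(cls) in r_present:
                table.loc[row, "TP"] += 1
            elif ref_classes:
                for other in ref_classes:
                    table.loc[row, class_name(other)] += 1
            else:
                table.loc[row, "NA"] += 1
    return table


def relative_improvement(new_value: float, old_value: float) -> float:
    """Percent change ``100 * (new - old) / old``, rounded to one decimal."""
    if old_value <= 0:
        raise ValueError(f"old_value must be positive, got {old_value}")
    return round(100.0 * (new_value - old_value) / old_value, 1)
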
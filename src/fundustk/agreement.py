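"""Inter-annotator agreement on per-image lesion counts.

Agreement is measured with the intraclass correlation coefficient in its
two-way random-effects, absolute-agreement, single-rater form (ICC(2,1)),
computed from the standard ANOVA mean-squares decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import LESION_CLASSES, LesionClass, class_name, validate_mask


def lesion_counts(
    masks: Sequence[np.ndarray], connectivity: int = 8
) -> pd.DataFrame:
    """Connected-component counts per image (rows) and lesion class (columns)."""
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    rows = []
    for mask in masks:
        mask = validate_mask(mask)
        rows.append(
            {
                class_name(cls): ndimage.label(mask == int(cls), structure=structure)[1]
                for cls in LESION_CLASSES
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ICCResult:
    value: float  # NaN when undefined
    msr: float  # between-image (row) mean square
    msc: float  # between-rater (column) mean square
    mse: float  # residual mean square

    @property
    def defined(self) -> bool:
        return not np.isnan(self.value)


def icc(counts: np.ndarray) -> ICCResult:
    """ICC(2,1) for an (images x raters) matrix of measurements.

    Returns NaN (flagged via ``defined``) when the total variance is zero,
    in which case agreement is not estimable.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"need an (n>=2, k>=2) matrix, got shape {x.shape}")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if sst == 0 or denom == 0:
        return ICCResult(value=float("nan"), msr=msr, msc=msc, mse=mse)
    return ICCResult(value=(msr - mse) / denom, msr=msr, msc=msc, mse=mse)


def agreement_by_class(
    masks_a: Sequence[np.ndarray],
    masks_b: Sequence[np.ndarray],
    connectivity: int = 8,
) -> pd.Series:
    """Per-lesion-class ICC(2,1) between two annotators' mask series."""
    if len(masks_a) != len(masks_b):
        raise ValueError("annotator mask lists must be aligned")
    ca = lesion_counts(masks_a, connectivity)
    cb = lesion_counts(masks_b, connectivity)
    values = {}
    for cls in LESION_CLASSES:
        name = class_name(cls)
        values[name] = icc(np.stack([ca[name], cb[name]], axis=1)).value
    return pd.Series(values, name="ICC")
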
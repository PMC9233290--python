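"""Label conventions shared by every module.

A :class:`LabelMask` is a 2-D ``uint8`` array with one label per pixel.
Label values are fixed:

====================  =====
label                 value
====================  =====
background            0
optic disc            1
MA  (microaneurysm)   2
HEM (hemorrhage)      3
CWS (cotton wool)     4
HE  (hard exudate)    5
PC  (photocoag. scar) 6
IRMA                  7
NV  (neovasc.)        8
====================  =====

Coordinates are 0-based ``(row, col)`` with the origin at the top-left.
The ascending integer order of the seven lesion classes doubles as the
deterministic tie-break order used wherever a tie must be resolved.
"""

from __future__ import annotations

import enum

import numpy as np

BACKGROUND: int = 0
OPTIC_DISC: int = 1


class LesionClass(enum.IntEnum):
    """The seven lesion classes evaluated at component level."""

    MA = 2
    HEM = 3
    CWS = 4
    HE = 5
    PC = 6
    IRMA = 7
    NV = 8


#: Reporting (and tie-break) order of the lesion classes.
LESION_CLASSES: tuple[LesionClass, ...] = (
    LesionClass.MA,
    LesionClass.HEM,
    LesionClass.CWS,
    LesionClass.HE,
    LesionClass.PC,
    LesionClass.IRMA,
    LesionClass.NV,
)

#: All valid label values, including the two reserved labels.
ALL_LABELS: tuple[int, ...] = (BACKGROUND, OPTIC_DISC) + tuple(int(c) for c in LESION_CLASSES)

N_LABELS: int = len(ALL_LABELS)

#: Display palette for masks and for superimposition onto feature images.
#: Lesion colors: MA green, HEM magenta, CWS yellow, HE red, IRMA cyan,
#: NV blue, PC purple; optic disc orange; background black.
DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    BACKGROUND: (0, 0, 0),
    OPTIC_DISC: (255, 170, 0),
    LesionClass.MA: (0, 255, 0),
    LesionClass.HEM: (255, 0, 255),
    LesionClass.CWS: (255, 255, 0),
    LesionClass.HE: (255, 0, 0),
    LesionClass.PC: (160, 32, 240),
    LesionClass.IRMA: (0, 255, 255),
    LesionClass.NV: (0, 0, 255),
}


def class_name(label: int) -> str:
    """Human-readable name for any valid label value."""
    if label == BACKGROUND:
        return "BG"
    if label == OPTIC_DISC:
        return "OD"
    return LesionClass(label).name


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check that *mask* is a 2-D integer array containing only known labels.

    Returns the mask as ``uint8``. Raises ``ValueError`` otherwise.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label mask must be integer-typed, got {arr.dtype}")
    bad = np.setdiff1d(np.unique(arr), np.asarray(ALL_LABELS))
    if bad.size:
        raise ValueError(f"unknown label values in mask: {bad.tolist()}")
    return arr.astype(np.uint8, copy=False)


def lesion_presence(mask: np.ndarray) -> dict[LesionClass, bool]:
    """Per-class presence flags (any pixel of the class in the mask)."""
    present = np.unique(mask)
    return {cls: bool(int(cls) in present) for cls in LESION_CLASSES}
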
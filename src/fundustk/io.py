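"""File formats: indexed-PNG masks, RGB images, grade CSVs, YAML manifests.

Masks are stored as paletted (mode "P") PNGs whose first nine palette
entries are the documented label colors; readers reject files whose
palette does not match, so a mask can never be silently reinterpreted
under a permuted palette.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .grading import GradeRecord
from .labels import ALL_LABELS, DEFAULT_PALETTE, N_LABELS, validate_mask

_PALETTE_FLAT: list[int] = []
for label in range(N_LABELS):
    _PALETTE_FLAT.extend(DEFAULT_PALETTE[ALL_LABELS[label]])
_PALETTE_FLAT.extend([0] * (768 - len(_PALETTE_FLAT)))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a label mask as an indexed PNG with the documented palette."""
    mask = validate_mask(mask)
    img = Image.fromarray(mask, mode="P")
    img.putpalette(_PALETTE_FLAT)
    img.save(path, format="PNG")


def read_mask(path: str | Path) -> np.ndarray:
    """Read an indexed-PNG label mask, verifying mode, palette and labels."""
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(f"{path}: expected an indexed (mode 'P') PNG, got mode {img.mode!r}")
    palette = img.getpalette() or []
    palette = palette + [0] * (768 - len(palette))
    for label in range(N_LABELS):
        expected = tuple(_PALETTE_FLAT[3 * label : 3 * label + 3])
        found = tuple(palette[3 * label : 3 * label + 3])
        if found != expected:
            raise ValueError(
                f"{path}: palette entry {label} is {found}, expected {expected}"
            )
    arr = np.asarray(img, dtype=np.uint8)
    if arr.max(initial=0) >= N_LABELS:
        raise ValueError(f"{path}: pixel value {int(arr.max())} outside the label set")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path, format="PNG")


def read_image(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "RGB":
        img = img.convert("RGB")
    return np.asarray(img, dtype=np.uint8)


# ---------------------------------------------------------------------------
# grade tables


def write_grades(path: str | Path, records: Iterable[GradeRecord]) -> None:
    rows = []
    for rec in records:
        row: dict = {
            "image_id": rec.image_id,
            "patient_id": rec.patient_id,
            "grade": rec.grade,
        }
        if rec.predicted is not None:
            row["predicted"] = rec.predicted
        if rec.scores is not None:
            for i, s in enumerate(rec.scores):
                row[f"score_{i}"] = s
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_grades(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "patient_id": str})
    for col in ("image_id", "grade"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# manifests and reports


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration dict."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int) -> None:
    payload = {"seed": seed, "config": config, "config_hash": config_hash(config)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_metric_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """Human-facing CSV with floats at 4 decimals."""
    frame.to_csv(path, float_format="%.4f")
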
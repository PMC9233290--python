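"""Patch sampling, augmentation, multi-head fusion and tiled inference.

Full-resolution inference runs a pixelwise predictor over overlapping
tiles and stitches the results, keeping only the central region of each
tile (the configured margin is cropped from every tile edge) so that
boundary artifacts of the predictor never reach the output. Tiles at the
image boundary are shifted inward rather than padded, so no pixel values
are invented.

The :class:`Predictor` contract is deliberately small so any backend can
plug in: a trained network, a thresholding rule, or a corrupted
ground-truth oracle. A reference color-threshold segmenter ships here for
tests and demos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .labels import BACKGROUND, LesionClass
from .synth import LESION_COLORS, OPTIC_DISC_COLOR, RETINA_BASE
from . import labels as _labels


@dataclass(frozen=True)
class TileConfig:
    """Geometry of patch training and tiled inference."""

    patch_size: int = 256
    tile_size: int = 1024
    margin: int = 128
    stride: int = 256
    head_weights: tuple[float, ...] = (0.33, 0.33, 0.33)

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.tile_size < 1:
            raise ValueError("patch_size and tile_size must be positive")
        if not 0 <= self.margin < self.tile_size / 2:
            raise ValueError(
                f"margin must satisfy 0 <= margin < tile_size/2, got {self.margin}"
            )
        if not 0 < self.stride <= self.patch_size:
            raise ValueError("stride must be in (0, patch_size]")
        if any(w <= 0 for w in self.head_weights):
            raise ValueError("head weights must be positive")

    @property
    def inference_stride(self) -> int:
        """Step between tile origins that makes cropped centers abut."""
        return self.tile_size - 2 * self.margin


@dataclass(frozen=True)
class AugmentParams:
    flip_horizontal: float = 0.5
    flip_vertical: float = 0.5
    shift_max: int = 16
    gamma_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        for name in ("flip_horizontal", "flip_vertical"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.shift_max < 0:
            raise ValueError("shift_max must be nonnegative")
        lo, hi = self.gamma_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid gamma_range {self.gamma_range}")


@runtime_checkable
class Predictor(Protocol):
    """Pixel-probability predictor contract.

    ``classes`` maps output-channel index to label value. ``predict``
    takes an RGB crop of any size and returns one ``(h, w, n_classes)``
    probability map per head; each pixel's probabilities must be
    nonnegative and sum to 1 within 1e-6.
    """

    classes: Sequence[int]

    def predict(self, crop: np.ndarray) -> list[np.ndarray]: ...


# ---------------------------------------------------------------------------
# patch sampling and augmentation


def _grid_origins(size: int, window: int, step: int) -> list[int]:
    origins = list(range(0, size - window + 1, step))
    if origins[-1] != size - window:
        origins.append(size - window)
    return origins


def sample_patches(
    image: np.ndarray, mask: np.ndarray, cfg: TileConfig
) -> list[tuple[np.ndarray, np.ndarray, tuple[int, int]]]:
    """Sliding-window patches over an image/mask pair.

    Returns ``(image_patch, mask_patch, (row, col) origin)`` triples in
    row-major order. A trailing window is appended per axis when the
    stride does not divide the image evenly, so the whole image is covered.
    """
    h, w = mask.shape
    p = cfg.patch_size
    if p > h or p > w:
        raise ValueError(f"patch size {p} exceeds image dimensions {(h, w)}")
    out = []
    for r in _grid_origins(h, p, cfg.stride):
        for c in _grid_origins(w, p, cfg.stride):
            out.append((image[r : r + p, c : c + p], mask[r : r + p, c : c + p], (r, c)))
    return out


def apply_shift(arr: np.ndarray, dy: int, dx: int, fill: int = 0) -> np.ndarray:
    """Translate by (dy, dx), filling vacated pixels with *fill*."""
    out = np.full_like(arr, fill)
    h, w = arr.shape[:2]
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[yd, xd] = arr[ys, xs]
    return out


def apply_gamma(image: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma-adjust an 8-bit image; gamma 1.0 is the identity."""
    if gamma == 1.0:
        return image.copy()
    lut = np.round(255.0 * (np.arange(256) / 255.0) ** gamma).astype(np.uint8)
    return lut[image]


def augment(
    patch: np.ndarray,
    mask_patch: np.ndarray,
    params: AugmentParams,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random flip / shift / gamma augmentation.

    Geometric transforms are applied identically to the image and the
    mask; the gamma adjustment touches the image only.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img, msk = patch, mask_patch
    if rng.random() < params.flip_horizontal:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < params.flip_vertical:
        img, msk = img[::-1], msk[::-1]
    if params.shift_max > 0:
        dy, dx = rng.integers(-params.shift_max, params.shift_max + 1, size=2)
        img = apply_shift(img, int(dy), int(dx))
        msk = apply_shift(msk, int(dy), int(dx), fill=BACKGROUND)
    lo, hi = params.gamma_range
    if (lo, hi) != (1.0, 1.0):
        img = apply_gamma(np.ascontiguousarray(img), float(rng.uniform(lo, hi)))
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


# ---------------------------------------------------------------------------
# fusion and tiled inference


def _validate_heads(head_probs: Sequence[np.ndarray], atol: float = 1e-6) -> np.ndarray:
    if not head_probs:
        raise ValueError("need at least one head")
    if any(np.shape(h) != np.shape(head_probs[0]) for h in head_probs):
        raise ValueError(f"head shapes differ: {[np.shape(h) for h in head_probs]}")
    stack = np.stack([np.asarray(h, dtype=float) for h in head_probs])
    if stack.ndim != 4:
        raise ValueError("each head must be an (h, w, n_classes) probability map")
    if (stack < -atol).any():
        raise ValueError("negative probabilities in head output")
    sums = stack.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-5):
        worst = float(np.abs(sums - 1.0).max())
        raise ValueError(f"head probabilities not normalized (max deviation {worst:.2e})")
    return stack


def fuse_heads(head_probs: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel argmax of the unweighted mean of the heads' probabilities.

    Returns an (h, w) array of channel indices; ties break to the lowest
    index.
    """
    stack = _validate_heads(head_probs)
    return np.argmax(stack.mean(axis=0), axis=-1)


def tiled_predict(image: np.ndarray, predictor: Predictor, cfg: TileConfig) -> np.ndarray:
    """Full-resolution label mask via overlapping-tile inference.

    Every output pixel is written exactly once, from a tile in which it
    lies at least ``cfg.margin`` pixels from the tile edge (except where
    the image boundary forces otherwise). Boundary tiles are shifted
    inward, never padded.
    """
    h, w = image.shape[:2]
    t, m = cfg.tile_size, cfg.margin
    if t > h or t > w:
        raise ValueError(f"tile size {t} exceeds image dimensions {(h, w)}")
    step = cfg.inference_stride
    classes = np.asarray(list(predictor.classes))

    def origins(size: int) -> list[int]:
        out = [0]
        while out[-1] + t < size:
            out.append(min(out[-1] + step, size - t))
        return out

    ys, xs = origins(h), origins(w)
    cuts_y = [0] + [o + m for o in ys[1:]] + [h]
    cuts_x = [0] + [o + m for o in xs[1:]] + [w]

    out = np.zeros((h, w), dtype=classes.dtype)
    for i, oy in enumerate(ys):
        for j, ox in enumerate(xs):
            tile = image[oy : oy + t, ox : ox + t]
            heads = predictor.predict(tile)
            try:
                idx = fuse_heads(heads)
            except ValueError as err:
                raise ValueError(f"invalid predictor output at tile ({oy}, {ox}): {err}")
            if idx.shape != (t, t):
                raise ValueError(
                    f"predictor returned shape {idx.shape} for tile at ({oy}, {ox}), "
                    f"expected {(t, t)}"
                )
            y0, y1 = cuts_y[i], cuts_y[i + 1]
            x0, x1 = cuts_x[j], cuts_x[j + 1]
            out[y0:y1, x0:x1] = classes[idx[y0 - oy : y1 - oy, x0 - ox : x1 - ox]]
    return out


def predict_whole(image: np.ndarray, predictor: Predictor) -> np.ndarray:
    """Single-shot prediction on the whole image (no tiling)."""
    idx = fuse_heads(predictor.predict(image))
    return np.asarray(list(predictor.classes))[idx]


# ---------------------------------------------------------------------------
# reference predictor


class ColorPrototypePredictor:
    """Pixelwise nearest-prototype segmenter with softmax probabilities.

    Classifies each pixel by the distance of its RGB value to a set of
    class prototype colors. Heads differ only in softmax temperature, so
    the fused argmax stays the nearest prototype. Because the output at a
    pixel depends only on that pixel's color, tiled inference must agree
    exactly with whole-image inference — this is the reference backend for
    the stitching-correctness checks.
    """

    def __init__(
        self,
        prototypes: Mapping[int, tuple[int, int, int]] | None = None,
        temperatures: Sequence[float] = (25.0, 40.0, 60.0),
    ) -> None:
        if prototypes is None:
            prototypes = {
                BACKGROUND: (0, 0, 0),
                _labels.OPTIC_DISC: OPTIC_DISC_COLOR,
                **{int(c): LESION_COLORS[c] for c in LESION_COLORS},
            }
            prototypes[BACKGROUND] = (0, 0, 0)
        self.classes = sorted(prototypes)
        self._colors = np.asarray([prototypes[c] for c in self.classes], dtype=float)
        # the retina base (across its radial shading range) counts as
        # background so the fundus disc itself is not read as lesion
        base = np.asarray(RETINA_BASE, dtype=float)
        self._bg_shades = np.stack([base * s for s in (1.0, 0.92, 0.84, 0.76)])
        self.temperatures = tuple(temperatures)

    def predict(self, crop: np.ndarray) -> list[np.ndarray]:
        rgb = np.asarray(crop, dtype=float)
        sq = (rgb**2).sum(axis=-1, keepdims=True)
        d2 = sq - 2.0 * (rgb @ self._colors.T) + (self._colors**2).sum(axis=1)
        d = np.sqrt(np.maximum(d2, 0.0))
        bg_idx = self.classes.index(BACKGROUND)
        d2_base = (
            sq - 2.0 * (rgb @ self._bg_shades.T) + (self._bg_shades**2).sum(axis=1)
        ).min(axis=-1)
        d[..., bg_idx] = np.minimum(d[..., bg_idx], np.sqrt(np.maximum(d2_base, 0.0)))
        heads = []
        for tau in self.temperatures:
            logits = -d / tau
            logits -= logits.max(axis=-1, keepdims=True)
            e = np.exp(logits)
            heads.append(e / e.sum(axis=-1, keepdims=True))
        return heads
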
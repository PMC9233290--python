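"""Seeded synthetic six-field-style fundus images with paired annotations.

The generator renders a dark circular "retina" on a black frame and places
non-overlapping lesions of the seven classes on it, with a composition
chosen so that the rule-based grade of the mask equals the requested ICDR
level. Rendering is deliberately cartoonish: only the topology and size
statistics matter to the downstream evaluation code, not photorealism.

Two corruption entry points produce a noisier "second annotator" mask and
an imperfect "model output" mask from the same reference, on independent
seed streams.

Randomness contract (needed to resimulate corruption draws in tests):
for each reference component, in the deterministic order returned by
:func:`fundustk.detection.extract_components`, the corruption engine draws

1. one uniform for the drop decision (only if ``drop_rate > 0``);
2. one uniform per applicable ``type_swap`` entry, in sorted key order,
   stopping at the first swap that fires (only for surviving components);
3. one integer pair in ``[-j, j]`` for the jitter offset (only if
   ``boundary_jitter > 0``).

Spurious components are drawn afterwards: one Poisson count, then per
component a class index, a diameter and a center position.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import disk as draw_disk

from .detection import extract_components
from .labels import (
    BACKGROUND,
    LESION_CLASSES,
    OPTIC_DISC,
    LesionClass,
    validate_mask,
)

# ---------------------------------------------------------------------------
# specs


def _default_counts() -> dict[LesionClass, int]:
    return {
        LesionClass.MA: 8,
        LesionClass.HEM: 4,
        LesionClass.CWS: 2,
        LesionClass.HE: 3,
        LesionClass.PC: 5,
        LesionClass.IRMA: 3,
        LesionClass.NV: 2,
    }


def _default_sizes() -> dict[LesionClass, tuple[int, int]]:
    # (min, max) diameter in pixels at the default 640 px frame
    return {
        LesionClass.MA: (2, 5),
        LesionClass.HEM: (6, 20),
        LesionClass.CWS: (8, 16),
        LesionClass.HE: (4, 10),
        LesionClass.PC: (8, 14),
        LesionClass.IRMA: (10, 24),
        LesionClass.NV: (12, 28),
    }


#: Render color per lesion class (dark lesions darker than the retina base,
#: bright deposits brighter). These drive the reference color-threshold
#: segmenter in :mod:`fundustk.tiling`.
LESION_COLORS: dict[LesionClass, tuple[int, int, int]] = {
    LesionClass.MA: (110, 30, 30),
    LesionClass.HEM: (60, 10, 20),
    LesionClass.CWS: (230, 230, 205),
    LesionClass.HE: (255, 235, 130),
    LesionClass.PC: (215, 190, 170),
    LesionClass.IRMA: (85, 35, 60),
    LesionClass.NV: (40, 25, 70),
}

RETINA_BASE: tuple[int, int, int] = (168, 70, 48)
OPTIC_DISC_COLOR: tuple[int, int, int] = (235, 190, 140)


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and composition parameters of one synthetic image."""

    width: int = 640
    height: int = 640
    retina_radius_fraction: float = 0.46
    lesion_counts: Mapping[LesionClass, int] = field(default_factory=_default_counts)
    size_ranges: Mapping[LesionClass, tuple[int, int]] = field(default_factory=_default_sizes)
    noise_amplitude: int = 10

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("image dimensions must be at least 64 px")
        if not 0 < self.retina_radius_fraction <= 0.5:
            raise ValueError("retina_radius_fraction must lie in (0, 0.5]")
        for cls, n in self.lesion_counts.items():
            if n < 0:
                raise ValueError(f"negative lesion count for {cls.name}")
        for cls, (lo, hi) in self.size_ranges.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid size range for {cls.name}: ({lo}, {hi})")

    @property
    def retina_radius(self) -> float:
        return self.retina_radius_fraction * min(self.width, self.height)

    @property
    def retina_center(self) -> tuple[float, float]:
        return (self.height / 2.0, self.width / 2.0)


@dataclass(frozen=True)
class AnnotatedImage:
    """Synthetic image with its reference mask, grade and identifiers."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8
    grade: int
    image_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")
        if not 0 <= self.grade <= 4:
            raise ValueError(f"grade must be in 0..4, got {self.grade}")


@dataclass(frozen=True)
class CorruptionParams:
    """Knobs for turning a reference mask into an imperfect one."""

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    type_swap: Mapping[tuple[LesionClass, LesionClass], float] = field(default_factory=dict)
    boundary_jitter: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be nonnegative")
        for (a, b), p in self.type_swap.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"swap probability for {a.name}->{b.name} out of [0, 1]")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return (
            self.drop_rate == 0
            and self.spurious_rate == 0
            and self.boundary_jitter == 0
            and not any(p > 0 for p in self.type_swap.values())
        )


@dataclass(frozen=True)
class SplitSpec:
    """Dataset split targets."""

    fractions: tuple[float, float, float] = (0.75, 0.10, 0.15)
    nv_train_fraction: float = 0.70
    patient_exclusive: bool = True

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(self.fractions)}")
        if not 0.0 <= self.nv_train_fraction <= 1.0:
            raise ValueError("nv_train_fraction must lie in [0, 1]")


# grade -> lesion classes rendered; the first entry is mandatory (it defines
# the grade), the rest are included when their configured count is > 0.
_GRADE_COMPOSITION: dict[int, tuple[LesionClass, ...]] = {
    0: (),
    1: (LesionClass.MA,),
    2: (LesionClass.HEM, LesionClass.MA, LesionClass.HE),
    3: (LesionClass.IRMA, LesionClass.MA, LesionClass.HEM, LesionClass.CWS),
    4: (
        LesionClass.NV,
        LesionClass.PC,
        LesionClass.IRMA,
        LesionClass.HEM,
        LesionClass.MA,
        LesionClass.HE,
    ),
}


# ---------------------------------------------------------------------------
# lesion footprint renderers (small local canvases -> relative coordinates)


def _footprint_disc(diameter: int, rng: np.random.Generator) -> np.ndarray:
    radius = max(diameter / 2.0, 1.0)
    rr, cc = draw_disk((0, 0), radius)
    return np.stack([rr, cc], axis=1)


def _footprint_blob(diameter: int, rng: np.random.Generator) -> np.ndarray:
    """Irregular blob: random walk dilated by a small disc."""
    half = max(diameter // 2, 2)
    canvas = np.zeros((2 * half + 5, 2 * half + 5), dtype=bool)
    r = c = half + 2
    for _ in range(max(diameter * 2, 8)):
        canvas[r, c] = True
        dr, dc = rng.integers(-1, 2, size=2)
        r = int(np.clip(r + dr, 2, canvas.shape[0] - 3))
        c = int(np.clip(c + dc, 2, canvas.shape[1] - 3))
    from scipy import ndimage as ndi

    canvas = ndi.binary_dilation(canvas, iterations=max(half // 3, 1))
    rr, cc = np.nonzero(canvas)
    return np.stack([rr - (half + 2), cc - (half + 2)], axis=1)


def _footprint_curve(diameter: int, rng: np.random.Generator) -> np.ndarray:
    """Thin vessel-like tangle: momentum random walk dilated by one pixel."""
    half = max(diameter // 2, 3)
    size = 2 * half + 5
    canvas = np.zeros((size, size), dtype=bool)
    r = c = float(half + 2)
    angle = rng.uniform(0, 2 * np.pi)
    for _ in range(max(diameter * 3, 12)):
        canvas[int(r), int(c)] = True
        angle += rng.uniform(-0.9, 0.9)
        r = float(np.clip(r + np.sin(angle), 1, size - 2))
        c = float(np.clip(c + np.cos(angle), 1, size - 2))
    from scipy import ndimage as ndi

    canvas = ndi.binary_dilation(canvas)
    rr, cc = np.nonzero(canvas)
    return np.stack([rr - (half + 2), cc - (half + 2)], axis=1)


_RENDERERS = {
    LesionClass.MA: _footprint_disc,
    LesionClass.HEM: _footprint_blob,
    LesionClass.CWS: _footprint_blob,
    LesionClass.HE: _footprint_blob,
    LesionClass.PC: _footprint_disc,
    LesionClass.IRMA: _footprint_curve,
    LesionClass.NV: _footprint_curve,
}


# ---------------------------------------------------------------------------
# image generation


def _child_seed(master_seed: int, image_id: str) -> int:
    """Stable 64-bit per-image seed derived from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{image_id}".encode(), digest_size=8)
    return int.from_bytes(digest.digest(), "big")


def generate_image(
    spec: ImageSpec, grade: int, seed: int, image_id: str = "", patient_id: str = ""
) -> AnnotatedImage:
    """Render one synthetic annotated image whose mask grades as *grade*.

    The same ``(spec, grade, seed)`` triple reproduces the output
    bit-for-bit.
    """
    if not isinstance(grade, (int, np.integer)) or not 0 <= grade <= 4:
        raise ValueError(f"grade must be an integer in 0..4, got {grade!r}")
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    cy, cx = spec.retina_center
    radius = spec.retina_radius

    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    inside = dist <= radius

    image = np.zeros((h, w, 3), dtype=np.int16)
    noise = rng.integers(
        -spec.noise_amplitude, spec.noise_amplitude + 1, size=(h, w, 3), dtype=np.int16
    )
    base = np.asarray(RETINA_BASE, dtype=np.int16)
    # mild radial shading so the disc is not flat
    shade = (1.0 - 0.25 * (dist / max(radius, 1.0)) ** 2)[..., None]
    image[inside] = np.clip(base * shade[inside] + noise[inside], 0, 255).astype(np.int16)

    mask = np.full((h, w), BACKGROUND, dtype=np.uint8)

    # optic disc: bright circle offset from the center
    od_radius = 0.16 * radius
    od_center = (cy - 0.35 * radius, cx + 0.4 * radius)
    rr, cc = draw_disk(od_center, od_radius, shape=(h, w))
    mask[rr, cc] = OPTIC_DISC
    image[rr, cc] = OPTIC_DISC_COLOR

    occupied = np.zeros((h, w), dtype=bool)
    occupied[rr, cc] = True

    classes = [
        cls
        for cls in _GRADE_COMPOSITION[grade]
        if spec.lesion_counts.get(cls, 0) > 0 or cls is _GRADE_COMPOSITION[grade][0]
    ] if grade else []

    for k, cls in enumerate(classes):
        n_wanted = max(spec.lesion_counts.get(cls, 0), 1 if k == 0 else 0)
        placed = _place_lesions(
            cls, n_wanted, spec, rng, mask, image, occupied, dist, radius
        )
        if k == 0 and placed == 0:
            raise ValueError(
                f"could not fit a mandatory {cls.name} lesion inside the retina disc"
            )

    out = np.clip(image, 0, 255).astype(np.uint8)
    out[~inside] = 0
    return AnnotatedImage(
        image=out, mask=mask, grade=int(grade), image_id=image_id, patient_id=patient_id
    )


def _place_lesions(
    cls: LesionClass,
    n_wanted: int,
    spec: ImageSpec,
    rng: np.random.Generator,
    mask: np.ndarray,
    image: np.ndarray,
    occupied: np.ndarray,
    dist: np.ndarray,
    radius: float,
) -> int:
    """Place up to *n_wanted* lesions of *cls*; returns the number placed."""
    h, w = mask.shape
    lo, hi = spec.size_ranges[cls]
    if lo >= 2 * radius:
        raise ValueError(f"{cls.name} lesions of size {lo} cannot fit the retina disc")
    color = np.asarray(LESION_COLORS[cls], dtype=np.int16)
    placed = 0
    for _ in range(n_wanted):
        for _attempt in range(60):
            diameter = int(rng.integers(lo, hi + 1))
            footprint = _RENDERERS[cls](diameter, rng)
            margin = float(np.abs(footprint).max()) + 2.0
            if margin >= radius:
                continue
            u = rng.random()
            theta = rng.uniform(0, 2 * np.pi)
            rad = (radius - margin) * np.sqrt(u)
            cy, cx = spec.retina_center
            r0 = int(round(cy + rad * np.sin(theta)))
            c0 = int(round(cx + rad * np.cos(theta)))
            rr = footprint[:, 0] + r0
            cc = footprint[:, 1] + c0
            if rr.min() < 1 or cc.min() < 1 or rr.max() >= h - 1 or cc.max() >= w - 1:
                continue
            # keep one-pixel separation from anything placed before so the
            # component count equals the lesion count under 8-connectivity
            halo = np.stack(
                [rr[:, None] + np.array([-1, -1, -1, 0, 0, 0, 1, 1, 1]),
                 cc[:, None] + np.array([-1, 0, 1, -1, 0, 1, -1, 0, 1])],
                axis=-1,
            ).reshape(-1, 2)
            if occupied[halo[:, 0], halo[:, 1]].any():
                continue
            if (dist[rr, cc] > radius - 1).any():
                continue
            mask[rr, cc] = int(cls)
            image[rr, cc] = color
            occupied[rr, cc] = True
            placed += 1
            break
    return placed


# ---------------------------------------------------------------------------
# corruption


def _paint_pixels(out: np.ndarray, pixels: np.ndarray, label: int) -> None:
    sel = out[pixels[:, 0], pixels[:, 1]] == BACKGROUND
    out[pixels[sel, 0], pixels[sel, 1]] = label


def _corrupt_mask(
    mask: np.ndarray, params: CorruptionParams, rng: np.random.Generator
) -> np.ndarray:
    mask = validate_mask(mask)
    h, w = mask.shape
    out = np.where(mask == OPTIC_DISC, OPTIC_DISC, BACKGROUND).astype(np.uint8)
    swap_keys = sorted(params.type_swap.items(), key=lambda kv: (int(kv[0][0]), int(kv[0][1])))
    for comp in extract_components(mask, connectivity=8):
        if params.drop_rate > 0 and rng.random() < params.drop_rate:
            continue
        cls_out = comp.cls
        for (src, dst), p in swap_keys:
            if src != comp.cls:
                continue
            if p > 0 and rng.random() < p:
                cls_out = dst
                break
        pixels = comp.pixels
        if params.boundary_jitter > 0:
            dy, dx = rng.integers(-params.boundary_jitter, params.boundary_jitter + 1, size=2)
            pixels = pixels + np.array([dy, dx])
            keep = (
                (pixels[:, 0] >= 0)
                & (pixels[:, 0] < h)
                & (pixels[:, 1] >= 0)
                & (pixels[:, 1] < w)
            )
            pixels = pixels[keep]
            if not len(pixels):
                continue
        _paint_pixels(out, pixels, int(cls_out))
    if params.spurious_rate > 0:
        n_spurious = int(rng.poisson(params.spurious_rate))
        radius = 0.45 * min(h, w)
        cy, cx = h / 2.0, w / 2.0
        for _ in range(n_spurious):
            cls = LESION_CLASSES[int(rng.integers(len(LESION_CLASSES)))]
            diameter = int(rng.integers(3, 9))
            u = rng.random()
            theta = rng.uniform(0, 2 * np.pi)
            rad = (radius - diameter) * np.sqrt(u)
            rr, cc = draw_disk(
                (cy + rad * np.sin(theta), cx + rad * np.cos(theta)),
                max(diameter / 2.0, 1.0),
                shape=(h, w),
            )
            _paint_pixels(out, np.stack([rr, cc], axis=1), int(cls))
    return out


def second_annotator(
    ref: AnnotatedImage, params: CorruptionParams, seed: int
) -> np.ndarray:
    """Simulate an independent second expert's annotation of *ref*."""
    rng = np.random.default_rng([seed, 11])
    return _corrupt_mask(ref.mask, params, rng)


def corrupt_as_model(
    ref: AnnotatedImage, params: CorruptionParams, seed: int
) -> np.ndarray:
    """Simulate an imperfect segmentation-model output for *ref*.

    Uses a seed stream independent from :func:`second_annotator` so the
    two error processes are uncorrelated at the same master seed.
    """
    rng = np.random.default_rng([seed, 23])
    return _corrupt_mask(ref.mask, params, rng)


# ---------------------------------------------------------------------------
# dataset assembly and splitting


@dataclass(frozen=True)
class SplitResult:
    train: tuple[str, ...]
    tune: tuple[str, ...]
    test: tuple[str, ...]
    warning: bool = False

    def subsets(self) -> dict[str, tuple[str, ...]]:
        return {"train": self.train, "tune": self.tune, "test": self.test}


def _target_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items into len(fractions) bins."""
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def split_dataset(
    items: Sequence[AnnotatedImage], spec: SplitSpec, seed: int
) -> SplitResult:
    """Partition images into train/tune/test id lists.

    Honors patient exclusivity (all images of a patient land in one subset)
    and steers the fraction of NV-containing images assigned to training
    toward ``spec.nv_train_fraction``. Infeasible constraints produce a
    best-effort split with ``warning=True``.
    """
    if len(items) < 3:
        raise ValueError("need at least 3 images to split")
    rng = np.random.default_rng(seed)
    has_nv = {
        it.image_id: bool(np.any(it.mask == int(LesionClass.NV))) for it in items
    }
    if spec.patient_exclusive:
        if any(not it.patient_id for it in items):
            raise ValueError("patient_exclusive split requires patient ids")
        groups: dict[str, list[str]] = {}
        for it in items:
            groups.setdefault(it.patient_id, []).append(it.image_id)
        units = [tuple(v) for _, v in sorted(groups.items())]
    else:
        units = [(it.image_id,) for it in items]

    n_images = len(items)
    targets = _target_sizes(n_images, spec.fractions)
    n_nv_total = sum(has_nv.values())
    nv_train_target = int(round(spec.nv_train_fraction * n_nv_total))

    nv_units = [u for u in units if any(has_nv[i] for i in u)]
    other_units = [u for u in units if not any(has_nv[i] for i in u)]
    rng.shuffle(nv_units)
    rng.shuffle(other_units)

    assigned: dict[int, list[str]] = {0: [], 1: [], 2: []}
    nv_in_train = 0
    deferred: list[tuple[str, ...]] = []
    for unit in nv_units:
        unit_nv = sum(has_nv[i] for i in unit)
        if nv_in_train < nv_train_target:
            assigned[0].extend(unit)
            nv_in_train += unit_nv
        else:
            deferred.append(unit)
    # remaining NV units go to tune/test by current deficit
    for unit in deferred:
        deficits = [targets[s] - len(assigned[s]) for s in (1, 2)]
        s = 1 if deficits[0] >= deficits[1] else 2
        assigned[s].extend(unit)
    for unit in other_units:
        deficits = [targets[s] - len(assigned[s]) for s in (0, 1, 2)]
        s = int(np.argmax(deficits))
        assigned[s].extend(unit)

    warning = False
    if n_nv_total and abs(nv_in_train - nv_train_target) > 1:
        warnings.warn(
            f"NV stratification off target: {nv_in_train} NV images in training, "
            f"target {nv_train_target}",
            stacklevel=2,
        )
        warning = True
    if any(len(assigned[s]) == 0 for s in (0, 1, 2)):
        warnings.warn("best-effort split left a subset empty", stacklevel=2)
        warning = True
    return SplitResult(
        train=tuple(assigned[0]),
        tune=tuple(assigned[1]),
        test=tuple(assigned[2]),
        warning=warning,
    )


DEFAULT_GRADE_WEIGHTS: tuple[float, ...] = (0.30, 0.15, 0.25, 0.15, 0.15)


def generate_dataset(
    n_images: int,
    spec: ImageSpec | None = None,
    seed: int = 0,
    grade_weights: Sequence[float] = DEFAULT_GRADE_WEIGHTS,
    images_per_patient: int = 2,
) -> list[AnnotatedImage]:
    """Generate a dataset of annotated images with patient ids and grades.

    Grades are drawn from ``grade_weights``; consecutive images share a
    patient id (``images_per_patient`` each). Per-image seeds are derived
    from the master seed by stable hashing of the image id, so any single
    image can be regenerated in isolation.
    """
    if n_images < 1:
        raise ValueError("n_images must be positive")
    spec = spec or ImageSpec()
    weights = np.asarray(grade_weights, dtype=float)
    if weights.shape != (5,) or (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("grade_weights must be 5 nonnegative values")
    weights = weights / weights.sum()
    master = np.random.default_rng(seed)
    grades = master.choice(5, size=n_images, p=weights)
    out = []
    for i in range(n_images):
        image_id = f"img_{i:04d}"
        patient_id = f"pat_{i // images_per_patient:04d}"
        out.append(
            generate_image(
                spec,
                int(grades[i]),
                _child_seed(seed, image_id),
                image_id=image_id,
                patient_id=patient_id,
            )
        )
    return out
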
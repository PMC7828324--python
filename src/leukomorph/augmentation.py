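"""Class-balancing geometric augmentation of single-cell crops.

Only rotation and flipping are used (photometric edits would alter cell
texture); the balancing plan assigns each source crop the same number of
distinct (angle, flip) transforms, ``k = ceil(target / n)``, so every class
ends up with k·n ≥ target outputs.

Arbitrary-angle rotation leaves out-of-support corners ("black frame").
To avoid any padding in the final fixed-size crop, the source is first
bilinearly enlarged so that the rotated support always contains the central
window: a centered s×s window is frame-free for every angle as soon as the
enlarged side reaches s·√2.  Right-angle rotations and flips are pixel-exact
and need no enlargement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize, rotate as _sk_rotate

__all__ = [
    "TransformPlan",
    "PlanEntry",
    "default_transform_grid",
    "plan_balance",
    "enlarge",
    "rotate",
    "flip",
    "center_crop",
    "augment_class",
]

SQRT2 = math.sqrt(2.0)
FLIPS = ("none", "horizontal", "vertical")
DEFAULT_ANGLES = tuple(range(0, 360, 15))  # 24 angles


@dataclass(frozen=True)
class PlanEntry:
    source_id: str
    angle: float  # degrees, ccw
    flip: str  # none | horizontal | vertical


@dataclass(frozen=True)
class TransformPlan:
    """Deterministic per-class augmentation schedule."""

    per_class: dict[str, tuple[PlanEntry, ...]]
    target_count: int
    transforms_per_source: dict[str, int]
    enlargement_factor: float = SQRT2

    def total(self, wbc_class: str) -> int:
        return len(self.per_class[wbc_class])


def default_transform_grid(
    angles: Sequence[float] = DEFAULT_ANGLES,
    flips: Sequence[str] = ("none", "horizontal"),
) -> list[tuple[float, str]]:
    """Fixed-order (angle, flip) grid, identity first.

    The default grid uses flips {none, horizontal} only: on square crops a
    vertical flip equals a horizontal flip composed with a 180° rotation,
    so including all three flips would duplicate transforms.  24 angles ×
    2 flips = 48 distinct transforms.
    """
    for f in flips:
        if f not in FLIPS:
            raise ValueError(f"unknown flip {f!r}")
    return [(float(a), f) for a in angles for f in flips]


def plan_balance(
    class_counts: Mapping[str, int],
    target_count: int,
    angle_grid: Sequence[float] | None = None,
    flips: Sequence[str] = ("none", "horizontal"),
    enlargement_factor: float = SQRT2,
    source_ids: Mapping[str, Sequence[str]] | None = None,
) -> TransformPlan:
    """Assign ``k = ceil(target / n)`` distinct transforms to every source.

    ``source_ids`` optionally names the per-class source crops; otherwise
    ids ``{class}_{i:05d}`` are generated.  The per-class output count is
    exactly ``k·n``, which lands in [target, target + n).
    """
    if not class_counts:
        raise ValueError("no classes given")
    grid = default_transform_grid(angle_grid or DEFAULT_ANGLES, flips)
    per_class: dict[str, tuple[PlanEntry, ...]] = {}
    k_per: dict[str, int] = {}
    for cls, n in class_counts.items():
        if n < 1:
            raise ValueError(f"class {cls!r} is empty")
        if target_count < n:
            raise ValueError("target_count must be >= every class count")
        k = math.ceil(target_count / n)
        if k > len(grid):
            raise ValueError(
                f"class {cls!r} needs {k} transforms but the grid has {len(grid)}"
            )
        ids = (
            list(source_ids[cls])
            if source_ids is not None
            else [f"{cls}_{i:05d}" for i in range(n)]
        )
        if len(ids) != n:
            raise ValueError("source_ids length must match class count")
        entries = [
            PlanEntry(source_id=sid, angle=a, flip=f)
            for sid in ids
            for a, f in grid[:k]
        ]
        per_class[cls] = tuple(entries)
        k_per[cls] = k
    return TransformPlan(
        per_class=per_class,
        target_count=target_count,
        transforms_per_source=k_per,
        enlargement_factor=enlargement_factor,
    )


def enlarge(image: np.ndarray, factor: float) -> np.ndarray:
    """Bilinear up-scaling; output dims = round(factor · input dims)."""
    if factor < 1:
        raise ValueError("enlargement factor must be >= 1")
    arr = np.asarray(image)
    if factor == 1:
        return arr.copy()
    out_shape = (int(round(factor * arr.shape[0])), int(round(factor * arr.shape[1])))
    out = _sk_resize(
        arr.astype(float), out_shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(arr.dtype)


def rotate(image: np.ndarray, angle_degrees: float, fill_value: int = 0) -> np.ndarray:
    """Rotate ccw about the image center with bilinear resampling.

    Right-angle multiples are handled by exact array transposition (for 90°
    and 270° the canvas dims swap); other angles resample on an expanded
    canvas with out-of-support pixels set to ``fill_value``.
    """
    arr = np.asarray(image)
    a = angle_degrees % 360.0
    if a % 90 == 0:
        return np.ascontiguousarray(np.rot90(arr, k=int(a // 90)))
    out = _sk_rotate(
        arr.astype(float), a, resize=True, order=1, cval=float(fill_value),
        preserve_range=True, mode="constant",
    )
    return np.clip(np.round(out), 0, 255).astype(arr.dtype)


def flip(image: np.ndarray, axis: str) -> np.ndarray:
    """Mirror the image; ``horizontal`` reverses columns, ``vertical`` rows."""
    arr = np.asarray(image)
    if axis == "horizontal":
        return arr[:, ::-1].copy()
    if axis == "vertical":
        return arr[::-1, :].copy()
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def center_crop(image: np.ndarray, side: int = 200) -> np.ndarray:
    """Central side×side window."""
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if h < side or w < side:
        raise ValueError(f"image {h}x{w} smaller than crop side {side}")
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return arr[r0 : r0 + side, c0 : c0 + side].copy()


def apply_transform(
    image: np.ndarray,
    angle: float,
    flip_axis: str,
    crop_side: int = 200,
    enlargement_factor: float = SQRT2,
    fill_value: int = 0,
) -> np.ndarray:
    """enlarge → rotate → flip → center-crop, guaranteed free of fill pixels.

    Right-angle rotations (including the identity) skip the enlargement:
    they create no out-of-support pixels, and skipping keeps those paths
    pixel-exact.  Arbitrary angles enlarge so the rotated support contains
    the central window: at least ``enlargement_factor`` (default √2, the
    geometric minimum) and at least ``(crop_side + 3)·√2 / min_dim`` — the
    3-px guard keeps the crop clear of the one-pixel band at the support
    edge where bilinear resampling blends with the fill value.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    a = angle % 360.0
    if a % 90 == 0:
        factor = max(1.0, crop_side / min(h, w))
        out = arr if factor == 1.0 else enlarge(arr, factor)
        out = rotate(out, a, fill_value)
    else:
        factor = max(enlargement_factor, (crop_side + 3) * SQRT2 / min(h, w))
        out = rotate(enlarge(arr, factor), a, fill_value)
    if flip_axis != "none":
        out = flip(out, flip_axis)
    return center_crop(out, crop_side)


def augment_class(
    crops: Mapping[str, np.ndarray],
    plan: TransformPlan,
    wbc_class: str,
    crop_side: int = 200,
    fill_value: int = 0,
) -> list[tuple[str, np.ndarray, PlanEntry]]:
    """Apply the class's plan; returns (out_id, image, provenance) triples."""
    entries = plan.per_class[wbc_class]
    out = []
    for i, entry in enumerate(entries):
        if entry.source_id not in crops:
            raise KeyError(f"missing source crop {entry.source_id!r}")
        img = apply_transform(
            crops[entry.source_id],
            entry.angle,
            entry.flip,
            crop_side=crop_side,
            enlargement_factor=plan.enlargement_factor,
            fill_value=fill_value,
        )
        out.append((f"{wbc_class}_aug_{i:06d}", img, entry))
    return out
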
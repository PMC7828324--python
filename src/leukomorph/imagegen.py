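"""Seeded synthetic bright-field scene generator with ground truth.

Emulates RBC-depleted bright-field frames of white blood cells at high
magnification: a bright noisy background with darker textured cell blobs,
slightly defocus-blurred.  Inactivated-like cells are rendered as disks,
activated-like granulocytes as elongated curved "worms", monocytes as mild
ellipses.  Every frame carries per-cell ground truth (class, activation,
bounding box, edge-touching and adhesion flags) so segmentation, shape
measurement and classification can all be scored against planted answers.

All randomness flows from one ``numpy.random.Generator`` per call; the same
(spec, seed) pair renders bit-identical frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as _draw_disk, ellipse as _draw_ellipse

__all__ = [
    "CellSpec",
    "SceneSpec",
    "CellRecord",
    "GroundTruth",
    "DatasetConfig",
    "render_scene",
    "cell_footprint",
    "make_dataset",
    "single_cell_crop",
]

WBC_CLASSES = ("granulocyte", "lymphocyte", "monocyte")
SHAPE_KINDS = ("disk", "ellipse", "worm")


@dataclass(frozen=True)
class CellSpec:
    """Geometry and appearance of one planted cell.

    ``major_axis``/``minor_axis`` are full extents in pixels (a disk has
    major == minor == diameter).  ``activation`` is only meaningful for
    granulocytes; other classes carry ``"n/a"``.
    """

    center: tuple[float, float]  # (row, col)
    shape_kind: str
    major_axis: float
    minor_axis: float
    orientation: float = 0.0  # radians, ccw from the column axis
    mean_intensity: float = 120.0
    texture_sd: float = 8.0
    wbc_class: str = "granulocyte"
    activation: str = "n/a"

    def __post_init__(self) -> None:
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.wbc_class not in WBC_CLASSES:
            raise ValueError(f"unknown wbc_class {self.wbc_class!r}")
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("need major_axis >= minor_axis > 0")
        if self.shape_kind == "disk" and self.major_axis != self.minor_axis:
            raise ValueError("a disk must have major_axis == minor_axis")
        if self.activation != "n/a" and self.wbc_class != "granulocyte":
            raise ValueError("activation only applies to granulocytes")
        if self.activation not in ("activated", "inactivated", "n/a"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class SceneSpec:
    """One frame to render: canvas, background statistics and cell list."""

    frame_height: int = 512
    frame_width: int = 512
    background_mean: float = 200.0
    background_sd: float = 5.0
    cells: tuple[CellSpec, ...] = ()
    seed: int = 0
    blur_sigma: float = 1.0  # defocus emulation

    def __post_init__(self) -> None:
        if self.frame_height <= 0 or self.frame_width <= 0:
            raise ValueError("frame dimensions must be positive")
        object.__setattr__(self, "cells", tuple(self.cells))


@dataclass(frozen=True)
class CellRecord:
    """Ground truth for one rendered cell."""

    spec: CellSpec
    bbox: tuple[int, int, int, int]  # half-open (row_min, col_min, row_max, col_max)
    touches_edge: bool
    adhered_group_id: int | None


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellRecord, ...]

    def __len__(self) -> int:
        return len(self.cells)


def _worm_footprint(
    shape: tuple[int, int], cell: CellSpec, n_samples: int = 48
) -> np.ndarray:
    """Curved capsule chain: disks of radius minor/2 stamped along a bowed
    centerline of end-to-end length major − minor (so the overall extent,
    caps included, is about major)."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    radius = cell.minor_axis / 2.0
    length = max(cell.major_axis - cell.minor_axis, 1.0)
    amp = 0.35 * cell.minor_axis  # mild bow; keeps the long axis dominant
    u = np.array([math.sin(cell.orientation), math.cos(cell.orientation)])
    v = np.array([math.cos(cell.orientation), -math.sin(cell.orientation)])
    for t in np.linspace(-0.5, 0.5, n_samples):
        p = (
            np.array(cell.center)
            + t * length * u
            + amp * math.sin(math.pi * t) * v
        )
        rr, cc = _draw_disk((p[0], p[1]), radius, shape=shape)
        out[rr, cc] = True
    return out


def cell_footprint(cell: CellSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean rendered footprint of one cell on an empty canvas.

    Public so that tests and ground-truth audits can recompute overlaps and
    edge contact from first principles.
    """
    if cell.shape_kind == "disk":
        out = np.zeros(shape, dtype=bool)
        rr, cc = _draw_disk(cell.center, cell.major_axis / 2.0, shape=shape)
        out[rr, cc] = True
        return out
    if cell.shape_kind == "ellipse":
        out = np.zeros(shape, dtype=bool)
        rr, cc = _draw_ellipse(
            cell.center[0],
            cell.center[1],
            cell.minor_axis / 2.0,
            cell.major_axis / 2.0,
            shape=shape,
            rotation=cell.orientation,
        )
        out[rr, cc] = True
        return out
    return _worm_footprint(shape, cell)


def _adhesion_groups(footprints: list[np.ndarray]) -> list[int | None]:
    """Union-find over pairwise footprint overlaps → group ids (None if alone)."""
    n = len(footprints)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.any(footprints[i] & footprints[j]):
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    sizes: dict[int, int] = {}
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    group_ids: dict[int, int] = {}
    out: list[int | None] = []
    for r in roots:
        if sizes[r] < 2:
            out.append(None)
        else:
            out.append(group_ids.setdefault(r, len(group_ids)))
    return out


def _bbox_of(footprint: np.ndarray) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(footprint)
    return (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one 8-bit frame and its ground truth.

    Background pixels ~ N(background_mean, background_sd²); each cell's
    footprint ~ N(mean_intensity, texture_sd²); the whole frame gets a
    Gaussian defocus blur, then is clipped to 0..255 and quantized.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_height, spec.frame_width
    img = rng.normal(spec.background_mean, spec.background_sd, size=(h, w))

    footprints: list[np.ndarray] = []
    for cell in spec.cells:
        fp = cell_footprint(cell, (h, w))
        if not fp.any():
            raise ValueError(f"cell at {cell.center} renders no pixels in frame")
        img[fp] = rng.normal(cell.mean_intensity, cell.texture_sd, size=int(fp.sum()))
        footprints.append(fp)

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma)
    frame = np.clip(np.round(img), 0, 255).astype(np.uint8)

    groups = _adhesion_groups(footprints)
    records = []
    for cell, fp, gid in zip(spec.cells, footprints, groups):
        rows, cols = np.nonzero(fp)
        touches = bool(
            rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
        )
        records.append(
            CellRecord(spec=cell, bbox=_bbox_of(fp), touches_edge=touches, adhered_group_id=gid)
        )
    return frame, GroundTruth(cells=tuple(records))


# ---------------------------------------------------------------------------
# dataset factory

#: default per-class morphology and appearance (pixel units, 8-bit levels):
#: granulocytes mid-sized, lymphocytes small, monocytes large and mildly
#: elliptical; activated granulocytes are 3:1 elongated worms.
CLASS_GEOMETRY = {
    "granulocyte": {"diameter": (48.0, 64.0)},
    "lymphocyte": {"diameter": (28.0, 40.0)},
    "monocyte": {"diameter": (72.0, 92.0), "ellipticity": (1.05, 1.15)},
}
WORM_ELONGATION = 3.0


@dataclass(frozen=True)
class DatasetConfig:
    """Study conditions for a synthetic dataset.

    ``class_counts`` plants that many cells per WBC class across frames;
    ``activated_fraction`` of granulocytes become worms (deterministic count,
    rounded to nearest).  ``edge_cells`` and ``adhered_pairs`` plant extra
    screening challenges and are excluded from the per-class counts' clean
    bookkeeping only in the sense that they are flagged in the manifest.
    """

    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {"granulocyte": 10, "lymphocyte": 5, "monocyte": 5}
    )
    activated_fraction: float = 0.25
    cells_per_frame: int = 8
    frame_height: int = 512
    frame_width: int = 512
    background_mean: float = 200.0
    background_sd: float = 5.0
    cell_intensity: tuple[float, float] = (110.0, 130.0)  # per-cell mean range
    texture_sd: float = 8.0
    blur_sigma: float = 1.0
    edge_cells: int = 0
    adhered_pairs: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_intensity", tuple(self.cell_intensity))
        for cls, n in self.class_counts.items():
            if cls not in WBC_CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError("counts must be >= 0")
        if not 0.0 <= self.activated_fraction <= 1.0:
            raise ValueError("activated_fraction must be in [0, 1]")


def _draw_cell_spec(
    cls: str, activation: str, rng: np.random.Generator, cfg: DatasetConfig
) -> CellSpec:
    """Sample one cell's geometry/appearance (center placed later)."""
    geo = CLASS_GEOMETRY[cls]
    d = rng.uniform(*geo["diameter"])
    mean_i = rng.uniform(*cfg.cell_intensity)
    orient = rng.uniform(0, np.pi)
    common = dict(
        center=(0.0, 0.0),
        mean_intensity=mean_i,
        texture_sd=cfg.texture_sd,
        wbc_class=cls,
        orientation=orient,
    )
    if cls == "granulocyte":
        if activation == "activated":
            return CellSpec(
                shape_kind="worm",
                major_axis=d * WORM_ELONGATION / 1.5,
                minor_axis=d / 1.5,
                activation="activated",
                **common,
            )
        return CellSpec(
            shape_kind="disk", major_axis=d, minor_axis=d,
            activation="inactivated", **common,
        )
    if cls == "monocyte":
        ecc = rng.uniform(*geo["ellipticity"])
        return CellSpec(shape_kind="ellipse", major_axis=d, minor_axis=d / ecc, **common)
    return CellSpec(shape_kind="disk", major_axis=d, minor_axis=d, **common)


def _place_cells(
    specs: list[CellSpec],
    rng: np.random.Generator,
    cfg: DatasetConfig,
    n_edge: int,
    n_adhered_pairs: int,
) -> list[CellSpec]:
    """Assign centers: interior non-overlapping by default; the first
    ``n_edge`` cells straddle the border and the next ``2*n_adhered_pairs``
    are placed as overlapping pairs."""
    h, w = cfg.frame_height, cfg.frame_width
    placed: list[CellSpec] = []
    occupied: list[tuple[float, float, float]] = []  # (row, col, radius)

    def radius(s: CellSpec) -> float:
        return s.major_axis / 2.0 + 0.35 * s.minor_axis

    def try_place(s: CellSpec, lo_r, hi_r, lo_c, hi_c, min_clear=6.0) -> CellSpec | None:
        for _ in range(1000):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all(
                math.hypot(r - orow, c - ocol) >= radius(s) + orad + min_clear
                for orow, ocol, orad in occupied
            ):
                out = replace(s, center=(r, c))
                occupied.append((r, c, radius(s)))
                return out
        raise RuntimeError("could not place cell without overlap; frame too crowded")

    i = 0
    for _ in range(n_edge):
        s = specs[i]
        # center just inside the border so the footprint crosses it
        side = rng.integers(4)
        m = s.major_axis * 0.25
        if side == 0:
            out = try_place(s, 1.0, m, m, w - m)
        elif side == 1:
            out = try_place(s, h - m, h - 2.0, m, w - m)
        elif side == 2:
            out = try_place(s, m, h - m, 1.0, m)
        else:
            out = try_place(s, m, h - m, w - m, w - 2.0)
        placed.append(out)
        i += 1
    for _ in range(n_adhered_pairs):
        a, b = specs[i], specs[i + 1]
        margin = max(radius(a), radius(b)) + 4
        pa = try_place(a, margin, h - margin, margin, w - margin)
        # partner offset 90% of the sum of radii: footprints overlap with a
        # pinched waist, like touching cells, rather than interpenetrating
        ang = rng.uniform(0, 2 * np.pi)
        dist = 0.9 * (a.major_axis / 2 + b.major_axis / 2)
        pb = replace(
            b,
            center=(pa.center[0] + dist * math.sin(ang), pa.center[1] + dist * math.cos(ang)),
        )
        occupied.append((pb.center[0], pb.center[1], radius(b)))
        placed.extend([pa, pb])
        i += 2
    for s in specs[i:]:
        margin = radius(s) + 2
        placed.append(try_place(s, margin, h - margin, margin, w - margin))
    return placed


MANIFEST_COLUMNS = [
    "frame_id",
    "cell_id",
    "row_min",
    "col_min",
    "row_max",
    "col_max",
    "wbc_class",
    "activation",
    "touches_edge",
    "adhered_group",
]


def make_dataset(
    config: DatasetConfig, out_dir: str | Path | None, seed: int
) -> tuple[list[tuple[np.ndarray, GroundTruth]], pd.DataFrame]:
    """Render a multi-frame dataset and its manifest.

    Returns the rendered ``(frame, ground_truth)`` pairs and a manifest
    DataFrame (one row per planted cell).  When ``out_dir`` is given, frames
    are written as ``frame_####.png`` and the manifest as ``manifest.csv``.
    """
    rng = np.random.default_rng(seed)
    cfg = config

    specs: list[CellSpec] = []
    n_gran = cfg.class_counts.get("granulocyte", 0)
    n_act = int(round(cfg.activated_fraction * n_gran))
    specs += [_draw_cell_spec("granulocyte", "activated", rng, cfg) for _ in range(n_act)]
    specs += [
        _draw_cell_spec("granulocyte", "inactivated", rng, cfg)
        for _ in range(n_gran - n_act)
    ]
    for cls in ("lymphocyte", "monocyte"):
        specs += [
            _draw_cell_spec(cls, "n/a", rng, cfg)
            for _ in range(cfg.class_counts.get(cls, 0))
        ]
    extra = [
        _draw_cell_spec("granulocyte", "inactivated", rng, cfg)
        for _ in range(cfg.edge_cells + 2 * cfg.adhered_pairs)
    ]
    # Deal the clean cells round-robin across frames so large (worm) cells
    # spread evenly and every frame stays placeable; edge/adhered challenge
    # cells all go in a dedicated leading frame.
    frames: list[tuple[np.ndarray, GroundTruth]] = []
    rows = []
    chunks: list[tuple[int, int, list[CellSpec]]] = []
    if extra:
        chunks.append((cfg.edge_cells, cfg.adhered_pairs, extra))
    n_frames = max(1, math.ceil(len(specs) / cfg.cells_per_frame)) if specs else 0
    clean_chunks: list[list[CellSpec]] = [[] for _ in range(n_frames)]
    for k, s in enumerate(specs):
        clean_chunks[k % n_frames].append(s)
    chunks.extend((0, 0, chunk) for chunk in clean_chunks if chunk)

    for frame_idx, (n_edge, n_pairs, chunk) in enumerate(chunks):
        placed = _place_cells(list(chunk), rng, cfg, n_edge, n_pairs)
        scene = SceneSpec(
            frame_height=cfg.frame_height,
            frame_width=cfg.frame_width,
            background_mean=cfg.background_mean,
            background_sd=cfg.background_sd,
            cells=tuple(placed),
            seed=int(rng.integers(2**31 - 1)),
            blur_sigma=cfg.blur_sigma,
        )
        frame, gt = render_scene(scene)
        frame_id = f"frame_{frame_idx:04d}"
        frames.append((frame, gt))
        for cell_id, rec in enumerate(gt.cells):
            rows.append(
                {
                    "frame_id": frame_id,
                    "cell_id": cell_id,
                    "row_min": rec.bbox[0],
                    "col_min": rec.bbox[1],
                    "row_max": rec.bbox[2],
                    "col_max": rec.bbox[3],
                    "wbc_class": rec.spec.wbc_class,
                    "activation": rec.spec.activation,
                    "touches_edge": rec.touches_edge,
                    "adhered_group": "" if rec.adhered_group_id is None else rec.adhered_group_id,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for frame_idx, (frame, _) in enumerate(frames):
            iio.imwrite(out / f"frame_{frame_idx:04d}.png", frame)
        manifest.to_csv(out / "manifest.csv", index=False)
    return frames, manifest


def single_cell_crop(
    cell: CellSpec,
    seed: int,
    pad: int = 20,
    background_mean: float = 200.0,
    background_sd: float = 5.0,
    blur_sigma: float = 1.0,
) -> np.ndarray:
    """Render one cell centered in a tight crop — handy for shape-measurement
    tests with known planted geometry."""
    side = int(math.ceil(cell.major_axis)) + 2 * pad
    centered = replace(cell, center=(side / 2.0, side / 2.0))
    scene = SceneSpec(
        frame_height=side,
        frame_width=side,
        background_mean=background_mean,
        background_sd=background_sd,
        cells=(centered,),
        seed=seed,
        blur_sigma=blur_sigma,
    )
    frame, _ = render_scene(scene)
    return frame
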
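"""Threshold segmentation and single-cell cropping from bright-field frames.

The stage turns an 8-bit grayscale frame into screened single-cell crops:

1. Otsu adaptive threshold — the gray level maximizing the between-class
   variance ``ω1·ω2·(μ1−μ2)²`` over the 256-bin histogram.
2. Binarization with a configurable foreground polarity (bright-field WBCs
   are usually darker than the illuminated background).
3. Morphological opening then closing to clean speckle and close gaps.
4. Chain-code contour extraction per 8-connected component, with polygonal
   perimeter (diagonal steps weighted √2).
5. Screening: edge-touching contours, out-of-range areas and suspected
   cell adhesions (low solidity or oversized blobs) are rejected; each
   survivor yields one square crop centered on its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "OtsuStats",
    "Contour",
    "CellCrop",
    "ScreeningParams",
    "DegenerateImageError",
    "otsu_threshold",
    "binarize",
    "refine_mask",
    "extract_contours",
    "screen_and_crop",
    "segment_frame",
]

SQRT2 = float(np.sqrt(2.0))

#: 8-neighbour offsets in clockwise order starting North, used by the
#: Moore boundary tracer.
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=int,
)

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


class DegenerateImageError(ValueError):
    """Raised when an image has a single gray level and no threshold exists."""


@dataclass(frozen=True)
class OtsuStats:
    """Optimal threshold and the class statistics at the optimum.

    ``g`` splits the histogram into a low class (levels ≤ g, proportion
    ``omega1``, mean ``mu1``) and a high class (levels > g, proportion
    ``omega2``, mean ``mu2``); which side is "cell" depends on the imaging
    polarity and is chosen at :func:`binarize` time.  ``variance`` is
    ω1·ω2·(μ1−μ2)² at ``g``.
    """

    g: int
    omega1: float
    omega2: float
    mu1: float
    mu2: float
    variance: float


@dataclass(frozen=True)
class Contour:
    """Closed 8-connected boundary of one foreground component.

    ``vertices`` are ordered (row, col) boundary pixels; ``area_px`` is the
    enclosed pixel count (component size, holes filled not included);
    ``perimeter_px`` the chain length with diagonal steps weighted √2.
    """

    vertices: np.ndarray
    area_px: int
    perimeter_px: float
    bbox: tuple[int, int, int, int]  # half-open (row_min, col_min, row_max, col_max)
    centroid: tuple[float, float]
    solidity: float


@dataclass(frozen=True)
class CellCrop:
    """Square single-cell crop plus provenance."""

    image: np.ndarray
    source_frame_id: str
    cell_id: int
    bbox: tuple[int, int, int, int]
    wbc_class: str | None = None
    contour: Contour | None = None


@dataclass(frozen=True)
class ScreeningParams:
    """Screening and crop-geometry knobs.

    min/max area bound plausible single-cell footprints at 100× scale; the
    area ceiling doubles as the main adhesion catch when set just above the
    largest plausible single cell (merged pairs are ~2× that).
    ``solidity_min`` rejects merged blobs with a visibly pinched waist; note
    two equal overlapping disks bottom out near solidity 0.88, so the floor
    alone cannot catch same-size pairs.  ``edge_margin`` treats contours
    whose bbox comes within that many pixels of the border as edge-touchers
    (defocus blur can shave the outermost mask pixel off a cell that truly
    crosses the frame edge).  ``margin`` pads the square crop.
    """

    min_area: int = 200
    max_area: int = 20_000
    solidity_min: float = 0.85
    edge_margin: int = 2
    margin: int = 10


def _validate_gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a nonempty 2D grayscale image")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("gray levels must lie in 0..255")
        arr = arr.astype(np.uint8)
    return arr


def otsu_threshold(image: np.ndarray) -> OtsuStats:
    """Between-class-variance-maximizing threshold of an 8-bit image.

    Evaluates every candidate threshold t in 0..254 (background = levels
    ≤ t) and returns the argmax of ω1·ω2·(μ1−μ2)², ties broken toward the
    lowest gray level.

    Raises
    ------
    DegenerateImageError
        if the image is constant (no two classes to separate).
    """
    arr = _validate_gray(image)
    hist = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image has no Otsu threshold")

    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w1 = np.cumsum(p)[:255]                      # P(level <= t), t = 0..254
    s1 = np.cumsum(p * levels)[:255]             # sum of level*p up to t
    total_mean = float(np.sum(p * levels))
    w2 = 1.0 - w1

    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = np.where(w1 > 0, s1 / w1, 0.0)
        mu2 = np.where(w2 > 0, (total_mean - s1) / w2, 0.0)
        var = w1 * w2 * (mu1 - mu2) ** 2
    var = np.where((w1 > 0) & (w2 > 0), var, -np.inf)

    g = int(np.argmax(var))  # first occurrence == lowest gray level on ties
    return OtsuStats(
        g=g,
        omega1=float(w1[g]),
        omega2=float(w2[g]),
        mu1=float(mu1[g]),
        mu2=float(mu2[g]),
        variance=float(var[g]),
    )


def binarize(
    image: np.ndarray, stats: OtsuStats, foreground: str = "dark"
) -> np.ndarray:
    """Split pixels at ``stats.g``; ``foreground`` picks which side is cell.

    ``"bright"`` marks pixels strictly above g as foreground, ``"dark"``
    the complement (bright-field cells are darker than the background).
    """
    arr = _validate_gray(image)
    above = arr > stats.g
    if foreground == "bright":
        return above
    if foreground == "dark":
        return ~above
    raise ValueError(f"foreground must be 'bright' or 'dark', got {foreground!r}")


def _square(radius: int) -> np.ndarray:
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def refine_mask(
    mask: np.ndarray, opening_radius: int = 1, closing_radius: int = 1
) -> np.ndarray:
    """Morphological opening then closing with square structuring elements."""
    if opening_radius < 0 or closing_radius < 0:
        raise ValueError("radii must be >= 0")
    out = np.asarray(mask, dtype=bool)
    if opening_radius > 0:
        out = ndimage.binary_opening(out, structure=_square(opening_radius))
    if closing_radius > 0:
        out = ndimage.binary_closing(out, structure=_square(closing_radius))
    return out


_DIR_INDEX = {tuple(v): i for i, v in enumerate(_MOORE)}


def _trace_boundary(component: np.ndarray) -> np.ndarray:
    """Moore-neighbour trace of one 8-connected component.

    Returns ordered (row, col) boundary pixels; the chain is closed (last
    vertex is 8-adjacent to the first).  Thin structures are traversed on
    both sides, so their pixels appear twice — the chain perimeter then
    counts both walls, as a polygonal boundary should.  A single-pixel
    component yields a one-vertex chain.
    """
    rows, cols = np.nonzero(component)
    if rows.size == 0:
        raise ValueError("empty component")
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    if rows.size == 1:
        return np.array([start], dtype=int)

    h, w = component.shape

    def is_fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(component[r, c])

    # The West neighbour of the topmost-leftmost pixel is background; use it
    # as the initial backtrack.  Terminate when a (pixel, backtrack) state
    # repeats — the walk is deterministic, so that closes the cycle.
    boundary: list[tuple[int, int]] = []
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    cur = start
    backtrack = (start[0], start[1] - 1)
    while (cur, backtrack) not in seen:
        seen.add((cur, backtrack))
        boundary.append(cur)
        d0 = _DIR_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        for k in range(1, 9):
            d = (d0 + k) % 8
            cand = (cur[0] + int(_MOORE[d][0]), cur[1] + int(_MOORE[d][1]))
            if is_fg(*cand):
                dprev = (d0 + k - 1) % 8
                backtrack = (
                    cur[0] + int(_MOORE[dprev][0]),
                    cur[1] + int(_MOORE[dprev][1]),
                )
                cur = cand
                break
        else:  # no foreground neighbour: isolated pixel (size-1 handled above)
            break
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary = boundary[:-1]
    return np.array(boundary, dtype=int)


def _chain_perimeter(vertices: np.ndarray) -> float:
    """Polygonal length of a closed chain; √2 per diagonal step."""
    if len(vertices) == 1:
        return 1.0  # convention for a single-pixel component
    closed = np.vstack([vertices, vertices[:1]])
    steps = np.abs(np.diff(closed, axis=0))
    diag = np.all(steps == 1, axis=1)
    straight = steps.sum(axis=1) == 1
    return float(np.sum(straight) + SQRT2 * np.sum(diag))


def _solidity(component: np.ndarray, vertices: np.ndarray, area: int) -> float:
    """area / convex-hull-area over pixel footprints (hull of pixel centers,
    +0.5 px dilation via the shoelace on centers plus the boundary length
    correction is overkill; convex_hull_image counts hull pixels)."""
    if area < 3:
        return 1.0
    try:
        hull = ConvexHull(vertices.astype(float))
    except QhullError:
        return 1.0  # collinear component: treat as solid
    # pixel-count hull area: rasterize hull over the component's bbox
    pts = vertices[hull.vertices]
    rr, cc = _draw_polygon(pts[:, 0], pts[:, 1], shape=component.shape)
    hull_px = max(len(rr), area)
    return float(area / hull_px)


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """One contour per 8-connected foreground component of ``mask``."""
    m = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(m, structure=_EIGHT)
    contours: list[Contour] = []
    slices = ndimage.find_objects(labeled)
    for i, sl in enumerate(slices, start=1):
        comp_local = labeled[sl] == i
        area = int(comp_local.sum())
        verts_local = _trace_boundary(comp_local)
        offset = np.array([sl[0].start, sl[1].start])
        verts = verts_local + offset
        perim = _chain_perimeter(verts_local)
        r, c = np.nonzero(comp_local)
        centroid = (
            float(r.mean() + sl[0].start),
            float(c.mean() + sl[1].start),
        )
        bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        sol = _solidity(comp_local, verts_local, area)
        contours.append(
            Contour(
                vertices=verts,
                area_px=area,
                perimeter_px=perim,
                bbox=bbox,
                centroid=centroid,
                solidity=sol,
            )
        )
    return contours


def _reject_reason(
    contour: Contour, frame_shape: tuple[int, int], params: ScreeningParams
) -> str | None:
    r0, c0, r1, c1 = contour.bbox
    h, w = frame_shape
    m = params.edge_margin
    if r0 <= m or c0 <= m or r1 >= h - m or c1 >= w - m:
        return "edge"
    if contour.area_px < params.min_area:
        return "too_small"
    if contour.area_px > params.max_area:
        return "adhesion_or_too_large"
    if contour.solidity < params.solidity_min:
        return "adhesion"
    return None


def screen_and_crop(
    image: np.ndarray,
    contours: Sequence[Contour],
    params: ScreeningParams | None = None,
    frame_id: str = "frame",
) -> tuple[list[CellCrop], pd.DataFrame]:
    """Screen contours and cut one square crop per accepted cell.

    Rejections (edge-touching bbox, area out of [min_area, max_area],
    low-solidity adhesion suspects) are recorded in the returned index
    table with a ``rejected_reason``; accepted rows have an empty reason.
    Crop side = max bbox side + 2·margin, centered on the centroid and
    clamped inside the frame.
    """
    arr = _validate_gray(image)
    params = params or ScreeningParams()
    h, w = arr.shape
    crops: list[CellCrop] = []
    rows = []
    for cell_id, ct in enumerate(contours):
        reason = _reject_reason(ct, (h, w), params)
        r0, c0, r1, c1 = ct.bbox
        if reason is None:
            side = max(r1 - r0, c1 - c0) + 2 * params.margin
            side = min(side, h, w)
            cr = int(round(ct.centroid[0] - side / 2))
            cc_ = int(round(ct.centroid[1] - side / 2))
            cr = min(max(cr, 0), h - side)
            cc_ = min(max(cc_, 0), w - side)
            bbox = (cr, cc_, cr + side, cc_ + side)
            crops.append(
                CellCrop(
                    image=arr[cr : cr + side, cc_ : cc_ + side].copy(),
                    source_frame_id=frame_id,
                    cell_id=cell_id,
                    bbox=bbox,
                    contour=ct,
                )
            )
        rows.append(
            {
                "frame_id": frame_id,
                "cell_id": cell_id,
                "row_min": r0,
                "col_min": c0,
                "row_max": r1,
                "col_max": c1,
                "area_px": ct.area_px,
                "perimeter_px": ct.perimeter_px,
                "rejected_reason": reason or "",
            }
        )
    index = pd.DataFrame(
        rows,
        columns=[
            "frame_id",
            "cell_id",
            "row_min",
            "col_min",
            "row_max",
            "col_max",
            "area_px",
            "perimeter_px",
            "rejected_reason",
        ],
    )
    return crops, index


def segment_frame(
    image: np.ndarray,
    params: ScreeningParams | None = None,
    foreground: str = "dark",
    opening_radius: int = 1,
    closing_radius: int = 1,
    frame_id: str = "frame",
) -> tuple[list[CellCrop], pd.DataFrame]:
    """Full per-frame pipeline: Otsu → binarize → open/close → contours → crops."""
    stats = otsu_threshold(image)
    mask = binarize(image, stats, foreground=foreground)
    mask = refine_mask(mask, opening_radius, closing_radius)
    contours = extract_contours(mask)
    return screen_and_crop(image, contours, params, frame_id=frame_id)


def save_crops(
    crops: Sequence[CellCrop], index: pd.DataFrame, out_dir: str | Path
) -> None:
    """Write crops as ``{frame_id}_{cell_id}.png`` plus the index CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for crop in crops:
        iio.imwrite(out / f"{crop.source_frame_id}_{crop.cell_id}.png", crop.image)
    index.to_csv(out / "crop_index.csv", index=False)
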
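"""Connected organelle objects, boundary contours, lengths and areas.

Objects are maximal connected components of one class (8-connectivity by
default, matching contour-following practice).  Each object's external
boundary is traced with the Moore-neighbor algorithm (Jacob's stopping
criterion), yielding an ordered, closed, clockwise sequence of boundary
pixel coordinates starting from the object's top-left-most pixel.  Internal
holes are ignored: one contour per organelle.

Lengths are polyline arc lengths through pixel centers (steps of 1 or √2
pixels) scaled by the calibration; areas are either pixel counts or the
shoelace area of the boundary polygon, both in nm².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal

import numpy as np
from scipy import ndimage

from .mask_io import Calibration, LabelMask

__all__ = [
    "ObjectRegion",
    "Contour",
    "label_objects",
    "trace_contour",
    "contour_arc_length",
    "region_area",
]

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)

# Clockwise compass directions in image coordinates (row grows downward):
# N, NE, E, SE, S, SW, W, NW.
_CW = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=int,
)
_DIR_INDEX = {(int(dr), int(dc)): i for i, (dr, dc) in enumerate(_CW)}
_W = 6  # index of the west direction


@dataclass
class ObjectRegion:
    """One connected organelle object of a single class."""

    class_id: int
    object_id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col) coordinates

    def __post_init__(self) -> None:
        pts = np.asarray(self.pixels, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("pixels must be a non-empty (n, 2) coordinate array")
        self.pixels = pts

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.shape[0])

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(rmin, cmin, rmax, cmax), inclusive."""
        rmin, cmin = self.pixels.min(axis=0)
        rmax, cmax = self.pixels.max(axis=0)
        return int(rmin), int(cmin), int(rmax), int(cmax)


@dataclass
class Contour:
    """Ordered external boundary of one object.

    ``points`` are distinct (row, col) boundary pixel coordinates in
    clockwise traversal order, starting at the top-left-most boundary pixel.
    When ``closed``, the step from the last point back to the first belongs
    to the polyline.
    """

    object_ref: tuple[int, int]  # (class_id, object_id)
    points: np.ndarray  # (n, 2) int array
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("contour needs at least one (row, col) point")
        self.points = pts

    def __len__(self) -> int:
        return int(self.points.shape[0])


def label_objects(
    mask: LabelMask,
    class_id: int,
    connectivity: Literal[4, 8] = 8,
    min_area_px: int = 0,
) -> List[ObjectRegion]:
    """Find connected components of one organelle class.

    Components are ordered deterministically by their top-left-most pixel in
    row-major order and numbered 1..n after dropping components smaller than
    ``min_area_px``.
    """
    if class_id not in (1, 2):
        raise ValueError(f"class_id must be 1 (mitochondria) or 2 (ER), got {class_id}")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    binary = mask.labels == class_id
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    lbl, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return []
    flat = lbl.ravel()
    # First row-major occurrence of each label defines the ordering.
    labels_present, first_idx = np.unique(flat, return_index=True)
    order = [
        (idx, lab)
        for lab, idx in zip(labels_present, first_idx)
        if lab != 0
    ]
    order.sort()
    regions: List[ObjectRegion] = []
    for _, lab in order:
        pts = np.argwhere(lbl == lab)
        if pts.shape[0] < min_area_px:
            continue
        regions.append(ObjectRegion(class_id=class_id, object_id=len(regions) + 1, pixels=pts))
    return regions


def _moore_trace(filled: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Clockwise Moore-neighbor boundary trace on a padded boolean array.

    ``start`` must be the first foreground pixel in row-major order, so its
    west neighbor is guaranteed background.  Terminates when the start pixel
    is re-entered from the same backtrack direction (Jacob's criterion).
    """
    path: list[tuple[int, int]] = []
    cur = start
    back = _W
    start_state = (start, _W)
    limit = 4 * int(filled.sum()) + 8
    for _ in range(limit):
        path.append(cur)
        for k in range(1, 9):
            j = (back + k) % 8
            nb = (cur[0] + _CW[j][0], cur[1] + _CW[j][1])
            if filled[nb]:
                jm = (j - 1) % 8
                prev_checked = (cur[0] + _CW[jm][0], cur[1] + _CW[jm][1])
                cur = nb
                back = _DIR_INDEX[
                    (prev_checked[0] - nb[0], prev_checked[1] - nb[1])
                ]
                break
        else:
            return path  # isolated single pixel
        if (cur, back) == start_state:
            return path
    return path  # pragma: no cover - safety bound


def trace_contour(region: ObjectRegion) -> Contour:
    """Trace the external boundary contour of one object.

    Holes inside the object are filled before tracing so exactly one closed
    contour per organelle results.  For 1-pixel-thick parts the trace passes
    out and back; the returned point list keeps each boundary pixel once, in
    first-visit order.
    """
    rmin, cmin, rmax, cmax = region.bounding_box()
    h = rmax - rmin + 3
    w = cmax - cmin + 3
    local = np.zeros((h, w), dtype=bool)
    local[region.pixels[:, 0] - rmin + 1, region.pixels[:, 1] - cmin + 1] = True
    local = ndimage.binary_fill_holes(local)
    start_flat = int(np.flatnonzero(local.ravel())[0])
    start = (start_flat // w, start_flat % w)
    raw = _moore_trace(local, start)
    seen: set[tuple[int, int]] = set()
    pts: list[tuple[int, int]] = []
    for p in raw:
        if p not in seen:
            seen.add(p)
            pts.append((p[0] + rmin - 1, p[1] + cmin - 1))
    return Contour(
        object_ref=(region.class_id, region.object_id),
        points=np.asarray(pts, dtype=int),
        closed=True,
    )


def contour_arc_length(contour: Contour, calibration: Calibration) -> float:
    """Polyline arc length of a contour in nm.

    Sum of Euclidean distances between consecutive points, including the
    closing step for closed contours; a single-point contour has length 0.
    """
    pts = contour.points.astype(float)
    n = pts.shape[0]
    if n < 2:
        return 0.0
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(steps.sum())
    if contour.closed:
        total += float(np.linalg.norm(pts[-1] - pts[0]))
    return total * calibration.pixel_size_nm


def region_area(
    region: ObjectRegion,
    calibration: Calibration,
    mode: Literal["pixel_count", "polygon"] = "pixel_count",
) -> float:
    """Object area in nm².

    ``pixel_count`` multiplies the number of object pixels by the pixel
    area; ``polygon`` is the shoelace area of the closed boundary polygon
    through pixel centers.  Pixel-count area is never smaller than polygon
    area for filled regions.
    """
    if mode == "pixel_count":
        return region.n_pixels * calibration.pixel_area_nm2
    if mode == "polygon":
        pts = trace_contour(region).points.astype(float)
        if pts.shape[0] < 3:
            return 0.0
        x = pts[:, 1]
        y = pts[:, 0]
        area_px = 0.5 * abs(
            float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        )
        return area_px * calibration.pixel_area_nm2
    raise ValueError(f"unknown area mode {mode!r}; expected 'pixel_count' or 'polygon'")
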
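"""Mitochondria–ER contact site (MERC) detection and per-image summaries.

A MERC is a maximal continuous run of mitochondrial contour pixels lying
within a distance threshold of the ER contour.  Two operational types are
distinguished, following the electron-microscopy literature on inter-membrane
spacing: *close* (first-type) contacts at distances below 15 nm, and *loose*
(second-type) contacts at 15–80 nm.  Distances are Euclidean, between pixel
centers of the mitochondrial contour and the nearest ER contour pixel,
computed in nm via an exact Euclidean distance transform seeded at ER
contour pixels — the nm threshold is the operative comparison; any pixel
equivalent (e.g. 80 nm = 211 px at 0.38 nm/px) is a derived convenience.

Per image the detector reports object counts and areas plus the four MERC
characteristics N_C1, L_C1 (count and total contour length of close
contacts) and N_C2, L_C2 (same for loose contacts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .contours import (
    Contour,
    ObjectRegion,
    contour_arc_length,
    label_objects,
    region_area,
    trace_contour,
)
from .mask_io import CLASS_ER, CLASS_MITOCHONDRIA, Calibration, LabelMask

__all__ = [
    "MercParams",
    "DistanceField",
    "ContactSegment",
    "MercReport",
    "CONTACT_NONE",
    "CONTACT_CLOSE",
    "CONTACT_LOOSE",
    "nm_to_px",
    "er_contour_pixels",
    "er_contour_distance_field",
    "classify_contact_pixels",
    "group_contacts",
    "analyze_mask",
    "summarize_mercs",
]

# Per-pixel contact labels.
CONTACT_NONE = 0
CONTACT_CLOSE = 1
CONTACT_LOOSE = 2
_TYPE_NAME = {CONTACT_CLOSE: "close", CONTACT_LOOSE: "loose"}


@dataclass(frozen=True)
class MercParams:
    """Thresholds and semantics of contact classification.

    close_nm / loose_nm:
        Distance thresholds in nm for first-type (close) and second-type
        (loose) contacts; defaults 15 and 80.
    classification_mode:
        ``per_pixel`` (default): maximal runs of same-type pixels each form
        one contact.  ``per_segment``: maximal runs of in-contact pixels of
        either type form one contact, typed by the run's minimum distance.
    strict_inequality:
        Strict ``<`` comparisons at both thresholds (default); when False,
        ``<=`` is used.
    """

    close_nm: float = 15.0
    loose_nm: float = 80.0
    classification_mode: Literal["per_pixel", "per_segment"] = "per_pixel"
    strict_inequality: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.close_nm < self.loose_nm):
            raise ValueError(
                f"thresholds must satisfy 0 < close_nm < loose_nm, "
                f"got close={self.close_nm}, loose={self.loose_nm}"
            )
        if self.classification_mode not in ("per_pixel", "per_segment"):
            raise ValueError(
                f"unknown classification_mode {self.classification_mode!r}"
            )


@dataclass
class DistanceField:
    """Per-pixel distance (nm) to the nearest ER contour pixel center.

    Infinite everywhere when the mask contains no ER object; zero exactly at
    ER contour pixels.
    """

    distances: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.distances.shape  # type: ignore[return-value]


@dataclass
class ContactSegment:
    """One detected MERC on a mitochondrial contour."""

    mito_ref: tuple[int, int]  # (class_id, object_id)
    contact_type: str  # "close" | "loose"
    pixel_indices: np.ndarray  # circular run of indices into the contour
    n_pixels: int
    length_nm: float
    min_distance_nm: float


@dataclass
class MercReport:
    """Per-image summary mirroring the CSV output of the analysis service."""

    image_id: str = ""
    n_mitochondria: int = 0
    mito_area_nm2: float = 0.0
    n_er_objects: int = 0
    er_area_nm2: float = 0.0
    n_close: int = 0  # N_C1
    len_close_nm: float = 0.0  # L_C1
    n_loose: int = 0  # N_C2
    len_loose_nm: float = 0.0  # L_C2
    total_mito_contour_nm: float = 0.0

    def as_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "n_mitochondria": self.n_mitochondria,
            "mito_area_nm2": self.mito_area_nm2,
            "n_er_objects": self.n_er_objects,
            "er_area_nm2": self.er_area_nm2,
            "n_close_contacts": self.n_close,
            "total_close_length_nm": self.len_close_nm,
            "n_loose_contacts": self.n_loose,
            "total_loose_length_nm": self.len_loose_nm,
        }


def nm_to_px(distance_nm: float, calibration: Calibration) -> int:
    """Convert a physical distance to a whole pixel count.

    Rounds to the nearest integer, halves away from zero: 80 nm at
    0.38 nm/px → 210.53 → 211 px.
    """
    if distance_nm < 0:
        raise ValueError(f"distance must be non-negative, got {distance_nm}")
    return int(math.floor(distance_nm / calibration.pixel_size_nm + 0.5))


def er_contour_pixels(
    mask: LabelMask, connectivity: Literal[4, 8] = 8
) -> np.ndarray:
    """(n, 2) coordinates of all ER external-contour pixels in the mask."""
    pts = [
        trace_contour(region).points
        for region in label_objects(mask, CLASS_ER, connectivity=connectivity)
    ]
    if not pts:
        return np.empty((0, 2), dtype=int)
    return np.concatenate(pts, axis=0)


def er_contour_distance_field(
    mask: LabelMask, connectivity: Literal[4, 8] = 8
) -> DistanceField:
    """Exact Euclidean distance (nm) from every pixel to the ER contour.

    Computed with an exact Euclidean distance transform seeded at the ER
    external-contour pixels; all-infinite when the mask has no ER object.
    """
    seeds = er_contour_pixels(mask, connectivity=connectivity)
    h, w = mask.shape
    if seeds.shape[0] == 0:
        return DistanceField(np.full((h, w), np.inf))
    not_seed = np.ones((h, w), dtype=bool)
    not_seed[seeds[:, 0], seeds[:, 1]] = False
    d_px = ndimage.distance_transform_edt(not_seed)
    return DistanceField(d_px * mask.calibration.pixel_size_nm)


def classify_contact_pixels(
    contour: Contour, field: DistanceField, params: MercParams
) -> np.ndarray:
    """Label each contour point none/close/loose by its ER distance.

    Strict mode: close iff d < close_nm; loose iff close_nm <= d < loose_nm.
    Non-strict mode uses ``<=`` at both thresholds.
    """
    pts = contour.points
    h, w = field.shape
    if (
        (pts[:, 0] < 0).any()
        or (pts[:, 1] < 0).any()
        or (pts[:, 0] >= h).any()
        or (pts[:, 1] >= w).any()
    ):
        raise ValueError("contour point lies outside the distance field grid")
    d = field.distances[pts[:, 0], pts[:, 1]]
    labels = np.full(len(d), CONTACT_NONE, dtype=np.int8)
    if params.strict_inequality:
        labels[d < params.loose_nm] = CONTACT_LOOSE
        labels[d < params.close_nm] = CONTACT_CLOSE
    else:
        labels[d <= params.loose_nm] = CONTACT_LOOSE
        labels[d <= params.close_nm] = CONTACT_CLOSE
    return labels


def _circular_runs(values: np.ndarray) -> list[np.ndarray]:
    """Decompose circular index space into maximal runs of equal values.

    Returns index arrays in circular order; a run spanning the end/start
    wrap appears once.  For a constant array a single run covers everything.
    """
    n = len(values)
    if n == 0:
        return []
    changes = np.flatnonzero(values != np.roll(values, 1))
    if changes.size == 0:
        return [np.arange(n)]
    runs = []
    for i, start in enumerate(changes):
        end = changes[(i + 1) % len(changes)]
        if end > start:
            runs.append(np.arange(start, end))
        else:
            runs.append(np.concatenate([np.arange(start, n), np.arange(0, end)]))
    return runs


def _run_length_nm(
    run: np.ndarray, contour: Contour, calibration: Calibration, full_contour: bool
) -> float:
    pts = contour.points.astype(float)
    if full_contour:
        return contour_arc_length(contour, calibration)
    if len(run) < 2:
        return 0.0
    steps = np.linalg.norm(pts[run[1:]] - pts[run[:-1]], axis=1)
    return float(steps.sum()) * calibration.pixel_size_nm


def group_contacts(
    labels: np.ndarray,
    contour: Contour,
    field: DistanceField,
    calibration: Calibration,
    params: MercParams,
) -> List[ContactSegment]:
    """Group per-pixel contact labels into maximal circular runs.

    In ``per_pixel`` mode each maximal run of one contact type is a
    segment; in ``per_segment`` mode maximal runs of in-contact pixels of
    either type are typed by their minimum distance.  A run covering the
    whole closed contour yields one segment whose length equals the full
    perimeter.  Run lengths are arc lengths over the run's consecutive
    steps (a run of k pixels has k−1 steps).
    """
    labels = np.asarray(labels)
    if len(labels) != len(contour):
        raise ValueError("labels are not aligned with the contour points")
    if params.classification_mode == "per_segment":
        group_values = (labels != CONTACT_NONE).astype(np.int8)
    else:
        group_values = labels
    d = field.distances[contour.points[:, 0], contour.points[:, 1]]
    segments: List[ContactSegment] = []
    n = len(labels)
    for run in _circular_runs(group_values):
        if group_values[run[0]] == 0:
            continue
        dmin = float(d[run].min())
        if params.classification_mode == "per_segment":
            if params.strict_inequality:
                ctype = CONTACT_CLOSE if dmin < params.close_nm else CONTACT_LOOSE
            else:
                ctype = CONTACT_CLOSE if dmin <= params.close_nm else CONTACT_LOOSE
        else:
            ctype = int(labels[run[0]])
        segments.append(
            ContactSegment(
                mito_ref=contour.object_ref,
                contact_type=_TYPE_NAME[ctype],
                pixel_indices=run,
                n_pixels=len(run),
                length_nm=_run_length_nm(
                    run, contour, calibration, full_contour=(len(run) == n)
                ),
                min_distance_nm=dmin,
            )
        )
    segments.sort(key=lambda s: int(s.pixel_indices[0]))
    return segments


def analyze_mask(
    mask: LabelMask,
    params: MercParams = MercParams(),
    connectivity: Literal[4, 8] = 8,
    min_area_px: int = 0,
    area_mode: Literal["pixel_count", "polygon"] = "pixel_count",
) -> tuple[MercReport, List[ContactSegment]]:
    """Full per-image pipeline: objects → contours → distances → contacts.

    Returns the per-image report together with every detected contact
    segment (for overlays and per-contact statistics).
    """
    cal = mask.calibration
    mito_regions = label_objects(
        mask, CLASS_MITOCHONDRIA, connectivity=connectivity, min_area_px=min_area_px
    )
    er_regions = label_objects(
        mask, CLASS_ER, connectivity=connectivity, min_area_px=min_area_px
    )
    report = MercReport(
        image_id=mask.image_id,
        n_mitochondria=len(mito_regions),
        mito_area_nm2=sum(region_area(r, cal, area_mode) for r in mito_regions),
        n_er_objects=len(er_regions),
        er_area_nm2=sum(region_area(r, cal, area_mode) for r in er_regions),
    )
    all_segments: List[ContactSegment] = []
    if mito_regions:
        field = er_contour_distance_field(mask, connectivity=connectivity)
        for region in mito_regions:
            contour = trace_contour(region)
            report.total_mito_contour_nm += contour_arc_length(contour, cal)
            if not np.isfinite(field.distances).any():
                continue
            labels = classify_contact_pixels(contour, field, params)
            all_segments.extend(group_contacts(labels, contour, field, cal, params))
    for seg in all_segments:
        if seg.contact_type == "close":
            report.n_close += 1
            report.len_close_nm += seg.length_nm
        else:
            report.n_loose += 1
            report.len_loose_nm += seg.length_nm
    return report, all_segments


def summarize_mercs(
    mask: LabelMask,
    params: MercParams = MercParams(),
    connectivity: Literal[4, 8] = 8,
    min_area_px: int = 0,
) -> MercReport:
    """Per-image MERC summary (counts, areas, N_C1/L_C1/N_C2/L_C2)."""
    report, _ = analyze_mask(
        mask, params, connectivity=connectivity, min_area_px=min_area_px
    )
    return report
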
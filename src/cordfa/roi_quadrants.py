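"""Quadrant partition of the cord cross-section ROI.

The cord ROI on an axial slice is split into posterior (P), anterior (A),
left (L) and right (R) subregions about a center point.  The two diagonals
through the center (the 45-degree rotations of the image axes) bound four
90-degree sectors; each ROI pixel is assigned to the sector containing it.

Center conventions
------------------
``"median"`` (default): the coordinate where the cumulative marginal sum of
the mask first reaches half its total, separately along x (columns) and y
(rows) — the marginal median of the cumulative intensity profile.
``"centroid"``: the mask center of mass.  Both are offered because either
reading is defensible for a cumulative-intensity center; the default is
documented and fixed.

Tie-break
---------
Pixels lying exactly on a diagonal are assigned to the sector
counter-clockwise of that boundary (angles measured with image-up as +90
degrees); the center pixel itself lands in the right sector.  Any fixed
deterministic rule works; this one is tested.

Orientation
-----------
The mapping from image directions to anatomy is configuration: by default
image-up is anterior, image-down posterior, image-left left, image-right
right.  Acquisition-specific rotations/flips belong in this mapping, not in
the partition code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .types import BASE_REGIONS, LABEL_CODES, FASlice, QuadrantLabelMap, SliceMeta


@dataclass(frozen=True)
class Orientation:
    """Image-direction → anatomical-region mapping for quadrant labelling."""

    up: str = "A"
    down: str = "P"
    left: str = "L"
    right: str = "R"

    def __post_init__(self) -> None:
        regions = {self.up, self.down, self.left, self.right}
        if regions != set(BASE_REGIONS):
            raise DataError(
                "orientation must assign each of P, A, L, R exactly once"
            )

    def rotated90(self) -> "Orientation":
        """Orientation after rotating the image 90 deg counter-clockwise."""
        return Orientation(
            up=self.right, left=self.up, down=self.left, right=self.down
        )


DEFAULT_ORIENTATION = Orientation()


def roi_center(mask: np.ndarray, method: str = "median") -> tuple[float, float]:
    """Center point (cx, cy) of a binary ROI mask.

    ``method="median"`` takes, along each axis, the first coordinate at
    which the cumulative marginal mask sum reaches half the total;
    ``method="centroid"`` takes the center of mass.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise DataError("mask must be 2-D")
    total = m.sum()
    if total == 0:
        raise DataError("empty ROI mask")
    if method == "median":
        col_sums = m.sum(axis=0)
        row_sums = m.sum(axis=1)
        cx = int(np.searchsorted(np.cumsum(col_sums), total / 2.0))
        cy = int(np.searchsorted(np.cumsum(row_sums), total / 2.0))
        return float(cx), float(cy)
    if method == "centroid":
        rows, cols = np.nonzero(m)
        return float(cols.mean()), float(rows.mean())
    raise DataError(f"unknown center method {method!r}")


def quadrant_labels(
    mask: np.ndarray,
    center: tuple[float, float] | None = None,
    orientation: Orientation = DEFAULT_ORIENTATION,
    center_method: str = "median",
) -> QuadrantLabelMap:
    """Assign every ROI pixel to one of the four quadrants.

    The plane is divided by the two diagonals through ``center``; a pixel's
    sector is decided by the angle of (pixel - center) with image-up taken
    as +90 degrees.  Sector boundaries belong to the sector
    counter-clockwise of them.
    """
    m = np.asarray(mask).astype(bool)
    if m.sum() == 0:
        raise DataError("empty ROI mask")
    if center is None:
        center = roi_center(m, method=center_method)
    cx, cy = center
    rows, cols = np.nonzero(m)
    dx = cols - cx
    dy = rows - cy  # image rows grow downward
    # angle in degrees, image-up = +90
    theta = np.degrees(np.arctan2(-dy, dx))
    sector = np.floor(((theta + 45.0) % 360.0) / 90.0).astype(int)
    sector_region = [
        orientation.right,
        orientation.up,
        orientation.left,
        orientation.down,
    ]
    labels = np.zeros(m.shape, dtype=np.int8)
    for s, region in enumerate(sector_region):
        sel = sector == s
        labels[rows[sel], cols[sel]] = LABEL_CODES[region]
    return QuadrantLabelMap(labels=labels, center=(float(cx), float(cy)))


def region_means(fa: FASlice, labels: QuadrantLabelMap) -> dict:
    """Mean FA per quadrant; raises naming the region if any is empty.

    Returns a record dict with subject/slice/class metadata and one entry
    per base region — one row of the base feature table.
    """
    if fa.fa.shape != labels.labels.shape:
        raise DataError("FA map and label map shapes disagree")
    record: dict = {
        "subject_id": fa.meta.subject_id,
        "slice_id": fa.meta.slice_id,
        "class": fa.meta.class_label,
    }
    for region in BASE_REGIONS:
        sel = labels.region_mask(region)
        if not sel.any():
            raise DataError(
                f"quadrant {region!r} is empty — ROI too small or degenerate"
            )
        record[region] = float(fa.fa[sel].mean())
    return record


def slices_to_table(slices, label_maps):
    """Build a base :class:`~cordfa.types.FeatureTable` from paired
    FA slices and quadrant label maps."""
    import pandas as pd

    from .types import FeatureTable

    records = [region_means(fa, lm) for fa, lm in zip(slices, label_maps)]
    return FeatureTable(pd.DataFrame(records), list(BASE_REGIONS))
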
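"""Core in-memory containers shared across the pipeline stages.

The pipeline moves through three representations:

* image level — :class:`TensorSlice` (per-voxel 3x3 diffusion tensors) and
  :class:`FASlice` (per-voxel fractional anisotropy), both carrying a binary
  region-of-interest mask over the cord cross-section;
* region level — :class:`QuadrantLabelMap`, the partition of the ROI into
  posterior/anterior/left/right sectors;
* table level — :class:`FeatureTable`, per-slice (or per-subject) feature
  rows with class labels, wrapped around a :class:`pandas.DataFrame`.

Class label conventions follow the clinical coding: ``0`` = patient
(injured), ``1`` = normal control.  The *positive* class for
sensitivity/specificity is the injured class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

#: Anatomical region codes used in integer label maps.
LABEL_CODES = {"background": 0, "P": 1, "A": 2, "L": 3, "R": 4}

#: The four base cord regions in canonical order.
BASE_REGIONS = ("P", "A", "L", "R")

PATIENT_CLASS = 0
NORMAL_CLASS = 1


@dataclass
class SliceMeta:
    """Identity of one axial slice: subject, slice index, class label."""

    subject_id: str = ""
    slice_id: int = 0
    class_label: int | None = None


@dataclass
class TensorSlice:
    """A 2-D grid of 3x3 symmetric diffusion tensors with an ROI mask.

    ``tensors`` has shape ``(ny, nx, 3, 3)``; each voxel's matrix must be
    symmetric to within ``1e-12`` (checked lazily by consumers).  ``mask``
    is boolean with shape ``(ny, nx)``.
    """

    tensors: np.ndarray
    mask: np.ndarray
    meta: SliceMeta = field(default_factory=SliceMeta)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.tensors.shape[:2] != self.mask.shape:
            raise DataError(
                f"tensor grid {self.tensors.shape[:2]} and mask "
                f"{self.mask.shape} shapes disagree"
            )
        if self.tensors.shape[2:] != (3, 3):
            raise DataError("tensors must have per-voxel shape (3, 3)")


@dataclass
class FASlice:
    """A 2-D fractional-anisotropy map with an ROI mask.

    FA is unitless in [0, 1]; voxels outside the mask are zero by contract.
    """

    fa: np.ndarray
    mask: np.ndarray
    meta: SliceMeta = field(default_factory=SliceMeta)

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.fa.shape != self.mask.shape:
            raise DataError(
                f"FA grid {self.fa.shape} and mask {self.mask.shape} "
                "shapes disagree"
            )


@dataclass
class QuadrantLabelMap:
    """Partition of an ROI into the four cord quadrants.

    ``labels`` holds the integer codes of :data:`LABEL_CODES`; every ROI
    pixel carries exactly one of P/A/L/R and non-ROI pixels are background.
    ``center`` is the (cx, cy) pivot in pixel coordinates (x = column,
    y = row).
    """

    labels: np.ndarray
    center: tuple[float, float]

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == LABEL_CODES[region]


class FeatureTable:
    """N records x M features with class labels and subject identity.

    Thin wrapper over a :class:`pandas.DataFrame` with reserved columns
    ``subject_id``, ``slice_id``, ``class`` and one column per feature.
    Base tables carry the four region means P, A, L, R; expanded tables
    carry the 15 subset averages (see :mod:`cordfa.features`).
    """

    META_COLUMNS = ("subject_id", "slice_id", "class")

    def __init__(self, frame: pd.DataFrame, feature_names: Sequence[str]):
        self.feature_names = list(feature_names)
        missing = [c for c in self.META_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"feature table missing columns: {missing}")
        missing = [c for c in self.feature_names if c not in frame.columns]
        if missing:
            raise DataError(f"feature table missing feature columns: {missing}")
        cols = list(self.META_COLUMNS) + self.feature_names
        self.frame = frame.loc[:, cols].reset_index(drop=True)
        if self.frame[self.feature_names].isna().any().any():
            raise DataError("feature table contains missing values")
        labels = set(self.frame["class"].unique())
        if not labels <= {PATIENT_CLASS, NORMAL_CLASS}:
            raise DataError(f"unexpected class labels: {sorted(labels)}")

    # -- array views -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """Feature matrix of shape (N, M), float."""
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["class"].to_numpy(dtype=int)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def subset(self, feature_names: Sequence[str]) -> "FeatureTable":
        """Restrict to the named feature columns (order preserved)."""
        unknown = [f for f in feature_names if f not in self.feature_names]
        if unknown:
            raise DataError(f"unknown features requested: {unknown}")
        return FeatureTable(self.frame, list(feature_names))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and self.frame.equals(other.frame)
        )

    def __repr__(self) -> str:
        return (
            f"FeatureTable(n_records={self.n_records}, "
            f"features={self.feature_names})"
        )

    # -- I/O ----------------------------------------------------------
    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path)
        features = [c for c in frame.columns if c not in cls.META_COLUMNS]
        return cls(frame, features)


@dataclass
class ConfusionCounts:
    """2x2 confusion counts; positive class = injured (class 0)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise DataError(f"negative confusion count {name}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Outcome of one cross-validated classification run."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    predictions: pd.DataFrame  # columns: subject_id, slice_id, truth, predicted
    scheme: str
    k: int
    seed: int | None = None
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _clean(x: float):
            return None if (isinstance(x, float) and math.isnan(x)) else x

        return {
            "scheme": self.scheme,
            "k": self.k,
            "seed": self.seed,
            "features": self.feature_names,
            "counts": {
                "TP": self.counts.tp,
                "TN": self.counts.tn,
                "FP": self.counts.fp,
                "FN": self.counts.fn,
            },
            "accuracy": _clean(self.accuracy),
            "sensitivity": _clean(self.sensitivity),
            "specificity": _clean(self.specificity),
        }

    def summary(self) -> str:
        c = self.counts
        return (
            f"{self.scheme} (k={self.k}, features={len(self.feature_names)}): "
            f"TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn} | "
            f"accuracy={self.accuracy:.3f} "
            f"sensitivity={self.sensitivity:.3f} "
            f"specificity={self.specificity:.3f}"
        )
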
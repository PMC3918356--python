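"""Synthetic cohorts and image phantoms for the cord-FA pipeline.

No public spinal-cord DTI cohort with quadrant annotations exists, so every
downstream stage is exercised on synthetic data with the statistical
structure the analysis assumes:

* **feature-level cohorts** — per-slice quadrant mean-FA records drawn from
  class-conditional multivariate Gaussians over (P, A, L, R).  The default
  calibration mirrors a cervical SCI cohort of 9 patients and 5 normal
  controls contributing 106 injured and 58 normal slices: class means are
  the published per-region FA averages, and the (unpublished) dispersions
  are recovered by inverting the published pooled two-sample t-test
  p-values at those group sizes (:func:`derive_sd_from_pvalue`).
* **image-level phantoms** — elliptical ROI masks with quadrant-structured
  FA fields (optionally encoded as prolate diffusion tensors), for testing
  the FA-map and quadrant-partition stages end to end.

Adjacent cord quadrants share tissue, so base regions are given a common
pairwise correlation (default 0.3).  FA is clamped to [0, 1] after
sampling, as FA is bounded by definition; at the calibrated dispersions
clamping affects well under 1% of values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .tensor_fa import eigenvalues_for_fa
from .types import (
    BASE_REGIONS,
    NORMAL_CLASS,
    PATIENT_CLASS,
    FASlice,
    FeatureTable,
    SliceMeta,
    TensorSlice,
)

#: Published per-region mean FA for patient (injured) and normal slices.
CLASS_MEANS: dict[str, tuple[float, float]] = {
    "P": (0.427, 0.535),
    "A": (0.451, 0.684),
    "L": (0.475, 0.645),
    "R": (0.419, 0.610),
}

#: Published two-tailed pooled t-test p-values for the base regions,
#: patient vs normal slices at group sizes 106 / 58.
REGION_PVALUES: dict[str, float] = {
    "P": 7.69e-9,
    "A": 8.05e-31,
    "L": 1.89e-20,
    "R": 2.39e-26,
}

#: Group sizes behind the published t-tests (injured, normal slices).
REFERENCE_GROUP_SIZES = (106, 58)


def derive_sd_from_pvalue(
    p_two_tailed: float, n1: int, n2: int, mean_diff: float
) -> float:
    """Pooled SD implied by a two-tailed pooled two-sample t-test.

    Inverts ``p = 2 * P(T_df >= |t|)`` with
    ``t = mean_diff / (s * sqrt(1/n1 + 1/n2))`` and ``df = n1 + n2 - 2`` to
    recover the pooled standard deviation ``s``.  Round-trip property:
    recomputing the test with the returned SD reproduces ``p``.
    """
    if not 0.0 < p_two_tailed < 1.0:
        raise ConfigError(f"p-value {p_two_tailed} outside (0, 1)")
    if mean_diff <= 0:
        raise ConfigError("mean difference must be positive")
    if n1 + n2 <= 2:
        raise ConfigError("need n1 + n2 > 2 for a pooled t-test")
    df = n1 + n2 - 2
    t_crit = stats.t.isf(p_two_tailed / 2.0, df)
    return float(mean_diff / (t_crit * np.sqrt(1.0 / n1 + 1.0 / n2)))


def default_class_sds() -> dict[str, float]:
    """Per-region pooled SDs recovered from the published p-values."""
    n1, n2 = REFERENCE_GROUP_SIZES
    return {
        r: derive_sd_from_pvalue(
            REGION_PVALUES[r], n1, n2, CLASS_MEANS[r][1] - CLASS_MEANS[r][0]
        )
        for r in BASE_REGIONS
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic feature-level cohort.

    ``class_means`` maps region → (patient_mean, normal_mean) in FA units;
    ``class_sds`` maps region → pooled SD shared by both classes;
    ``base_correlation`` is the common pairwise correlation between the
    four base regions within a slice.
    """

    n_patients: int = 9
    n_controls: int = 5
    slices_per_subject: int = 12
    class_means: dict = field(default_factory=lambda: dict(CLASS_MEANS))
    class_sds: dict = field(default_factory=default_class_sds)
    base_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_controls, self.slices_per_subject) < 1:
            raise ConfigError("subject and slice counts must be >= 1")
        for r in BASE_REGIONS:
            pm, nm = self.class_means[r]
            if not (0.0 < pm < 1.0 and 0.0 < nm < 1.0):
                raise ConfigError(f"class means for {r} must lie in (0, 1)")
            if self.class_sds[r] <= 0:
                raise ConfigError(f"SD for {r} must be positive")
        if not 0.0 <= self.base_correlation < 1.0:
            raise ConfigError("base correlation must lie in [0, 1)")

    def covariance(self) -> np.ndarray:
        """4x4 covariance with common correlation; checked positive-definite."""
        sds = np.array([self.class_sds[r] for r in BASE_REGIONS])
        corr = np.full((4, 4), self.base_correlation)
        np.fill_diagonal(corr, 1.0)
        cov = corr * np.outer(sds, sds)
        if np.min(np.linalg.eigvalsh(cov)) <= 0:
            raise ConfigError("covariance is not positive definite")
        return cov

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["class_means"] = {k: tuple(v) for k, v in raw["class_means"].items()}
        return cls(**raw)


def generate_feature_cohort(config: CohortConfig) -> FeatureTable:
    """Draw a per-slice base feature table for the configured cohort.

    Patient subjects' slices are drawn from the patient-mean multivariate
    Gaussian over (P, A, L, R), controls from the normal-mean Gaussian,
    with the shared covariance of ``config``; values are clamped to [0, 1].
    Identical config and seed produce an identical table.
    """
    cov = config.covariance()
    rng = np.random.default_rng(config.seed)
    mean_pat = np.array([config.class_means[r][0] for r in BASE_REGIONS])
    mean_nor = np.array([config.class_means[r][1] for r in BASE_REGIONS])
    rows = []
    subjects = [(f"patient{i + 1:02d}", PATIENT_CLASS) for i in range(config.n_patients)]
    subjects += [(f"control{i + 1:02d}", NORMAL_CLASS) for i in range(config.n_controls)]
    for subject_id, cls in subjects:
        mean = mean_pat if cls == PATIENT_CLASS else mean_nor
        draws = rng.multivariate_normal(
            mean, cov, size=config.slices_per_subject, method="cholesky"
        )
        draws = np.clip(draws, 0.0, 1.0)
        for s in range(config.slices_per_subject):
            row = {"subject_id": subject_id, "slice_id": s, "class": cls}
            row.update({r: draws[s, j] for j, r in enumerate(BASE_REGIONS)})
            rows.append(row)
    return FeatureTable(pd.DataFrame(rows), list(BASE_REGIONS))


@dataclass
class PhantomConfig:
    """Parameters of the image-level phantom slices.

    ``quadrant_fa`` maps region → (patient_fa, normal_fa); the ROI is an
    axis-aligned ellipse centered on the grid.
    """

    grid_shape: tuple[int, int] = (32, 32)
    roi_semi_axes: tuple[float, float] = (10.0, 12.0)
    quadrant_fa: dict = field(default_factory=lambda: dict(CLASS_MEANS))
    noise_sd: float = 0.02
    n_slices: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.grid_shape
        ax, ay = self.roi_semi_axes
        if 2 * ax >= nx or 2 * ay >= ny:
            raise ConfigError("ROI ellipse does not fit inside the grid")
        for r in BASE_REGIONS:
            pm, nm = self.quadrant_fa[r]
            if not (0.0 < pm < 1.0 and 0.0 < nm < 1.0):
                raise ConfigError(f"quadrant FA for {r} must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be non-negative")


def _elliptical_mask(config: PhantomConfig) -> np.ndarray:
    ny, nx = config.grid_shape
    ax, ay = config.roi_semi_axes
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def generate_phantom_slices(
    config: PhantomConfig,
    class_label: int,
    mode: str = "fa",
    orientation=None,
) -> list:
    """Quadrant-structured phantom slices for one class.

    Each ROI pixel's FA is the configured per-quadrant class mean plus
    Gaussian noise, clamped to [0, 1]; background is zero.  With
    ``mode="fa"`` returns :class:`FASlice` objects; with ``mode="tensor"``
    each pixel carries a prolate diffusion tensor whose FA equals the
    target value, so the full tensor → FA → quadrant pipeline can run.
    """
    from .roi_quadrants import DEFAULT_ORIENTATION, quadrant_labels

    if class_label not in (PATIENT_CLASS, NORMAL_CLASS):
        raise ConfigError(f"class label must be 0 or 1, got {class_label}")
    if mode not in ("fa", "tensor"):
        raise ConfigError(f"unknown phantom mode {mode!r}")
    orientation = orientation or DEFAULT_ORIENTATION
    mask = _elliptical_mask(config)
    labels = quadrant_labels(mask, orientation=orientation)
    col = 0 if class_label == PATIENT_CLASS else 1
    rng = np.random.default_rng(config.seed)
    out = []
    for s in range(config.n_slices):
        fa = np.zeros(config.grid_shape, dtype=float)
        for region in BASE_REGIONS:
            sel = labels.region_mask(region)
            base = config.quadrant_fa[region][col]
            noise = rng.normal(0.0, config.noise_sd, size=int(sel.sum()))
            fa[sel] = np.clip(base + noise, 0.0, 1.0)
        meta = SliceMeta(
            subject_id=f"phantom_c{class_label}", slice_id=s, class_label=class_label
        )
        if mode == "fa":
            out.append(FASlice(fa=fa, mask=mask.copy(), meta=meta))
        else:
            tensors = np.zeros(config.grid_shape + (3, 3), dtype=float)
            rows, cols = np.nonzero(mask)
            for r, c in zip(rows, cols):
                tensors[r, c] = np.diag(eigenvalues_for_fa(fa[r, c]))
            out.append(TensorSlice(tensors=tensors, mask=mask.copy(), meta=meta))
    return out
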
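"""Image and table I/O: NIfTI-1 / ANALYZE 7.5 via nibabel, CSV via pandas.

2-D slices are stored as single-slice 3-D volumes (ny, nx, 1).  Masks and
quadrant label maps are integer volumes; FA maps are float.  The ANALYZE
pair format (.hdr/.img) is accepted on read and selected on write by file
extension, since legacy cord ROI tooling emits it.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError
from .types import FASlice, QuadrantLabelMap, SliceMeta


def _to_volume(arr: np.ndarray) -> np.ndarray:
    # store (ny, nx) slices as (nx, ny, 1) in image axis order (x, y, z)
    return np.ascontiguousarray(arr.T[:, :, None])


def _from_volume(vol: np.ndarray) -> np.ndarray:
    vol = np.asarray(vol)
    if vol.ndim == 3:
        if vol.shape[2] != 1:
            raise DataError(
                f"expected a single-slice volume, got shape {vol.shape}"
            )
        vol = vol[:, :, 0]
    elif vol.ndim != 2:
        raise DataError(f"cannot interpret image of shape {vol.shape}")
    return vol.T


def _make_image(data: np.ndarray, path: Path):
    if path.suffix in (".hdr", ".img"):
        return nib.AnalyzeImage(data, affine=None)
    return nib.Nifti1Image(data, affine=np.eye(4))


def save_scalar_image(arr: np.ndarray, path) -> None:
    """Write a 2-D scalar grid as NIfTI-1 (.nii/.nii.gz) or ANALYZE (.hdr)."""
    path = Path(path)
    data = _to_volume(np.asarray(arr, dtype=np.float64))
    nib.save(_make_image(data, path), str(path))


def load_scalar_image(path) -> np.ndarray:
    """Read a 2-D scalar grid from a NIfTI-1 or ANALYZE file."""
    img = nib.load(str(path))
    return _from_volume(np.asarray(img.dataobj, dtype=np.float64))


def save_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    data = _to_volume(np.asarray(mask).astype(np.uint8))
    nib.save(_make_image(data, path), str(path))


def load_mask(path) -> np.ndarray:
    return load_scalar_image(path) > 0.5


def save_fa_slice(slice_: FASlice, fa_path, mask_path) -> None:
    save_scalar_image(slice_.fa, fa_path)
    save_mask(slice_.mask, mask_path)


def load_fa_slice(fa_path, mask_path, meta: SliceMeta | None = None) -> FASlice:
    fa = load_scalar_image(fa_path)
    mask = load_mask(mask_path)
    return FASlice(fa=fa, mask=mask, meta=meta or SliceMeta())


def save_label_map(labels: QuadrantLabelMap, path) -> None:
    """Write a quadrant label map with codes {0:bg, 1:P, 2:A, 3:L, 4:R}."""
    path = Path(path)
    data = _to_volume(labels.labels.astype(np.int16))
    nib.save(_make_image(data, path), str(path))


def load_label_map(path, center=(0.0, 0.0)) -> QuadrantLabelMap:
    arr = load_scalar_image(path).astype(np.int8)
    return QuadrantLabelMap(labels=arr, center=tuple(center))
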
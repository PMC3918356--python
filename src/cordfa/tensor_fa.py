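"""Diffusion-tensor eigenvalues and fractional anisotropy (FA).

FA quantifies how directionally constrained water diffusion is in a voxel.
With tensor eigenvalues :math:`\\lambda_1, \\lambda_2, \\lambda_3` and their
mean :math:`\\bar\\lambda`,

.. math::

    \\mathrm{FA} = \\sqrt{\\tfrac{3}{2}}
        \\frac{\\sqrt{\\sum_i (\\lambda_i - \\bar\\lambda)^2}}
             {\\sqrt{\\sum_i \\lambda_i^2}}

which is 0 for isotropic diffusion (all eigenvalues equal) and 1 in the
single-direction (stick) limit, and is invariant to overall scaling and to
permutation of the eigenvalues.

Negative eigenvalues (noise artifacts of tensor estimation) are passed
through unmodified but counted in a QC counter, so data problems surface
instead of being clamped away.  The all-zero tensor maps to FA = 0 by
convention, matching the isotropic limit while avoiding 0/0.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError
from .types import FASlice, TensorSlice

SYMMETRY_TOL = 1e-12


def tensor_eigenvalues(tensor: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Eigenvalues of a 3x3 symmetric tensor, sorted descending.

    Parameters
    ----------
    tensor : (3, 3) array
        Symmetric diffusion tensor.
    tol : float
        Maximum allowed asymmetry ``max|D - D.T|``.

    Returns
    -------
    (3,) ndarray of real eigenvalues, largest first.
    """
    d = np.asarray(tensor, dtype=float)
    if d.shape != (3, 3):
        raise DataError(f"expected a 3x3 tensor, got shape {d.shape}")
    if np.max(np.abs(d - d.T)) > tol:
        raise DataError("tensor is asymmetric beyond tolerance")
    return np.linalg.eigvalsh(d)[::-1]


def fractional_anisotropy(eigenvalues) -> float:
    """FA of an eigenvalue triple; 0 by convention for the all-zero triple."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape != (3,):
        raise DataError("expected three eigenvalues")
    if not np.all(np.isfinite(lam)):
        raise DataError("eigenvalues must be finite")
    sumsq = float(np.dot(lam, lam))
    if sumsq == 0.0:
        return 0.0
    lam_bar = lam.mean()
    dev = float(np.dot(lam - lam_bar, lam - lam_bar))
    return float(np.sqrt(1.5 * dev / sumsq))


def fa_map(slice_: TensorSlice) -> FASlice:
    """Per-voxel FA over the ROI mask; zero elsewhere; metadata propagated.

    Returns an :class:`FASlice` whose ``qc`` attribute records the number of
    masked voxels with at least one negative eigenvalue.
    """
    ny, nx = slice_.mask.shape
    fa = np.zeros((ny, nx), dtype=float)
    n_negative = 0
    rows, cols = np.nonzero(slice_.mask)
    for r, c in zip(rows, cols):
        lam = tensor_eigenvalues(slice_.tensors[r, c])
        if np.any(lam < 0):
            n_negative += 1
        fa[r, c] = fractional_anisotropy(lam)
    out = FASlice(fa=fa, mask=slice_.mask.copy(), meta=slice_.meta)
    out.qc = {"n_negative_eigenvalue_voxels": n_negative}
    return out


def eigenvalues_for_fa(target_fa: float) -> np.ndarray:
    """Prolate eigenvalue triple ``(1+2d, 1-d, 1-d)`` attaining a target FA.

    Inverts the FA formula along the axially-symmetric family with unit mean
    eigenvalue: ``d = f / sqrt(3 - 2 f^2)`` for ``f`` in [0, 1].  Used to
    build tensor phantoms with prescribed FA.
    """
    f = float(target_fa)
    if not 0.0 <= f <= 1.0:
        raise DataError(f"target FA {f} outside [0, 1]")
    d = f / np.sqrt(3.0 - 2.0 * f * f)
    return np.array([1.0 + 2.0 * d, 1.0 - d, 1.0 - d])
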
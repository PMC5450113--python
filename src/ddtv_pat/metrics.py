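"""Quantitative image-quality metrics: PSNR and normalized L2 distance.

Both metrics follow the protocol of comparing images at the same gray
level: each image is divided by its own maximum so that the peak value
(MAXI) equals 1 before the squared error is accumulated.
"""

from __future__ import annotations

import numpy as np

from .phantoms import normalize

__all__ = ["psnr", "distance_d", "line_profile"]


def psnr(A: np.ndarray, ref: np.ndarray, normalize_inputs: bool = True) -> float:
    """Peak signal-to-noise ratio in dB.

    ``10 log10( Nx Ny MAXI^2 / sum (A - ref)^2 )`` with MAXI = 1 after
    normalization.  Identical images return ``inf`` (flag, not an error).
    """
    A = np.asarray(A, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if A.shape != ref.shape:
        raise ValueError("images must share a shape")
    if normalize_inputs:
        A = normalize(A)
        ref = normalize(ref)
    err = float(np.sum((A - ref) ** 2))
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(A.size / err))


def distance_d(A: np.ndarray, ref: np.ndarray,
               normalize_inputs: bool = True) -> float:
    """Normalized L2 distance ``( sum (A-ref)^2 / sum ref^2 )**0.5``.

    0 for identical images, 1 for an all-zero reconstruction.
    """
    A = np.asarray(A, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if A.shape != ref.shape:
        raise ValueError("images must share a shape")
    if normalize_inputs:
        A = normalize(A)
        ref = normalize(ref)
    denom = float(np.sum(ref**2))
    if denom == 0:
        raise ValueError("reference image must not be all-zero")
    return float(np.sqrt(np.sum((A - ref) ** 2) / denom))


def line_profile(A: np.ndarray, index: int, axis: int = 0) -> np.ndarray:
    """Extract one row (axis=0 fixes x: profile along y) or column of pixels."""
    A = np.asarray(A)
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    if not 0 <= index < A.shape[axis]:
        raise ValueError(f"index {index} out of range for axis {axis}")
    return A[index, :].copy() if axis == 0 else A[:, index].copy()
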
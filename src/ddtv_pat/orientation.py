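"""Block-wise orientation-field estimation from image gradients.

The local texture direction theta and its reliability (coherence) C are
estimated per block from first-order image gradients, in the classic
gradient/structure-tensor fashion used for fingerprint orientation fields:

* per-block dominant direction from the doubled-angle gradient moments,
  rotated by pi/2 so that theta points along the texture (perpendicular to
  the dominant gradient);
* Gaussian smoothing of the direction on the doubled circle, which avoids
  the mod-pi wrap-around problem;
* coherence C in [0, 1]: 0 for isotropic blocks, 1 for unidirectional ones.

C is mapped affinely to the ellipse major-axis length
``alpha = (alpha_max - 1) * C + 1`` used by the directional TV: an
isotropic block keeps the unit circle (plain TV), a strongly oriented block
stretches the ellipse along the texture direction.

Angles are defined modulo pi; comparisons should use the doubled-angle
metric.  theta is measured from array axis 0 toward axis 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GradientField",
    "OrientationField",
    "image_gradients",
    "block_orientation",
    "smooth_orientation",
    "block_coherence",
    "axis_length",
    "estimate_orientation_field",
    "save_quiver",
]


@dataclass(frozen=True)
class GradientField:
    """Backward first differences of an image along each axis.

    ``g1[i, j] = A[i, j] - A[i-1, j]`` and ``g2[i, j] = A[i, j] - A[i, j-1]``,
    with the first row/column set to 0 where the difference is undefined.
    """

    g1: np.ndarray
    g2: np.ndarray

    def __post_init__(self):
        if self.g1.shape != self.g2.shape:
            raise ValueError("gradient components must share a shape")


@dataclass(frozen=True)
class OrientationField:
    """Per-pixel texture direction, coherence, and ellipse axis length.

    All pixels of one block share the block's theta and C.  ``degenerate``
    flags blocks whose gradients vanish identically (direction undefined,
    reported as pi/2 with C = 0).
    """

    theta: np.ndarray
    coherence: np.ndarray
    alpha: np.ndarray
    block_size: int
    degenerate: np.ndarray | None = None

    def __post_init__(self):
        if not (self.theta.shape == self.coherence.shape == self.alpha.shape):
            raise ValueError("orientation field components must share a shape")


def image_gradients(A: np.ndarray) -> GradientField:
    """Backward-difference gradient field of an image (>= 2x2)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or min(A.shape) < 2:
        raise ValueError("image must be at least 2x2")
    g1 = np.zeros_like(A)
    g2 = np.zeros_like(A)
    g1[1:, :] = A[1:, :] - A[:-1, :]
    g2[:, 1:] = A[:, 1:] - A[:, :-1]
    return GradientField(g1, g2)


def _block_sums(arr: np.ndarray, block_size: int) -> np.ndarray:
    """Sum over blocks of ``block_size``; trailing partial blocks kept."""
    n1, n2 = arr.shape
    b1 = -(-n1 // block_size)
    b2 = -(-n2 // block_size)
    out = np.add.reduceat(
        np.add.reduceat(arr, np.arange(0, n1, block_size), axis=0),
        np.arange(0, n2, block_size), axis=1,
    )
    assert out.shape == (b1, b2)
    return out


def block_orientation(grad: GradientField, block_size: int) -> np.ndarray:
    """Per-block dominant texture direction O_k.

    ``O_k = 0.5 * atan2(sum 2 g1 g2, sum (g1^2 - g2^2)) + pi/2`` — the
    two-argument arctangent resolves the quadrant ambiguity of the printed
    single-argument form, and the pi/2 turns the dominant gradient direction
    into the texture direction.  Degenerate all-zero blocks return pi/2.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    num = _block_sums(2 * grad.g1 * grad.g2, block_size)
    den = _block_sums(grad.g1**2 - grad.g2**2, block_size)
    O = 0.5 * np.arctan2(num, den) + np.pi / 2
    degenerate = (num == 0) & (den == 0)
    O[degenerate] = np.pi / 2
    return O


def smooth_orientation(O: np.ndarray, sigma: float, truncate: float = 5.0) -> np.ndarray:
    """Gaussian smoothing of a direction field on the doubled circle.

    The doubled-angle sine and cosine are filtered separately (replicate
    boundary) and recombined with the half two-argument arctangent, so that
    e.g. neighbors at +85 and -85 degrees average toward 90 degrees rather
    than 0.  ``sigma`` is in block units; 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(O, dtype=float).copy()
    s = gaussian_filter(np.sin(2 * O), sigma, mode="nearest", truncate=truncate)
    c = gaussian_filter(np.cos(2 * O), sigma, mode="nearest", truncate=truncate)
    theta = 0.5 * np.arctan2(s, c)
    return np.mod(theta, np.pi)


def block_coherence(grad: GradientField, block_size: int) -> np.ndarray:
    """Per-block directivity strength C_k in [0, 1].

    ``C_k = [ (sum(g1^2 - g2^2))^2 + 4 (sum g1 g2)^2 ] / (sum(g1^2 + g2^2))^2``.
    1 for unidirectional gradients, 0 for isotropic or all-zero blocks.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    diff = _block_sums(grad.g1**2 - grad.g2**2, block_size)
    cross = _block_sums(grad.g1 * grad.g2, block_size)
    total = _block_sums(grad.g1**2 + grad.g2**2, block_size)
    C = np.zeros_like(total)
    np.divide(diff**2 + 4 * cross**2, total**2, out=C, where=total > 0)
    return np.clip(C, 0.0, 1.0)


def axis_length(C, alpha_max: float):
    """Ellipse major-axis length ``alpha = (alpha_max - 1) * C + 1``.

    Affine in the coherence: 1 (a circle, plain TV) at C = 0 and
    ``alpha_max`` at C = 1.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0) or np.any(C > 1):
        raise ValueError("coherence values must lie in [0, 1]")
    if alpha_max < 1:
        raise ValueError("alpha_max must be >= 1")
    out = (alpha_max - 1.0) * C + 1.0
    return float(out) if out.ndim == 0 else out


def estimate_orientation_field(
    A: np.ndarray,
    block_size: int = 5,
    sigma: float = 1.0,
    alpha_max: float = 2.5,
) -> OrientationField:
    """Full orientation-field pipeline: gradients -> blocks -> per pixel.

    The image is subdivided into ``block_size`` squares (default 5x5;
    trailing partial blocks cover their remaining pixels), each block's
    direction and coherence are estimated and smoothed on the block
    lattice, and the values are broadcast to every pixel of the block.
    """
    A = np.asarray(A, dtype=float)
    grad = image_gradients(A)
    O = block_orientation(grad, block_size)
    degen_blocks = _block_sums(grad.g1**2 + grad.g2**2, block_size) == 0
    theta_b = smooth_orientation(O, sigma)
    C_b = block_coherence(grad, block_size)
    alpha_b = axis_length(C_b, alpha_max)

    reps1 = _block_lengths(A.shape[0], block_size)
    reps2 = _block_lengths(A.shape[1], block_size)

    def expand(B):
        return np.repeat(np.repeat(B, reps1, axis=0), reps2, axis=1)

    return OrientationField(
        theta=expand(np.mod(theta_b, np.pi)),
        coherence=expand(C_b),
        alpha=expand(alpha_b),
        block_size=block_size,
        degenerate=expand(degen_blocks),
    )


def save_quiver(field: OrientationField, path, background: np.ndarray | None = None):
    """Write a quiver-plot diagnostic of a per-pixel orientation field.

    One arrow per block, oriented along theta and scaled by the coherence,
    optionally over the image the field was estimated from.  Requires
    matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    b = field.block_size
    n1, n2 = field.theta.shape
    ci = np.arange(b // 2, n1, b)
    cj = np.arange(b // 2, n2, b)
    J, I = np.meshgrid(cj, ci)
    th = field.theta[I, J]
    C = field.coherence[I, J]
    fig, ax = plt.subplots(figsize=(6, 6))
    if background is not None:
        ax.imshow(background.T, origin="lower", cmap="gray")
    # array axis0=x, axis1=y: display with x horizontal
    ax.quiver(I, J, C * np.cos(th), C * np.sin(th), angles="xy",
              color="tab:red", headwidth=2, pivot="mid")
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def _block_lengths(n: int, block_size: int) -> np.ndarray:
    """Pixel counts of the consecutive blocks tiling an axis of length n."""
    edges = np.arange(0, n, block_size)
    return np.diff(np.append(edges, n))
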
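"""Synthetic absorption phantoms: Shepp-Logan, directional textures, disks.

All generators are deterministic given their parameters and return images
normalized to [0, 1].  Images follow the package convention: array axis 0
along x, axis 1 along y (both increasing with the physical coordinate).

The striped and concentric-ring textures are parameterized surrogates for
scanned texture bitmaps: binary patterns with a controllable period and
orientation, which is the property the directional regularizer responds to.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "shepp_logan",
    "texture_transverse",
    "texture_circular",
    "grating",
    "disk",
    "point_absorber",
    "normalize",
    "load_image",
]

# Ten-ellipse Shepp-Logan head phantom, modified (Toft) contrast values:
# (intensity, semi-axis a, semi-axis b, x0, y0, tilt in degrees), on the
# unit square [-1, 1]^2 with x rightward and y upward.
_SHEPP_LOGAN_ELLIPSES = [
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
]


def shepp_logan(n: int, supersample: int = 1) -> np.ndarray:
    """Standard ten-ellipse Shepp-Logan phantom on an n x n grid.

    Rendered analytically from the ellipse parameter table (modified
    contrast values), normalized to [0, 1] with an exactly zero background.
    The default point-sampled rendering matches the classical phantom;
    ``supersample > 1`` area-averages the ellipse edges instead.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    m = n * supersample
    coords = ((np.arange(m) + 0.5) / supersample - 0.5 - (n - 1) / 2) / (n / 2)
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    img = np.zeros((m, m))
    for inten, a, b, x0, y0, phi_deg in _SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(phi_deg)
        xr = (X - x0) * np.cos(phi) + (Y - y0) * np.sin(phi)
        yr = -(X - x0) * np.sin(phi) + (Y - y0) * np.cos(phi)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += inten
    img = np.clip(img, 0.0, None)
    img = img.reshape(n, supersample, n, supersample).mean(axis=(1, 3))
    return normalize(img)


def _supersampled(n: int, supersample: int, fn) -> np.ndarray:
    """Area-average a sub-pixel indicator function onto an n x n grid."""
    m = n * supersample
    i = (np.arange(m) + 0.5) / supersample - 0.5 - (n - 1) / 2
    I, J = np.meshgrid(i, i, indexing="ij")
    fine = fn(I, J).astype(float)
    return fine.reshape(n, supersample, n, supersample).mean(axis=(1, 3))


def texture_transverse(n: int, period_px: float = 8.0, angle_deg: float = 0.0,
                       supersample: int = 4) -> np.ndarray:
    """Binarized stripe pattern with the given period and orientation.

    Stripes run along the direction ``angle_deg`` (measured from array
    axis 0 toward axis 1); the intensity alternates with period
    ``period_px`` along the perpendicular.  ``angle_deg = 0`` gives stripes
    constant along axis 0, i.e. 128 px with period 8 shows 16 full cycles.
    Edges are anti-aliased by area averaging (``supersample = 1`` for hard
    binary), so gradient-based orientation estimates see the true edge
    direction rather than staircase steps.
    """
    if period_px < 2:
        raise ValueError("period_px must be >= 2")
    phi = np.deg2rad(angle_deg)

    def stripes(I, J):
        perp = -I * np.sin(phi) + J * np.cos(phi)
        return np.sin(2 * np.pi * perp / period_px) >= 0

    return _supersampled(n, supersample, stripes)


def grating(n: int, period_px: float = 8.0, angle_deg: float = 0.0) -> np.ndarray:
    """Smooth sinusoidal grating in [0, 1] along the given direction."""
    if period_px < 2:
        raise ValueError("period_px must be >= 2")
    phi = np.deg2rad(angle_deg)
    i = np.arange(n) - (n - 1) / 2
    I, J = np.meshgrid(i, i, indexing="ij")
    perp = -I * np.sin(phi) + J * np.cos(phi)
    return 0.5 + 0.5 * np.sin(2 * np.pi * perp / period_px)


def texture_circular(n: int, period_px: float = 8.0,
                     supersample: int = 4) -> np.ndarray:
    """Concentric binarized rings centered on the grid.

    Radially periodic with ``period_px``; exactly invariant under 90 degree
    rotations.  The number of full bright rings is about
    ``n / (2 * period_px)``.  Edges are anti-aliased by area averaging.
    """
    if period_px < 2:
        raise ValueError("period_px must be >= 2")

    def rings(I, J):
        return np.sin(2 * np.pi * np.hypot(I, J) / period_px) >= 0

    return _supersampled(n, supersample, rings)


def disk(n: int, radius_px: float, center_px: tuple[float, float] = (0.0, 0.0),
         supersample: int = 4) -> np.ndarray:
    """Uniform disk with anti-aliased (area-averaged) edge.

    ``center_px`` is relative to the grid center in pixel units.  The
    supersampled rendering makes boundary pixels carry their covered
    fraction, which keeps arc-integral comparisons against the analytic
    circle-intersection formula accurate to sub-pixel level.
    """
    m = n * supersample
    i = (np.arange(m) + 0.5) / supersample - 0.5 - (n - 1) / 2
    I, J = np.meshgrid(i, i, indexing="ij")
    fine = (np.hypot(I - center_px[0], J - center_px[1]) <= radius_px).astype(float)
    return fine.reshape(n, supersample, n, supersample).mean(axis=(1, 3))


def point_absorber(n: int, center_px: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Single-pixel-scale absorber (a one-pixel-radius disk)."""
    return disk(n, radius_px=1.0, center_px=center_px)


def normalize(A: np.ndarray) -> np.ndarray:
    """Divide by the maximum value so the peak equals 1.

    All-zero images are returned unchanged; for signed images the maximum
    absolute value is used so the result stays within [-1, 1].
    """
    A = np.asarray(A, dtype=float)
    m = A.max() if A.size else 0.0
    if m <= 0:
        m = np.abs(A).max() if A.size else 0.0
        if m == 0:
            return A.copy()
    return A / m


def load_image(path, n: int | None = None) -> np.ndarray:
    """Load a raster image as a normalized grayscale absorption map.

    Multi-channel images are averaged to one channel.  The file's row/column
    layout is mapped to the package's (x, y) axis convention.  If ``n`` is
    given the image is cropped/padded centrally to n x n.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    # image rows run top-to-bottom in y; convert to axis0=x, axis1=y (up)
    arr = arr[::-1, :].T
    if n is not None:
        out = np.zeros((n, n))
        sx = min(n, arr.shape[0])
        sy = min(n, arr.shape[1])
        ox, oy = (n - sx) // 2, (n - sy) // 2
        ix, iy = (arr.shape[0] - sx) // 2, (arr.shape[1] - sy) // 2
        out[ox:ox + sx, oy:oy + sy] = arr[ix:ix + sx, iy:iy + sy]
        arr = out
    return normalize(arr)
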
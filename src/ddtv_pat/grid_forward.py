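"""Discrete spherical-mean forward model for 2D photoacoustic tomography.

The integrated signal ``g_l(t_h)`` recorded at detector l is the line
integral of the absorption image A over the arc of radius ``c * t_h``
centered at the detector.  On a pixel grid this becomes a sparse linear map

    g = W A'

where ``A'`` is the row-major flattening of A and each matrix row carries
triangular interpolation weights ``1 - |t_h/dt - |r_l - r_m|/(c dt)||`` for
the pixels within one time bin of the arc.  The same stored matrix provides
the exact adjoint (image <- sinogram) used by the iterative solvers.

Units: lengths in mm, times in seconds, sound speed in m/s.  The physical
prefactor ``4*pi*C_p/beta`` relating pressure to the integrated signal is
folded to 1 (normalized units); reconstructed images are normalized to
[0, 1] before any comparison, so absolute amplitudes never matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import ScanGeometry

__all__ = [
    "ImageGrid",
    "AcousticSampling",
    "Sinogram",
    "WeightMatrix",
    "make_grid",
    "default_sampling",
    "arc_weight",
    "build_weight_matrix",
    "build_quadrature_matrix",
    "forward_project",
    "adjoint_project",
    "pressure_to_g",
]

log = logging.getLogger(__name__)

PRESSURE = "pressure_p"
INTEGRATED = "integrated_g"


@dataclass(frozen=True)
class ImageGrid:
    """Uniform pixel grid centered on the origin.

    Array axis 0 runs along x, axis 1 along y; pixel (i, j) is centered at
    ``((i - (n_x-1)/2) * pixel_mm, (j - (n_y-1)/2) * pixel_mm)``.  This
    row-major enumeration is the one flattening used everywhere the weight
    matrix is built or applied.
    """

    n_x: int
    n_y: int
    pixel_mm: float

    def __post_init__(self):
        if self.n_x < 1 or self.n_y < 1 or self.pixel_mm <= 0:
            raise ValueError("grid sizes and pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_x, self.n_y)

    @property
    def n_pixels(self) -> int:
        return self.n_x * self.n_y

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.n_x * self.pixel_mm, self.n_y * self.pixel_mm)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1D arrays of pixel-center coordinates along x and y (mm)."""
        x = (np.arange(self.n_x) - (self.n_x - 1) / 2) * self.pixel_mm
        y = (np.arange(self.n_y) - (self.n_y - 1) / 2) * self.pixel_mm
        return x, y

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.centers()
        return np.meshgrid(x, y, indexing="ij")


def make_grid(n_x: int, n_y: int, extent_mm: float) -> ImageGrid:
    """Grid of ``n_x x n_y`` pixels spanning ``extent_mm`` along x.

    The pixel pitch is ``extent_mm / n_x``; e.g. 128 pixels over 76.8 mm
    gives 0.6 mm pixels.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("n_x and n_y must be >= 1")
    if extent_mm <= 0:
        raise ValueError("extent_mm must be positive")
    return ImageGrid(n_x, n_y, extent_mm / n_x)


@dataclass(frozen=True)
class AcousticSampling:
    """Temporal sampling of the detected signals.

    Attributes
    ----------
    c : float
        Speed of sound in m/s (default 1500, homogeneous medium).
    dt : float
        Time step in seconds.
    n_samples : int
        Number of time samples S; sample h corresponds to ``t_h = h * dt``.
    """

    c: float
    dt: float
    n_samples: int

    def __post_init__(self):
        if self.c <= 0 or self.dt <= 0 or self.n_samples < 1:
            raise ValueError("c, dt must be positive and n_samples >= 1")

    @property
    def c_mm(self) -> float:
        """Sound speed in mm/s."""
        return self.c * 1e3

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def bin_mm(self) -> float:
        """Radial extent of one time bin, ``c * dt``, in mm."""
        return self.c_mm * self.dt


def default_sampling(grid: ImageGrid, geom: ScanGeometry, c: float = 1500.0,
                     dt: float | None = None) -> AcousticSampling:
    """Sampling that covers every detector-pixel distance.

    By default the time step is chosen so that one bin spans half a pixel
    (``c * dt = pixel_mm / 2``), i.e. the arc discretization is finer than
    the image discretization.
    """
    c_mm = c * 1e3
    if dt is None:
        dt = grid.pixel_mm / 2 / c_mm
    x, y = grid.centers()
    corners = np.array([[x[0], y[0]], [x[0], y[-1]], [x[-1], y[0]], [x[-1], y[-1]]])
    dmax = max(
        np.hypot(*(corner - pos)) for corner in corners for pos in geom.positions
    )
    n = int(np.ceil(dmax / (c_mm * dt))) + 2
    return AcousticSampling(c=c, dt=dt, n_samples=n)


@dataclass
class Sinogram:
    """Per-detector time series, in either the pressure or integrated domain.

    ``values`` has shape (M, S): one row per detector, one column per time
    sample.  ``domain`` tags whether the rows hold the raw pressure p or the
    integrated signal g (the arc integrals the forward model produces).
    """

    values: np.ndarray
    domain: str
    geometry: ScanGeometry
    sampling: AcousticSampling

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("sinogram values must be 2D (M, S)")
        if v.shape[0] != self.geometry.n_views:
            raise ValueError("sinogram rows must match the geometry's view count")
        if v.shape[1] != self.sampling.n_samples:
            raise ValueError("sinogram columns must match the sampling's n_samples")
        if self.domain not in (PRESSURE, INTEGRATED):
            raise ValueError(f"unknown sinogram domain {self.domain!r}")
        self.values = v

    def copy_with(self, values: np.ndarray, domain: str | None = None) -> "Sinogram":
        return Sinogram(values, domain or self.domain, self.geometry, self.sampling)

    # --- persistence -----------------------------------------------------
    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.attrs["domain"] = self.domain
            f.attrs["c"] = self.sampling.c
            f.attrs["dt"] = self.sampling.dt
            f.create_dataset("positions", data=self.geometry.positions)
            f.attrs["mode"] = self.geometry.mode
            if self.geometry.radius_mm is not None:
                f.attrs["radius_mm"] = self.geometry.radius_mm

    @staticmethod
    def load_h5(path) -> "Sinogram":
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][()]
            positions = f["positions"][()]
            mode = f.attrs["mode"]
            radius = float(f.attrs["radius_mm"]) if "radius_mm" in f.attrs else None
            geom = ScanGeometry(positions, str(mode), radius_mm=radius)
            sampling = AcousticSampling(
                c=float(f.attrs["c"]), dt=float(f.attrs["dt"]),
                n_samples=values.shape[1],
            )
            return Sinogram(values, str(f.attrs["domain"]), geom, sampling)


def arc_weight(t_h: float, dist: float, c: float, dt: float) -> float:
    """Triangular interpolation weight of a pixel for one (detector, bin).

    ``1 - |t_h/dt - dist/(c dt)|`` when the offset is below one bin, else 0.
    ``dist`` and ``c * t`` must share units (mm and mm/s, or any consistent
    pair).  Total function with range [0, 1].
    """
    off = abs(t_h / dt - dist / (c * dt))
    return float(max(0.0, 1.0 - off))


@dataclass
class WeightMatrix:
    """Sparse forward operator: rows are (detector, time-bin) samples.

    ``matrix`` has shape (M*S, n_pixels); applying it to the row-major
    flattened image gives the stacked integrated sinogram, and its transpose
    is the exact adjoint.
    """

    matrix: sp.csr_matrix
    geometry: ScanGeometry
    grid: ImageGrid
    sampling: AcousticSampling
    _spectral_norm: float | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def forward_values(self, A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        if A.shape != self.grid.shape:
            raise ValueError(f"image shape {A.shape} does not match grid {self.grid.shape}")
        out = self.matrix @ A.ravel()
        return out.reshape(self.geometry.n_views, self.sampling.n_samples)

    def adjoint_values(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        expected = (self.geometry.n_views, self.sampling.n_samples)
        if s.shape != expected:
            raise ValueError(f"sinogram shape {s.shape} does not match {expected}")
        out = self.matrix.T @ s.ravel()
        return out.reshape(self.grid.shape)

    def spectral_norm(self, seed: int = 0, n_iter: int = 20) -> float:
        """Largest singular value, estimated by seeded power iteration."""
        if self._spectral_norm is None:
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(self.matrix.shape[1])
            v /= np.linalg.norm(v)
            sigma2 = 0.0
            for _ in range(n_iter):
                w = self.matrix.T @ (self.matrix @ v)
                sigma2 = float(v @ w)
                nrm = np.linalg.norm(w)
                if nrm == 0:
                    break
                v = w / nrm
            self._spectral_norm = float(np.sqrt(max(sigma2, 0.0)))
        return self._spectral_norm

    @property
    def frobenius_norm(self) -> float:
        return float(sp.linalg.norm(self.matrix))


def build_weight_matrix(geom: ScanGeometry, grid: ImageGrid,
                        sampling: AcousticSampling,
                        subpixel: int = 1) -> WeightMatrix:
    """Assemble the sparse arc-interpolation system matrix.

    With ``subpixel = 1`` this is the classic triangular-interpolation
    matrix: each pixel (a point mass at its center) contributes to the at
    most two time bins bracketing its travel time to each detector, with
    the weights of :func:`arc_weight`.  ``subpixel = q`` splits every pixel
    into ``q x q`` equal point masses before binning, which sharpens the
    agreement with the continuous arc integral while keeping the same
    model form.  A warning is logged if some pixel's travel time exceeds
    the sampled window for any detector.
    """
    if subpixel < 1:
        raise ValueError("subpixel must be >= 1")
    X, Y = grid.meshgrid()
    n_pix = grid.n_pixels
    S = sampling.n_samples
    bin_mm = sampling.bin_mm
    pix = grid.pixel_mm
    offsets = (np.arange(subpixel) + 0.5) / subpixel - 0.5
    rows, cols, vals = [], [], []
    pix_idx = np.arange(n_pix)
    uncovered = False
    for l, (xl, yl) in enumerate(geom.positions):
        for ox in offsets:
            for oy in offsets:
                dist = np.hypot(X + ox * pix - xl, Y + oy * pix - yl).ravel()
                tau = dist / bin_mm  # fractional bin index of the arrival time
                h0 = np.floor(tau).astype(np.int64)
                frac = tau - h0
                if np.any(h0 > S - 1):
                    uncovered = True
                for h, w in ((h0, 1.0 - frac), (h0 + 1, frac)):
                    keep = (w > 0) & (h >= 0) & (h < S)
                    rows.append(l * S + h[keep])
                    cols.append(pix_idx[keep])
                    vals.append(w[keep] / subpixel**2)
    if uncovered:
        log.warning(
            "n_samples=%d does not cover every detector-pixel distance; "
            "distant pixels are invisible to the model", S,
        )
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_views * S, n_pix),
    ).tocsr()
    mat.sum_duplicates()
    return WeightMatrix(mat, geom, grid, sampling)


def build_quadrature_matrix(geom: ScanGeometry, grid: ImageGrid,
                            sampling: AcousticSampling,
                            upsample: int = 2) -> WeightMatrix:
    """Arc-quadrature system matrix with a bilinear pixel footprint.

    Discretizes the same spherical-mean integral as
    :func:`build_weight_matrix`, but by sampling each detection arc at
    sub-pixel steps (``pixel_mm / upsample``) and spreading every
    quadrature point over its four neighboring pixels with bilinear
    weights.  This converges to the continuous integral operator much
    faster than the triangular-binned matrix and is the default forward
    model for the reconstruction studies; the simulated measurements use
    the same quadrature at a finer resolution, so the reconstruction never
    inverts its own discretization exactly.
    """
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    n_x, n_y = grid.shape
    pix = grid.pixel_mm
    ds = pix / upsample
    S = sampling.n_samples
    radii = sampling.c_mm * sampling.times
    x0, y0 = grid.centers()
    half_x = x0[-1] + pix
    half_y = y0[-1] + pix
    scale = sampling.bin_mm / pix**2
    rows_all, cols_all, vals_all = [], [], []
    for l, (xl, yl) in enumerate(geom.positions):
        d_near = np.hypot(max(abs(xl) - half_x, 0.0), max(abs(yl) - half_y, 0.0))
        d_far = np.hypot(abs(xl) + half_x, abs(yl) + half_y)
        fi_l, fj_l, w_l, row_l = [], [], [], []
        for h in range(S):
            rho = radii[h]
            if rho <= 0 or rho < d_near or rho > d_far:
                continue
            n_ang = max(8, int(np.ceil(2 * np.pi * rho / ds)))
            ang = (np.arange(n_ang) + 0.5) * (2 * np.pi / n_ang)
            px = xl + rho * np.cos(ang)
            py = yl + rho * np.sin(ang)
            keep = (np.abs(px) <= half_x) & (np.abs(py) <= half_y)
            n_keep = int(keep.sum())
            if n_keep == 0:
                continue
            fi_l.append(px[keep])
            fj_l.append(py[keep])
            w_l.append(np.full(n_keep, rho * (2 * np.pi / n_ang) * scale))
            row_l.append(np.full(n_keep, l * S + h, dtype=np.int64))
        if not fi_l:
            continue
        fi = np.concatenate(fi_l) / pix + (n_x - 1) / 2
        fj = np.concatenate(fj_l) / pix + (n_y - 1) / 2
        w = np.concatenate(w_l)
        row = np.concatenate(row_l)
        i0 = np.floor(fi).astype(np.int64)
        j0 = np.floor(fj).astype(np.int64)
        di = fi - i0
        dj = fj - j0
        # scatter each quadrature point to its four bilinear neighbors
        for ii, wi in ((i0, 1 - di), (i0 + 1, di)):
            for jj, wj in ((j0, 1 - dj), (j0 + 1, dj)):
                ok = (ii >= 0) & (ii < n_x) & (jj >= 0) & (jj < n_y)
                wv = (wi * wj)[ok] * w[ok]
                nz = wv > 0
                rows_all.append(row[ok][nz].astype(np.int32))
                cols_all.append((ii[ok][nz] * n_y + jj[ok][nz]).astype(np.int32))
                vals_all.append(wv[nz])
    mat = sp.coo_matrix(
        (np.concatenate(vals_all),
         (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(geom.n_views * S, grid.n_pixels),
    ).tocsr()  # duplicate quadrature contributions are summed here
    return WeightMatrix(mat, geom, grid, sampling)


def forward_project(W: WeightMatrix, A: np.ndarray) -> Sinogram:
    """Apply the forward model: image -> integrated sinogram g."""
    return Sinogram(W.forward_values(A), INTEGRATED, W.geometry, W.sampling)


def adjoint_project(W: WeightMatrix, s: Sinogram) -> np.ndarray:
    """Apply the exact transpose: sinogram -> image (back-projection sum)."""
    return W.adjoint_values(s.values)


def pressure_to_g(p: Sinogram, sampling: AcousticSampling | None = None) -> Sinogram:
    """Integrate a pressure sinogram into the g domain.

    ``g_h = t_h * sum_{h' <= h} p_h' * dt`` (normalized units: the physical
    constant ``4 pi C_p / beta`` is folded to 1).
    """
    if p.domain != PRESSURE:
        raise ValueError("pressure_to_g expects a pressure_p sinogram")
    sampling = sampling or p.sampling
    t = sampling.times
    g = t[None, :] * np.cumsum(p.values, axis=1) * sampling.dt
    return p.copy_with(g, INTEGRATED)
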
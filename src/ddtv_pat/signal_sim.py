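"""Inverse-crime-free signal simulation and measurement noise.

The detector signals used to test the solvers are generated by dense arc
quadrature of the continuous spherical-mean integral — bilinear image
interpolation at sub-pixel resolution along each arc — rather than by the
sparse system matrix that the reconstruction itself uses.  The two
discretizations share only the governing integral, so reconstructing from
these signals does not commit the inverse crime.

Signals are expressed in the same normalized units as the system matrix.
A matrix row for time bin h sums triangular weights over the pixels near
the arc, which approximates ``arc_length * (c dt) / pixel_mm^2``; the
quadrature result (the arc line integral in mm) is therefore scaled by
``c dt / pixel_mm^2`` so that a high-resolution simulation converges to
``forward_project`` up to discretization error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import ScanGeometry
from .grid_forward import (
    INTEGRATED,
    PRESSURE,
    AcousticSampling,
    ImageGrid,
    Sinogram,
)

__all__ = [
    "NoiseSpec",
    "simulate_spherical_means",
    "differentiate_to_pressure",
    "add_noise",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian measurement noise.

    ``snr_db`` is the signal-to-noise ratio in dB measured against the mean
    signal power over all detectors jointly (one global noise level);
    ``np.inf`` disables the noise.  ``seed`` fixes the realization exactly.
    """

    snr_db: float
    seed: int = 0


def simulate_spherical_means(
    A: np.ndarray,
    grid: ImageGrid,
    geom: ScanGeometry,
    sampling: AcousticSampling,
    upsample: int = 4,
) -> Sinogram:
    """Integrate the image over detection arcs by dense quadrature.

    For every detector and time bin the circle of radius ``c * t_h`` is
    sampled at arc-length steps of ``pixel_mm / upsample`` and the image is
    evaluated by bilinear interpolation (zero outside the grid).  The sum
    times the step length gives the arc line integral, reported in
    system-matrix units (scaled by ``c dt / pixel_mm**2``).

    Parameters
    ----------
    upsample : int
        Sub-pixel quadrature refinement (>= 2).
    """
    if upsample < 2:
        raise ValueError("upsample must be >= 2 for sub-pixel quadrature")
    A = np.asarray(A, dtype=float)
    if A.shape != grid.shape:
        raise ValueError(f"image shape {A.shape} does not match grid {grid.shape}")

    pix = grid.pixel_mm
    ds = pix / upsample
    x0, y0 = grid.centers()
    half_x = x0[-1] + pix  # one-pixel margin for the bilinear support
    half_y = y0[-1] + pix
    S = sampling.n_samples
    radii = sampling.c_mm * sampling.times
    out = np.zeros((geom.n_views, S))
    # zero-pad so boundary tents interpolate correctly instead of being
    # clipped by the interpolator's constant mode
    A_pad = np.pad(A, 1)

    for l, (xl, yl) in enumerate(geom.positions):
        # radii that can intersect the (margin-padded) grid rectangle
        d_near = np.hypot(max(abs(xl) - half_x, 0.0), max(abs(yl) - half_y, 0.0))
        d_far = np.hypot(abs(xl) + half_x, abs(yl) + half_y)
        pts_i, pts_j, offsets, bins = [], [], [0], []
        for h in range(S):
            rho = radii[h]
            if rho <= 0 or rho < d_near or rho > d_far:
                continue
            n_ang = max(8, int(np.ceil(2 * np.pi * rho / ds)))
            ang = (np.arange(n_ang) + 0.5) * (2 * np.pi / n_ang)
            px = xl + rho * np.cos(ang)
            py = yl + rho * np.sin(ang)
            keep = (np.abs(px) <= half_x) & (np.abs(py) <= half_y)
            if not keep.any():
                continue
            pts_i.append(px[keep] / pix + (grid.n_x - 1) / 2)
            pts_j.append(py[keep] / pix + (grid.n_y - 1) / 2)
            offsets.append(offsets[-1] + int(keep.sum()))
            bins.append((h, rho * 2 * np.pi / n_ang))
        if not bins:
            continue
        ci = np.concatenate(pts_i) + 1.0  # shift into the padded frame
        cj = np.concatenate(pts_j) + 1.0
        vals = map_coordinates(A_pad, [ci, cj], order=1, mode="constant", cval=0.0)
        sums = np.add.reduceat(vals, offsets[:-1]) if len(offsets) > 1 else []
        scale = sampling.bin_mm / pix**2
        for (h, dl), ssum in zip(bins, sums):
            out[l, h] = ssum * dl * scale

    return Sinogram(out, INTEGRATED, geom, sampling)


def differentiate_to_pressure(g: Sinogram,
                              sampling: AcousticSampling | None = None) -> Sinogram:
    """Recover the pressure trace from an integrated sinogram.

    Inverts ``g = t * cumulative_integral(p)``: divides by ``t_h`` (zero at
    t = 0) and takes the backward finite difference.  The round trip with
    the forward integration is exact up to quadrature error O(dt).
    """
    if g.domain != INTEGRATED:
        raise ValueError("differentiate_to_pressure expects an integrated_g sinogram")
    sampling = sampling or g.sampling
    t = sampling.times
    cum = np.zeros_like(g.values)
    cum[:, 1:] = g.values[:, 1:] / t[1:][None, :]
    p = np.zeros_like(g.values)
    p[:, 1:] = np.diff(cum, axis=1) / sampling.dt
    return g.copy_with(p, PRESSURE)


def add_noise(s: Sinogram, spec: NoiseSpec) -> Sinogram:
    """Add seeded white Gaussian noise at the requested global SNR.

    The noise variance is ``mean(s**2) / 10**(snr_db / 10)`` over the whole
    sinogram.  ``snr_db = inf`` returns the input unchanged.
    """
    if np.isinf(spec.snr_db):
        return s.copy_with(s.values.copy())
    power = float(np.mean(s.values**2))
    if power == 0:
        raise ValueError("cannot set a finite SNR on an all-zero sinogram")
    sigma = np.sqrt(power / 10 ** (spec.snr_db / 10))
    rng = np.random.default_rng(spec.seed)
    noisy = s.values + rng.normal(0.0, sigma, size=s.values.shape)
    return s.copy_with(noisy)
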
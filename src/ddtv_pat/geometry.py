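"""Detector scan geometries for 2D photoacoustic tomography.

All positions live in a common image-centered frame: origin at the center of
the imaging region, x rightward, y upward, angles counter-clockwise from +x,
lengths in millimetres.  Point-like (omnidirectional) detectors are assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanGeometry", "circular_scan", "linear_scan"]

#: valid scan modes
MODES = ("circular", "limited_view", "linear")


@dataclass(frozen=True)
class ScanGeometry:
    """Ordered detector positions with scan-mode metadata.

    Parameters
    ----------
    positions : (M, 2) ndarray
        Detector coordinates in mm, image-centered frame.
    mode : {"circular", "limited_view", "linear"}
    radius_mm : float or None
        Scan radius for the circular modes; ``None`` for linear scans.
    """

    positions: np.ndarray
    mode: str
    radius_mm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError("positions must be an (M, 2) array with M >= 1")
        object.__setattr__(self, "positions", pos)
        if self.mode not in MODES:
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.mode in ("circular", "limited_view"):
            if self.radius_mm is None:
                raise ValueError("circular modes require radius_mm")
            r = np.hypot(pos[:, 0], pos[:, 1])
            if not np.allclose(r, self.radius_mm, atol=1e-9):
                raise ValueError("circular positions must lie on the scan radius")

    @property
    def n_views(self) -> int:
        return self.positions.shape[0]

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "n_views": self.n_views}
        if self.radius_mm is not None:
            d["radius_mm"] = float(self.radius_mm)
        d.update(self.meta)
        return d


def circular_scan(
    n_views: int,
    radius_mm: float,
    start_angle_deg: float = 0.0,
    arc_deg: float = 360.0,
) -> ScanGeometry:
    """Detectors uniformly spaced on a circular arc.

    The angular step is ``arc_deg / n_views`` (half-open arc), so a full
    360 deg scan with 30 views has 12 deg spacing and a 120 deg arc with 30
    views has 4 deg spacing, without a duplicated endpoint.

    Parameters
    ----------
    n_views : int
        Number of detection points M (>= 1).
    radius_mm : float
        Scan radius (> 0).
    start_angle_deg : float
        Angle of the first detector, CCW from +x.
    arc_deg : float
        Angular extent of the scan, in (0, 360].
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if not 0 < arc_deg <= 360:
        raise ValueError("arc_deg must lie in (0, 360]")
    angles = np.deg2rad(start_angle_deg + arc_deg * np.arange(n_views) / n_views)
    pos = radius_mm * np.column_stack([np.cos(angles), np.sin(angles)])
    mode = "circular" if arc_deg == 360 else "limited_view"
    meta = {"start_angle_deg": float(start_angle_deg), "arc_deg": float(arc_deg)}
    return ScanGeometry(pos, mode, radius_mm=float(radius_mm), meta=meta)


def linear_scan(
    n_points: int,
    length_mm: float,
    offset: tuple[float, float] = (0.0, -50.0),
    direction: tuple[float, float] = (1.0, 0.0),
) -> ScanGeometry:
    """Detectors uniformly spaced on a straight segment.

    Endpoints are inclusive: spacing = ``length_mm / (n_points - 1)``, so 41
    points over 40 mm gives a 1 mm sampling interval.

    Parameters
    ----------
    n_points : int
        Number of detection points (>= 2).
    length_mm : float
        Total scan length (> 0), endpoints included.
    offset : (2,) tuple
        Center of the scan segment, mm.
    direction : (2,) tuple
        Direction of the segment (normalized internally).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2 for a linear scan")
    if length_mm <= 0:
        raise ValueError("length_mm must be positive")
    d = np.asarray(direction, dtype=float)
    nrm = np.hypot(*d)
    if nrm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / nrm
    s = np.linspace(-length_mm / 2, length_mm / 2, n_points)
    pos = np.asarray(offset, dtype=float)[None, :] + s[:, None] * d[None, :]
    meta = {"length_mm": float(length_mm), "offset": tuple(map(float, offset)),
            "direction": tuple(map(float, d))}
    return ScanGeometry(pos, "linear", radius_mm=None, meta=meta)
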
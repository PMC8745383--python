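"""Astigmatic 3D localization.

A cylindrical lens in the emission path makes the PSF widths along x
and y depend on the emitter's axial position z in opposite senses; a
width-vs-z calibration then turns an elliptical fit (sigma_x, sigma_y)
into a z estimate.  The defocus model per axis is a quartic-extended
hyperbola

    sigma(z) = sigma0 * sqrt(1 + u^2 + A u^3 + B u^4),  u = (z - c) / d

with focal width sigma0 (px), focal offset c (nm), depth scale d (nm),
and optional higher-order terms A, B (0 by default).  The crossing
point sigma_x = sigma_y defines z = 0.

z estimation minimizes the root-sigma distance

    D(z) = (sqrt(sx) - sqrt(sx_cal(z)))^2 + (sqrt(sy) - sqrt(sy_cal(z)))^2

over a dense 1 nm grid with parabolic refinement; deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "AstigCalibration",
    "Localization3D",
    "default_calibration",
    "fit_calibration",
    "z_lookup",
    "axial_precision",
    "reconstruct_3d",
]


def _defocus(z, sigma0, c, d, A=0.0, B=0.0):
    u = (np.asarray(z, dtype=float) - c) / d
    val = 1.0 + u * u + A * u ** 3 + B * u ** 4
    return sigma0 * np.sqrt(np.maximum(val, 1e-12))


@dataclass(frozen=True)
class AstigCalibration:
    """Per-axis defocus parameters; widths in px, z in nm."""

    sigma0_x: float = 1.3
    c_x: float = -200.0
    d_x: float = 400.0
    sigma0_y: float = 1.3
    c_y: float = 200.0
    d_y: float = 400.0
    A_x: float = 0.0
    B_x: float = 0.0
    A_y: float = 0.0
    B_y: float = 0.0
    z_range: tuple[float, float] = (-500.0, 500.0)

    def sigma_x(self, z):
        return _defocus(z, self.sigma0_x, self.c_x, self.d_x, self.A_x, self.B_x)

    def sigma_y(self, z):
        return _defocus(z, self.sigma0_y, self.c_y, self.d_y, self.A_y, self.B_y)

    def __post_init__(self):
        zlo, zhi = self.z_range
        zz = np.linspace(zlo, zhi, 257)
        sx, sy = self.sigma_x(zz), self.sigma_y(zz)
        if np.any(sx <= 0) or np.any(sy <= 0):
            raise ValueError("calibration widths must stay positive over z_range")
        sign = np.sign(sx - sy)
        nz = sign[sign != 0]
        n_cross = int((np.diff(nz) != 0).sum())
        if n_cross != 1:
            raise ValueError(
                f"calibration must have exactly one sigma_x = sigma_y crossing "
                f"in z_range, found {n_cross}")

    def crossing_z(self) -> float:
        zlo, zhi = self.z_range
        f = lambda z: float(self.sigma_x(z) - self.sigma_y(z))
        return brentq(f, zlo, zhi)


def default_calibration() -> AstigCalibration:
    return AstigCalibration()


@dataclass
class Localization3D:
    x: float           # nm
    y: float
    z: float
    precision_xy: float
    precision_z: float
    intensity: float
    frame: int = 0


def fit_calibration(
    zs: Sequence[float],
    sigma_x: Sequence[float],
    sigma_y: Sequence[float],
    fit_higher_order: bool = False,
    z_range: Optional[tuple[float, float]] = None,
) -> AstigCalibration:
    """Least-squares fit of the defocus model to measured bead widths at
    known z planes.  The fitted calibration is re-centered so the
    sigma_x = sigma_y crossing sits at z = 0."""
    zs = np.asarray(zs, dtype=float)
    if zs.size < 7:
        raise ValueError("need at least 7 z planes to calibrate")
    if z_range is None:
        z_range = (float(zs.min()), float(zs.max()))

    def fit_axis(widths):
        widths = np.asarray(widths, dtype=float)
        s0 = float(widths.min())
        c0 = float(zs[int(np.argmin(widths))])
        d0 = (zs.max() - zs.min()) / 2.0
        if fit_higher_order:
            p0 = [s0, c0, d0, 0.0, 0.0]
            fun = lambda p: _defocus(zs, p[0], p[1], p[2], p[3], p[4]) - widths
        else:
            p0 = [s0, c0, d0]
            fun = lambda p: _defocus(zs, p[0], p[1], p[2]) - widths
        sol = least_squares(fun, p0, method="trf")
        p = list(sol.x)
        if not fit_higher_order:
            p += [0.0, 0.0]
        return p

    px = fit_axis(sigma_x)
    py = fit_axis(sigma_y)
    calib = AstigCalibration(
        sigma0_x=px[0], c_x=px[1], d_x=px[2], A_x=px[3], B_x=px[4],
        sigma0_y=py[0], c_y=py[1], d_y=py[2], A_y=py[3], B_y=py[4],
        z_range=z_range,
    )
    z0 = calib.crossing_z()
    zlo, zhi = z_range
    return AstigCalibration(
        sigma0_x=px[0], c_x=px[1] - z0, d_x=px[2], A_x=px[3], B_x=px[4],
        sigma0_y=py[0], c_y=py[1] - z0, d_y=py[2], A_y=py[3], B_y=py[4],
        z_range=(zlo - z0, zhi - z0),
    )


def z_lookup(
    sigma_x: float,
    sigma_y: float,
    calib: AstigCalibration,
    grid_step: float = 1.0,
) -> tuple[float, bool]:
    """Axial position minimizing the root-sigma distance to the
    calibration curves.

    Returns ``(z_nm, in_range)``; ``in_range`` is False when the
    minimum sits on the boundary of the calibrated range.
    """
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("widths must be positive")
    zlo, zhi = calib.z_range
    zz = np.arange(zlo, zhi + grid_step, grid_step)
    dx = np.sqrt(sigma_x) - np.sqrt(calib.sigma_x(zz))
    dy = np.sqrt(sigma_y) - np.sqrt(calib.sigma_y(zz))
    D = dx * dx + dy * dy
    i = int(np.argmin(D))
    if i == 0 or i == len(zz) - 1:
        return float(zz[i]), False
    # parabolic refinement through the three points around the minimum
    y0, y1, y2 = D[i - 1], D[i], D[i + 1]
    denom = y0 - 2 * y1 + y2
    off = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-300 else 0.0
    return float(zz[i] + off * grid_step), True


def axial_precision(spot, context, calib: AstigCalibration, z: float) -> float:
    """Axial precision (nm) propagated from the per-axis width
    uncertainties through the calibration slopes:

        var(z) = 1 / [ (dsx/dz)^2 / var(sx) + (dsy/dz)^2 / var(sy) ]
    """
    from .psffit import width_variance

    eps = 1.0
    dsx = float(calib.sigma_x(z + eps) - calib.sigma_x(z - eps)) / (2 * eps)
    dsy = float(calib.sigma_y(z + eps) - calib.sigma_y(z - eps)) / (2 * eps)
    vx = width_variance(spot, context, float(spot.sigma_x))
    vy = width_variance(spot, context, float(spot.sigma_y))
    info = dsx * dsx / vx + dsy * dsy / vy
    if info <= 0:
        return float("inf")
    return math.sqrt(1.0 / info)


def reconstruct_3d(
    fits,
    calib: AstigCalibration,
    context,
) -> tuple[list[Localization3D], int]:
    """Turn converged elliptical fits into 3D localizations in nm.

    Accepts an iterable of :class:`smls.psffit.SpotFit` with elliptical
    widths.  Spots whose z estimate hits the calibration boundary are
    dropped; the second return value counts them.
    """
    from .psffit import localization_precision

    out: list[Localization3D] = []
    n_dropped = 0
    for spot in fits:
        if not getattr(spot, "converged", True):
            continue
        if spot.sigma_x is None or spot.sigma_y is None:
            raise ValueError("reconstruct_3d requires elliptical fits")
        z, ok = z_lookup(float(spot.sigma_x), float(spot.sigma_y), calib)
        if not ok:
            n_dropped += 1
            continue
        prec_xy, _ = localization_precision(spot, context)
        prec_z = axial_precision(spot, context, calib, z)
        out.append(Localization3D(
            x=spot.x * context.pixel_size,
            y=spot.y * context.pixel_size,
            z=z,
            precision_xy=prec_xy,
            precision_z=prec_z,
            intensity=spot.intensity,
            frame=getattr(spot, "frame_index", 0),
        ))
    return out, n_dropped
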
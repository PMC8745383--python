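"""Sub-pixel spot parametrization by least-squares fitting of a
pixel-integrated Gaussian point-spread-function model.

The expected value of pixel ``(i, j)`` (row ``i`` spanning ``[i, i+1)`` in
y, column ``j`` spanning ``[j, j+1)`` in x) for an emitter at continuous
position ``(x, y)`` with integrated intensity ``C`` over a flat background
``B`` is

    mu_ij = B + C * [Phi((j+1-x)/sx) - Phi((j-x)/sx)]
              * [Phi((i+1-y)/sy) - Phi((i-y)/sy)]

where ``Phi`` is the standard normal CDF, expressed via the error
function.  Summed over the whole plane the model mass is exactly
``C + B * area``, so ``C`` is the spot's total signal in camera counts —
the quantity the downstream stoichiometry analysis works with.

Fitting uses a rectangular trust-region dogleg optimizer
(``scipy.optimize.least_squares``, ``method="dogbox"``) with an analytic
Jacobian; the cost is unweighted least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

_SQRT2 = math.sqrt(2.0)

__all__ = [
    "SpotFit",
    "pixel_mass_1d",
    "psf_model",
    "fit_spot",
    "fit_spot_elliptical",
    "fit_spots",
    "localization_precision",
]


@dataclass
class SpotFit:
    """One fitted emitter, in the pixel coordinates of the fitted array."""

    x: float
    y: float
    sigma: float                      # symmetric width; for elliptical fits the geometric mean
    intensity: float                  # integrated signal C above background (counts)
    background: float                 # counts / pixel
    residual_norm: float
    n_iterations: int
    converged: bool
    sigma_x: Optional[float] = None   # set for elliptical fits only
    sigma_y: Optional[float] = None
    sigma_at_bound: bool = False
    frame_index: int = 0
    _jac_cov: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def elliptical(self) -> bool:
        return self.sigma_x is not None


def pixel_mass_1d(edges_lo: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Mass of a 1D Gaussian(center, sigma) over unit pixels starting at
    ``edges_lo`` (each pixel spans [e, e+1))."""
    a = (edges_lo - center) / (sigma * _SQRT2)
    b = (edges_lo + 1.0 - center) / (sigma * _SQRT2)
    return 0.5 * (erf(b) - erf(a))


def psf_model(
    x: float,
    y: float,
    sigma: float | tuple[float, float],
    intensity: float,
    background: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Expected pixel values of one emitter over a ``shape = (rows, cols)``
    window whose pixel (0, 0) spans [0,1) x [0,1).

    ``sigma`` may be a scalar (symmetric PSF) or ``(sigma_x, sigma_y)``.
    """
    rows, cols = shape
    if np.isscalar(sigma):
        sx = sy = float(sigma)
    else:
        sx, sy = sigma
    mx = pixel_mass_1d(np.arange(cols, dtype=float), x, sx)
    my = pixel_mass_1d(np.arange(rows, dtype=float), y, sy)
    return background + intensity * np.outer(my, mx)


def _gauss_pdf_diff(edges_lo: np.ndarray, center: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """phi at lower/upper pixel edges for Jacobian terms."""
    lo = (edges_lo - center) / sigma
    hi = (edges_lo + 1.0 - center) / sigma
    phi_lo = np.exp(-0.5 * lo * lo) / (sigma * math.sqrt(2 * math.pi))
    phi_hi = np.exp(-0.5 * hi * hi) / (sigma * math.sqrt(2 * math.pi))
    return phi_lo, phi_hi, lo, hi


def _residual_and_jac(params, data, shape, elliptical):
    rows, cols = shape
    jx = np.arange(cols, dtype=float)
    iy = np.arange(rows, dtype=float)
    if elliptical:
        x, y, sx, sy, c, b = params
    else:
        x, y, s, c, b = params
        sx = sy = s
    mx = pixel_mass_1d(jx, x, sx)
    my = pixel_mass_1d(iy, y, sy)
    model = b + c * np.outer(my, mx)
    res = (model - data).ravel()

    phx_lo, phx_hi, ux_lo, ux_hi = _gauss_pdf_diff(jx, x, sx)
    phy_lo, phy_hi, uy_lo, uy_hi = _gauss_pdf_diff(iy, y, sy)
    dmx_dx = phx_lo - phx_hi                       # d/dx of x-axis mass
    dmy_dy = phy_lo - phy_hi
    dmx_dsx = ux_lo * phx_lo - ux_hi * phx_hi      # d/dsigma of x-axis mass
    dmy_dsy = uy_lo * phy_lo - uy_hi * phy_hi

    d_dx = c * np.outer(my, dmx_dx)
    d_dy = c * np.outer(dmy_dy, mx)
    d_dc = np.outer(my, mx)
    d_db = np.ones_like(model)
    if elliptical:
        d_dsx = c * np.outer(my, dmx_dsx)
        d_dsy = c * np.outer(dmy_dsy, mx)
        jac = np.stack(
            [d_dx.ravel(), d_dy.ravel(), d_dsx.ravel(), d_dsy.ravel(),
             d_dc.ravel(), d_db.ravel()], axis=1)
    else:
        d_ds = c * (np.outer(my, dmx_dsx) + np.outer(dmy_dsy, mx))
        jac = np.stack(
            [d_dx.ravel(), d_dy.ravel(), d_ds.ravel(),
             d_dc.ravel(), d_db.ravel()], axis=1)
    return res, jac


def _fit(
    window: np.ndarray,
    x0: float,
    y0: float,
    sigma0: float,
    c0: Optional[float],
    b0: Optional[float],
    elliptical: bool,
    tol: float,
    max_iter: int,
):
    window = np.asarray(window, dtype=float)
    rows, cols = window.shape
    if rows < 7 or cols < 7:
        raise ValueError("fit window must be at least 7x7 pixels")
    if not (0 <= x0 <= cols and 0 <= y0 <= rows):
        raise ValueError("initial position outside the window")
    if b0 is None:
        b0 = float(np.median(window))
    if c0 is None:
        c0 = float(max(window.sum() - b0 * window.size, 1.0))

    sig_lo, sig_hi = 0.5 * sigma0, 3.0 * sigma0
    if elliptical:
        p0 = [x0, y0, sigma0, sigma0, c0, b0]
        lo = [-1.0, -1.0, sig_lo, sig_lo, 0.0, -np.inf]
        hi = [cols + 1.0, rows + 1.0, sig_hi, sig_hi, np.inf, np.inf]
    else:
        p0 = [x0, y0, sigma0, c0, b0]
        lo = [-1.0, -1.0, sig_lo, 0.0, -np.inf]
        hi = [cols + 1.0, rows + 1.0, sig_hi, np.inf, np.inf]

    def fun(p):
        return _residual_and_jac(p, window, (rows, cols), elliptical)[0]

    def jac(p):
        return _residual_and_jac(p, window, (rows, cols), elliptical)[1]

    sol = least_squares(
        fun, p0, jac=jac, bounds=(lo, hi), method="dogbox",
        ftol=tol, xtol=1e-8, gtol=1e-12, max_nfev=max_iter * (len(p0) + 1),
    )
    # covariance of the estimate from the Jacobian at the solution
    jtj = sol.jac.T @ sol.jac
    dof = max(window.size - len(p0), 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = None

    if elliptical:
        x, y, sx, sy, c, b = sol.x
        at_bound = (
            math.isclose(sx, sig_lo) or math.isclose(sx, sig_hi)
            or math.isclose(sy, sig_lo) or math.isclose(sy, sig_hi)
        )
        return SpotFit(
            x=x, y=y, sigma=math.sqrt(sx * sy), intensity=c, background=b,
            residual_norm=math.sqrt(2 * sol.cost), n_iterations=sol.nfev,
            converged=bool(sol.success) and not at_bound,
            sigma_x=sx, sigma_y=sy, sigma_at_bound=at_bound, _jac_cov=cov,
        )
    x, y, s, c, b = sol.x
    at_bound = math.isclose(s, sig_lo) or math.isclose(s, sig_hi)
    return SpotFit(
        x=x, y=y, sigma=s, intensity=c, background=b,
        residual_norm=math.sqrt(2 * sol.cost), n_iterations=sol.nfev,
        converged=bool(sol.success) and not at_bound,
        sigma_at_bound=at_bound, _jac_cov=cov,
    )


def fit_spot(
    window: np.ndarray,
    x0: float,
    y0: float,
    sigma0: float,
    c0: Optional[float] = None,
    b0: Optional[float] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SpotFit:
    """Least-squares fit of a symmetric pixel-integrated Gaussian to a
    window.  Positions are in the window's own pixel coordinates."""
    return _fit(window, x0, y0, sigma0, c0, b0, False, tol, max_iter)


def fit_spot_elliptical(
    window: np.ndarray,
    x0: float,
    y0: float,
    sigma0: float,
    c0: Optional[float] = None,
    b0: Optional[float] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SpotFit:
    """As :func:`fit_spot` with independent widths along x and y
    (astigmatic PSF)."""
    return _fit(window, x0, y0, sigma0, c0, b0, True, tol, max_iter)


def default_window_size(sigma_prior: float) -> int:
    """4*sigma radius rounded up to the next odd span."""
    w = int(math.ceil(4.0 * sigma_prior))
    return 2 * w + 1


def fit_spots(
    frame: np.ndarray,
    candidates,
    sigma_prior: float,
    window_size: Optional[int] = None,
    elliptical: bool = False,
    frame_index: int = 0,
) -> list[SpotFit]:
    """Fit every candidate on a frame; returns fits in frame coordinates.

    Candidates closer than half a window to the edge are dropped.  Fits
    that fail the quality filters (non-converged, width at its bounds,
    non-positive intensity) are returned with ``converged=False`` so
    callers can log them; downstream consumers should keep converged
    fits only.
    """
    frame = np.asarray(frame, dtype=float)
    if window_size is None:
        window_size = default_window_size(sigma_prior)
    half = window_size // 2
    out: list[SpotFit] = []
    for cand in candidates:
        r, c = int(cand.row), int(cand.col)
        if not (half <= r < frame.shape[0] - half and half <= c < frame.shape[1] - half):
            continue
        win = frame[r - half: r + half + 1, c - half: c + half + 1]
        b0 = getattr(cand, "local_background", None)
        fitter = fit_spot_elliptical if elliptical else fit_spot
        fit = fitter(win, half + 0.5, half + 0.5, sigma_prior, b0=b0)
        fit.x += c - half
        fit.y += r - half
        fit.frame_index = frame_index
        if fit.intensity <= 0:
            fit.converged = False
        out.append(fit)
    return out


def _noise_terms(spot: SpotFit, context) -> tuple[float, float]:
    """(effective photon count N, background noise variance per pixel b^2
    in photons).  The fitted background includes the camera baseline
    offset, which contributes no noise and is subtracted."""
    gain_per_photon = context.em_gain / context.photons_per_count
    n_photons = max(spot.intensity / gain_per_photon, 1e-12)
    excess = 2.0 if getattr(context, "excess_noise", False) else 1.0
    n_eff = n_photons / excess
    baseline = getattr(context, "baseline", 0.0)
    bg_photons = max(spot.background - baseline, 0.0) / gain_per_photon
    b2 = bg_photons + (context.read_noise_sd / gain_per_photon) ** 2
    return n_eff, b2


def localization_precision(spot: SpotFit, context) -> tuple[float, Optional[float]]:
    """Per-spot lateral localization precision estimate in nm.

    Variance-of-estimator form for unweighted least-squares fitting,
    combining photon count, PSF width, pixelation and background noise
    (Mortensen's least-squares variant of the Thompson formula):

        sa^2   = s^2 + a^2/12
        tau    = 2*pi*sa^2*b^2 / (N*a^2)
        var_xy = sa^2/N * (16/9 + 4*tau)

    with ``s`` the PSF width in nm, ``a`` the pixel size in nm, ``N`` the
    (excess-noise-corrected) photon count and ``b^2`` the background
    noise variance per pixel in photons.  Axial precision for elliptical
    fits is propagated from the per-axis width uncertainties through the
    calibration-curve slope by :func:`smls.localize3d.axial_precision`.

    Returns ``(lateral_sd_nm, None)``; axial is attached by the 3D stage.
    """
    a = context.pixel_size
    n_eff, b2 = _noise_terms(spot, context)
    s = spot.sigma * a
    sa2 = s * s + a * a / 12.0
    tau = 2 * math.pi * sa2 * b2 / (n_eff * a * a)
    var = sa2 / n_eff * (16.0 / 9.0 + 4.0 * tau)
    return math.sqrt(var), None


def width_variance(spot: SpotFit, context, sigma_px: float) -> float:
    """Variance (px^2) of a fitted PSF width along one axis: half the
    position variance with the same pixelation and background
    corrections (the Fisher information for a Gaussian's width is twice
    that for its center)."""
    n_eff, b2 = _noise_terms(spot, context)
    sa2 = sigma_px * sigma_px + 1.0 / 12.0
    tau = 2 * math.pi * sa2 * b2 / n_eff
    return sa2 / (2.0 * n_eff) * (16.0 / 9.0 + 4.0 * tau)
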
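"""Synthetic single-molecule data with known ground truth.

Emulates sparse diffraction-limited spots on an EMCCD: each spot's
integrated signal is the sum of ``n`` independent single-fluorophore
signals, with ``n`` drawn from a copy-number mixture (the generative twin
of the degree-of-labeling weights recovered by
:mod:`smls.stoichiometry`).  Frames are rendered with the same
pixel-integrated Gaussian PSF the fitter assumes, and the camera chain is

    Poisson(expected photons) -> x em_gain -> + read noise -> + baseline

Defaults mirror the acquisition regime the analysis targets: 100 nm
pixels, 5 ms illumination at 3.2 kW/cm^2, single GFP integrated signal
157 +/- 65 counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .psffit import pixel_mass_1d

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionContext",
    "FluorophoreModel",
    "TailPolicy",
    "MixtureSpec",
    "GroundTruthSpot",
    "Frame",
    "GFP_CONTEXT",
    "JF646_CONTEXT",
    "GFP_MODEL",
    "CRISPR_EV_WEIGHTS",
    "OE_EV_WEIGHTS",
    "sample_copy_numbers",
    "sample_spot_intensity",
    "sample_intensities",
    "render_frame",
    "render_astig_frame",
    "scatter_positions",
]


@dataclass(frozen=True)
class AcquisitionContext:
    """Optical and camera metadata needed for cross-condition
    normalization and noise simulation.

    pixel_size nm/px; t_ill ms; laser_intensity kW/cm^2; read_noise_sd
    and baseline in camera counts; photons_per_count converts counts to
    photons at unit gain.
    """

    pixel_size: float = 100.0
    t_ill: float = 5.0
    laser_intensity: float = 3.2
    em_gain: float = 1.0
    read_noise_sd: float = 0.7
    baseline: float = 100.0
    photons_per_count: float = 1.0
    excess_noise: bool = False   # optional EM excess-noise factor (x2 variance)

    def __post_init__(self):
        for name in ("pixel_size", "t_ill", "laser_intensity", "em_gain", "photons_per_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.read_noise_sd < 0 or self.baseline < 0:
            raise ValueError("read_noise_sd and baseline must be >= 0")


GFP_CONTEXT = AcquisitionContext()
JF646_CONTEXT = AcquisitionContext(t_ill=10.0, laser_intensity=4.4)


def _truncnorm_parent(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated Normal whose truncated
    mean and sd equal the requested values."""
    from scipy.optimize import fsolve

    def eqs(p):
        mu, sig = p
        sig = abs(sig)
        d = stats.truncnorm(-mu / sig, np.inf, loc=mu, scale=sig)
        return [d.mean() - mean, d.std() - sd]

    sol, _, ok, _ = fsolve(eqs, [mean, sd], full_output=True)
    if ok != 1:
        return mean, sd
    return float(sol[0]), float(abs(sol[1]))


@dataclass(frozen=True)
class FluorophoreModel:
    """Single-fluorophore integrated-signal distribution: a Normal
    truncated at zero whose post-truncation mean and sd equal the
    reported ``mean_signal`` and ``sd_signal`` (the reported moments are
    of the observed, necessarily nonnegative, signal)."""

    mean_signal: float = 157.0
    sd_signal: float = 65.0
    reference_context: AcquisitionContext = GFP_CONTEXT

    def __post_init__(self):
        if self.mean_signal <= 0:
            raise ValueError("mean_signal must be > 0")
        if self.sd_signal < 0:
            raise ValueError("sd_signal must be >= 0")
        if self.sd_signal > 0:
            mu, sig = _truncnorm_parent(self.mean_signal, self.sd_signal)
        else:
            mu, sig = self.mean_signal, 0.0
        object.__setattr__(self, "_parent", (mu, sig))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Independent truncated-at-zero Normal draws."""
        mu, sig = self._parent
        if sig == 0:
            return np.full(size, mu)
        return stats.truncnorm.rvs(
            -mu / sig, np.inf, loc=mu, scale=sig, size=size, random_state=rng,
        )


GFP_MODEL = FluorophoreModel()


@dataclass(frozen=True)
class TailPolicy:
    """How the open-ended ">= n_max" copy-number class is realized when
    sampling: a fixed copy number, or uniform over a small range."""

    kind: str = "uniform"          # "fixed" | "uniform"
    n: int = 4                     # fixed value, or lower edge of the range
    span: int = 2                  # uniform over {n, ..., n + span}

    def realize(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, self.n, dtype=int)
        if self.kind == "uniform":
            return rng.integers(self.n, self.n + self.span + 1, size=size)
        raise ValueError(f"unknown tail policy kind {self.kind!r}")


@dataclass(frozen=True)
class MixtureSpec:
    """Copy-number mixture: ``copy_weights[k]`` is the probability of
    ``k+1`` copies; the last class is the open ">=" class realized by
    ``tail_policy``."""

    copy_weights: tuple[float, ...]
    tail_policy: TailPolicy = field(default=None)  # default set in __post_init__

    def __post_init__(self):
        w = np.asarray(self.copy_weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("copy_weights must be a non-empty 1D sequence")
        if np.any(w < 0):
            raise ValueError("copy_weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("copy_weights must sum to 1 within 1e-12")
        object.__setattr__(self, "copy_weights", tuple(w))
        if self.tail_policy is None:
            object.__setattr__(self, "tail_policy", TailPolicy(n=len(w)))

    @property
    def n_classes(self) -> int:
        return len(self.copy_weights)


# Degree-of-labeling compositions of the two EV populations under study:
# genome-edited (CRISPR) EVs are predominantly single-labeled; over-
# expression (OE) EVs carry a heavy multi-label tail.
CRISPR_EV_WEIGHTS = (0.83, 0.11, 0.04, 0.02)
OE_EV_WEIGHTS = (0.36, 0.19, 0.03, 0.42)


@dataclass
class GroundTruthSpot:
    x: float                      # pixel units; pixel (i, j) spans [i, i+1)
    y: float
    z: float = 0.0                # nm; 0 for 2D
    n_copies: int = 1
    true_integrated_signal: float = 0.0

    def __post_init__(self):
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.true_integrated_signal < 0:
            raise ValueError("true_integrated_signal must be >= 0")


@dataclass
class Frame:
    pixels: np.ndarray
    context: AcquisitionContext
    truth: Optional[list[GroundTruthSpot]] = None


def sample_copy_numbers(
    mixture: MixtureSpec, n_spots: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw copy numbers from the mixture; the last weight class is
    expanded through the tail policy."""
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    classes = rng.choice(mixture.n_classes, size=n_spots, p=mixture.copy_weights)
    out = classes + 1
    tail = classes == mixture.n_classes - 1
    if mixture.n_classes > 1 and tail.any():
        out = out.astype(int)
        out[tail] = mixture.tail_policy.realize(rng, int(tail.sum()))
    elif mixture.n_classes == 1:
        out = np.ones(n_spots, dtype=int)
    return out.astype(int)


def sample_spot_intensity(
    n_copies: int, fluor: FluorophoreModel, seed: int | np.random.Generator
) -> float:
    """Integrated signal of one spot: the sum of ``n_copies`` independent
    single-fluorophore draws (not one draw scaled by n)."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return float(fluor.draw(rng, n_copies).sum())


def sample_intensities(
    mixture: MixtureSpec,
    fluor: FluorophoreModel,
    n_spots: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized spot-intensity sampler.

    Returns ``(intensities, copy_numbers)`` for ``n_spots`` spots.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ns = sample_copy_numbers(mixture, n_spots, rng)
    total = int(ns.sum())
    draws = fluor.draw(rng, total)
    bounds = np.concatenate([[0], np.cumsum(ns)])
    sums = np.add.reduceat(draws, bounds[:-1]) if total else np.zeros(0)
    return sums, ns


def _expected_image(
    spots: Sequence[GroundTruthSpot],
    background: float,
    shape: tuple[int, int],
    sigma_xy,
) -> tuple[np.ndarray, list[GroundTruthSpot]]:
    rows, cols = shape
    img = np.full(shape, float(background))
    kept: list[GroundTruthSpot] = []
    jx = np.arange(cols, dtype=float)
    iy = np.arange(rows, dtype=float)
    for spot in spots:
        if not (0 <= spot.x <= cols and 0 <= spot.y <= rows):
            logger.warning("spot at (%.2f, %.2f) outside %sx%s frame; rejected",
                           spot.x, spot.y, rows, cols)
            continue
        sx, sy = sigma_xy(spot)
        img += spot.true_integrated_signal * np.outer(
            pixel_mass_1d(iy, spot.y, sy), pixel_mass_1d(jx, spot.x, sx))
        kept.append(spot)
    return img, kept


def _apply_camera(
    expected: np.ndarray, context: AcquisitionContext, rng: np.random.Generator
) -> np.ndarray:
    gain_per_photon = context.em_gain / context.photons_per_count
    photons = expected / gain_per_photon
    noisy = rng.poisson(photons).astype(float)
    if context.excess_noise:
        # multiplicative EM excess noise, variance factor 2
        noisy += rng.normal(0.0, np.sqrt(np.maximum(photons, 0.0)))
    counts = noisy * gain_per_photon
    if context.read_noise_sd > 0:
        counts += rng.normal(0.0, context.read_noise_sd, size=counts.shape)
    counts += context.baseline
    return np.maximum(counts, 0.0)


def render_frame(
    spots: Sequence[GroundTruthSpot],
    psf_sigma: float,
    background: float,
    context: AcquisitionContext,
    shape: tuple[int, int],
    seed: int | np.random.Generator,
    noise: bool = True,
) -> Frame:
    """Render a 2D frame of symmetric pixel-integrated Gaussian spots.

    With ``noise=False`` the expected image (plus baseline) is returned,
    which is what the conservation and self-consistency checks use.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    expected, kept = _expected_image(
        spots, background, shape, lambda s: (psf_sigma, psf_sigma))
    if noise:
        pixels = _apply_camera(expected, context, rng)
    else:
        pixels = expected + context.baseline
    return Frame(pixels=pixels, context=context, truth=kept)


def render_astig_frame(
    spots: Sequence[GroundTruthSpot],
    calib,
    background: float,
    context: AcquisitionContext,
    shape: tuple[int, int],
    seed: int | np.random.Generator,
    noise: bool = True,
) -> Frame:
    """Render a frame with astigmatism: per-spot widths follow the
    calibration curves sigma_x(z), sigma_y(z) at the spot's axial
    position."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    zlo, zhi = calib.z_range
    for spot in spots:
        if not (zlo <= spot.z <= zhi):
            raise ValueError(
                f"spot z={spot.z} nm outside calibrated range [{zlo}, {zhi}] nm")
    expected, kept = _expected_image(
        spots, background, shape,
        lambda s: (calib.sigma_x(s.z), calib.sigma_y(s.z)))
    if noise:
        pixels = _apply_camera(expected, context, rng)
    else:
        pixels = expected + context.baseline
    return Frame(pixels=pixels, context=context, truth=kept)


def scatter_positions(
    n_spots: int,
    shape: tuple[int, int],
    min_separation: float,
    rng: np.random.Generator,
    margin: float = 0.0,
    max_tries: int = 10000,
) -> np.ndarray:
    """Uniform random (x, y) positions with a minimum pairwise distance
    (dart throwing); used to build sparse well-separated fields."""
    rows, cols = shape
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n_spots and tries < max_tries * max(n_spots, 1):
        tries += 1
        x = rng.uniform(margin, cols - margin)
        y = rng.uniform(margin, rows - margin)
        if all((x - p[0]) ** 2 + (y - p[1]) ** 2 >= min_separation ** 2 for p in pts):
            pts.append((x, y))
    if len(pts) < n_spots:
        raise RuntimeError("could not place the requested number of spots")
    return np.array(pts)
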
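"""Fluorophore counting by intensity-PDF convolution.

The integrated intensity ``C`` of a spot carrying ``n`` independent
fluorophores is the sum of ``n`` single-fluorophore intensities, so its
density is the n-fold convolution of the single-fluorophore density
``P1``:

    P2(C) = integral P1(C') P1(C - C') dC'
    Pn(C) = integral P1(C') P(n-1)(C - C') dC'

The observed (empirical) density of a sample with unknown labeling is
modeled as a convex combination

    Pemp(C) ~ sum_n w_n Pn(C),

and the weights ``w_n`` — the degree-of-labeling (DOL) fractions — are
obtained by nonnegative least squares on a common intensity grid under
the simplex constraint sum w_n = 1.

Density estimation is Gaussian KDE.  When an empirical sample is
decomposed against a family built from a reference density, the sample
is smoothed with the *reference's* bandwidth rather than its own
Silverman value: the mixture's inflated spread would otherwise
oversmooth Pemp relative to the family and bias weight toward higher n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DensityEstimate",
    "StoichiometryResult",
    "make_grid",
    "silverman_bandwidth",
    "estimate_pdf",
    "convolve_next",
    "build_family",
    "decompose",
    "dol_report",
    "compare_populations",
    "normalized_signal_ratio",
]

MIN_SAMPLES = 30


@dataclass
class DensityEstimate:
    """A probability density on a uniform intensity grid (counts)."""

    grid: np.ndarray
    density: np.ndarray
    n_samples: int = 0
    label: str = "P1"
    bandwidth: Optional[float] = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have the same shape")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    @property
    def sd(self) -> float:
        m = self.mean
        v = np.trapezoid((self.grid - m) ** 2 * self.density, self.grid)
        return float(np.sqrt(max(v, 0.0)))

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def normalized(self) -> "DensityEstimate":
        z = self.integral()
        if z <= 0:
            raise ValueError("cannot normalize a zero density")
        return DensityEstimate(self.grid, self.density / z,
                               self.n_samples, self.label, self.bandwidth)


@dataclass
class StoichiometryResult:
    """DOL fractions w_n for n = 1..n_max plus fit diagnostics."""

    weights: np.ndarray
    fit_residual: float
    n_max: int
    anchoring_mode: str = "none"
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    def tail_weight(self, aggregate_at: int) -> float:
        return float(self.weights[aggregate_at - 1:].sum())


def make_grid(mean: float, sd: float, n_max: int = 6,
              grid_step: Optional[float] = None,
              c_max: Optional[float] = None) -> np.ndarray:
    """Uniform intensity grid sized so n-fold convolutions up to n_max
    keep their mass: step = min(sd/10, 5) counts, range
    [0, n_max*(mean + 6 sd)]."""
    if grid_step is None:
        grid_step = min(sd / 10.0, 5.0) if sd > 0 else 5.0
    if c_max is None:
        c_max = n_max * (mean + 6.0 * sd)
    n = int(np.ceil(c_max / grid_step)) + 1
    return np.arange(n, dtype=float) * grid_step


def silverman_bandwidth(samples: np.ndarray) -> float:
    x = np.asarray(samples, dtype=float)
    return float(1.06 * np.std(x, ddof=1) * len(x) ** (-0.2))


def _fit_truncnorm_moments(samples: np.ndarray) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated Normal whose truncated
    moments match the sample mean and sd."""
    m, s = float(np.mean(samples)), float(np.std(samples, ddof=1))

    def eqs(p):
        mu, sig = p
        sig = abs(sig)
        a = -mu / sig
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sig)
        return [d.mean() - m, d.std() - s]

    sol = optimize.fsolve(eqs, [m, s], full_output=True)
    if sol[2] == 1:
        mu, sig = sol[0]
        return float(mu), float(abs(sig))
    return m, s   # truncation negligible; sample moments are the parent's


def estimate_pdf(
    samples: Sequence[float],
    method: str = "kde",
    bandwidth: Optional[float] = None,
    grid: Optional[np.ndarray] = None,
    grid_step: Optional[float] = None,
    c_max: Optional[float] = None,
    n_max: int = 6,
    label: str = "Pemp",
) -> DensityEstimate:
    """Estimate a normalized intensity density on [0, c_max].

    method "kde": Gaussian kernel, Silverman bandwidth unless given.
    method "truncnorm": zero-truncated Normal fit by moments.
    Negative intensities (possible under read noise) are clipped to 0
    before estimation; the count is logged.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < MIN_SAMPLES:
        raise ValueError(
            f"need at least {MIN_SAMPLES} samples for a density estimate, got {x.size}")
    n_neg = int((x < 0).sum())
    if n_neg:
        logger.info("clipped %d negative intensities to 0", n_neg)
        x = np.maximum(x, 0.0)
    if grid is None:
        grid = make_grid(float(x.mean()), float(x.std(ddof=1)), n_max,
                         grid_step=grid_step, c_max=c_max)
    grid = np.asarray(grid, dtype=float)

    if method == "kde":
        h = bandwidth if bandwidth is not None else silverman_bandwidth(x)
        if h <= 0:
            h = max(1e-3, 1e-3 * max(abs(x).max(), 1.0))
        d = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
    elif method == "truncnorm":
        mu, sig = _fit_truncnorm_moments(x)
        a = -mu / sig
        d = stats.truncnorm.pdf(grid, a, np.inf, loc=mu, scale=sig)
        h = None
    else:
        raise ValueError(f"unknown density method {method!r}")

    z = np.trapezoid(d, grid)
    if z <= 0:
        raise ValueError("density integrates to zero on the grid; widen c_max")
    return DensityEstimate(grid, d / z, n_samples=x.size, label=label, bandwidth=h)


def convolve_next(p1: DensityEstimate, p_prev: DensityEstimate,
                  mass_tol: float = 0.01) -> DensityEstimate:
    """One convolution step: density of X + Y for X ~ p1, Y ~ p_prev, on
    the shared grid.  Mass pushed beyond the grid end is an error above
    ``mass_tol`` (enlarge c_max), otherwise logged and renormalized
    away."""
    if p1.grid.shape != p_prev.grid.shape or not np.allclose(p1.grid, p_prev.grid):
        raise ValueError("convolve_next requires identical grids")
    step = p1.grid_step
    full = np.convolve(p1.density, p_prev.density) * step
    kept = full[: len(p1.grid)]
    total = np.trapezoid(full, dx=step)
    lost = 1.0 - (np.trapezoid(kept, dx=step) / total if total > 0 else 0.0)
    if lost > mass_tol:
        raise ValueError(
            f"convolution lost {lost:.1%} of probability mass beyond the grid; "
            "increase c_max")
    if lost > 0:
        logger.debug("convolution truncation mass loss %.2e", lost)
    out = DensityEstimate(p1.grid, kept, n_samples=p_prev.n_samples)
    out = out.normalized()
    prev_n = p_prev.label
    n = 2 if prev_n == "P1" else int(prev_n[1:]) + 1 if prev_n.startswith("P") and prev_n[1:].isdigit() else 0
    out.label = f"P{n}" if n else "Pn"
    return out


def _rescale_mode(p: DensityEstimate, target_mode: float) -> DensityEstimate:
    """Stretch the intensity axis so the mode lands on ``target_mode``,
    then renormalize on the original grid."""
    m = p.mode
    if m <= 0:
        return p
    s = target_mode / m
    d = np.interp(p.grid / s, p.grid, p.density, left=0.0, right=0.0) / s
    out = DensityEstimate(p.grid, d, p.n_samples, p.label, p.bandwidth)
    return out.normalized()


def build_family(p1: DensityEstimate, n_max: int,
                 anchoring: str = "none") -> list[DensityEstimate]:
    """[P1, P2, ..., Pn_max] by iterated convolution.

    anchoring "rescale-to-multiples" stretches each Pn so its mode sits
    exactly at n * mean(P1) — mimicking pinning the convolution maxima
    at integer multiples of the single-fluorophore average.  For a
    near-symmetric P1 this is a negligible correction; default "none"
    keeps the pure convolutions.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if anchoring not in ("none", "rescale-to-multiples"):
        raise ValueError(f"unknown anchoring mode {anchoring!r}")
    fam = [p1]
    for _ in range(2, n_max + 1):
        fam.append(convolve_next(p1, fam[-1]))
    if anchoring == "rescale-to-multiples":
        mu1 = p1.mean
        fam = [fam[0]] + [
            _rescale_mode(pn, (i + 2) * mu1) for i, pn in enumerate(fam[1:])
        ]
        for i, pn in enumerate(fam):
            pn.label = f"P{i + 1}"
    return fam


def decompose(p_emp: DensityEstimate, family: Sequence[DensityEstimate],
              anchoring_mode: str = "none") -> StoichiometryResult:
    """Solve min_w || p_emp - sum_n w_n Pn ||_2 on the grid, subject to
    w >= 0 and sum w = 1 (penalty-augmented Lawson-Hanson NNLS).

    Near-duplicate family members are collapsed into the lowest n with a
    warning.
    """
    if not family:
        raise ValueError("family must be nonempty")
    for p in family:
        if p.grid.shape != p_emp.grid.shape or not np.allclose(p.grid, p_emp.grid):
            raise ValueError("family and empirical density must share one grid")
    A = np.stack([p.density for p in family], axis=1)

    # collapse duplicated densities (degenerate family)
    groups = list(range(A.shape[1]))
    for j in range(1, A.shape[1]):
        for i in range(j):
            if groups[i] == i and np.allclose(A[:, i], A[:, j], atol=1e-12):
                warnings.warn(
                    f"family members {i + 1} and {j + 1} are duplicates; "
                    f"their weights are summed into n={i + 1}")
                groups[j] = i
                break
    uniq = sorted(set(groups))
    Au = A[:, uniq]

    scale = max(np.abs(A).max(), 1.0)
    mu = 1e4 * scale
    A_aug = np.vstack([Au, mu * np.ones((1, Au.shape[1]))])
    b_aug = np.concatenate([p_emp.density, [mu]])
    w_u, _ = optimize.nnls(A_aug, b_aug)
    total = w_u.sum()
    if total <= 0:
        raise ValueError("degenerate decomposition: all weights zero")
    w_u = w_u / total

    w = np.zeros(A.shape[1])
    for idx, j in enumerate(uniq):
        w[j] = w_u[idx]

    residual = float(np.linalg.norm(p_emp.density - A @ w))
    return StoichiometryResult(
        weights=w, fit_residual=residual, n_max=len(family),
        anchoring_mode=anchoring_mode,
        settings={"n_samples_emp": p_emp.n_samples,
                  "bandwidth_emp": p_emp.bandwidth},
    )


def dol_report(result: StoichiometryResult, aggregate_at: int = 4):
    """Degree-of-labeling table: fractions for n = 1..aggregate_at-1 and
    one ">= aggregate_at" class, as a pandas DataFrame with percentages
    to one decimal."""
    import pandas as pd

    if aggregate_at > result.n_max:
        raise ValueError("aggregate_at must be <= n_max")
    rows = []
    for n in range(1, aggregate_at):
        rows.append({"dol": str(n), "fraction": float(result.weights[n - 1])})
    rows.append({"dol": f">={aggregate_at}",
                 "fraction": result.tail_weight(aggregate_at)})
    df = pd.DataFrame(rows)
    df["percent"] = (100.0 * df["fraction"]).round(1)
    return df


def compare_populations(
    p_ref: DensityEstimate | Sequence[float],
    samples: Sequence[float],
    n_max: int = 6,
    anchoring: str = "none",
    grid: Optional[np.ndarray] = None,
) -> StoichiometryResult:
    """Decompose a sample against a family built from a reference
    density (or reference sample).

    The reference "unit" need not be a single fluorophore — e.g. the
    on-glass density of single EVs serves as P1 when quantifying EV
    aggregation inside cells.  The sample's empirical density is
    smoothed with the reference's bandwidth (matched-kernel smoothing).
    """
    x = np.asarray(samples, dtype=float)
    if not isinstance(p_ref, DensityEstimate):
        ref_arr = np.asarray(p_ref, dtype=float)
        if grid is None:
            grid = make_grid(float(ref_arr.mean()), float(ref_arr.std(ddof=1)), n_max)
        p_ref = estimate_pdf(ref_arr, grid=grid, label="P1")
    family = build_family(p_ref, n_max, anchoring)
    p_emp = estimate_pdf(x, bandwidth=p_ref.bandwidth, grid=p_ref.grid, label="Pemp")
    return decompose(p_emp, family, anchoring_mode=anchoring)


def normalized_signal_ratio(mean_a: float, ctx_a, mean_b: float, ctx_b) -> float:
    """Ratio of two mean signals after linear normalization by
    illumination time and laser intensity:

        (mean_a / (t_ill_a * I_a)) / (mean_b / (t_ill_b * I_b))
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("means must be positive")
    den_a = ctx_a.t_ill * ctx_a.laser_intensity
    den_b = ctx_b.t_ill * ctx_b.laser_intensity
    if den_a <= 0 or den_b <= 0:
        raise ValueError("illumination time and laser intensity must be positive")
    return (mean_a / den_a) / (mean_b / den_b)
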
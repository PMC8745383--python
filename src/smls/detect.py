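"""Candidate spot finding: Gaussian smoothing, robust background and
noise estimation, and non-maximum suppression (NMS).

A pixel is a candidate if it is the maximum of its (2*radius+1)^2
Chebyshev window on the smoothed image, strictly greater than at least
one window neighbor (flat regions yield nothing), and exceeds the
background by a threshold.  Ties between equal-valued maxima inside one
window are broken lexicographically by (row, col), which makes the
output deterministic and guarantees that no two candidates are within
``radius`` of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SpotCandidate",
    "estimate_background",
    "estimate_noise_sd",
    "nms_candidates",
]


@dataclass
class SpotCandidate:
    frame_index: int
    row: int
    col: int
    peak_value: float          # smoothed-image value at the peak
    local_background: float


def _pixels(frame) -> np.ndarray:
    arr = getattr(frame, "pixels", frame)
    return np.asarray(arr, dtype=float)


def estimate_background(frame, method: str = "median", q: float = 0.5) -> float:
    """Scalar per-frame background estimate (counts/pixel)."""
    arr = _pixels(frame)
    if arr.size == 0:
        raise ValueError("empty frame")
    if method == "median":
        return float(np.median(arr))
    if method == "quantile":
        return float(np.quantile(arr, q))
    raise ValueError(f"unknown background method {method!r}")


def estimate_noise_sd(frame) -> float:
    """Robust noise sd via the median absolute deviation (MAD * 1.4826)."""
    arr = _pixels(frame)
    return float(1.4826 * np.median(np.abs(arr - np.median(arr))))


def nms_candidates(
    frame,
    smooth_sigma: float,
    radius: int = None,
    threshold: float = None,
    k_mad: float = 3.0,
    frame_index: int = 0,
) -> list[SpotCandidate]:
    """Non-maximum-suppression candidate search on one frame.

    Parameters
    ----------
    smooth_sigma : Gaussian pre-smoothing width in pixels (use the PSF
        sigma); 0 disables smoothing.
    radius : suppression radius in pixels; default ceil(2*smooth_sigma),
        at least 1.
    threshold : required peak height above background, in counts on the
        smoothed image.  Default is ``k_mad`` times the robust noise sd
        of the smoothed image.

    Returns candidates sorted by descending peak value.
    """
    arr = _pixels(frame)
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be >= 0")
    if radius is None:
        radius = max(int(math.ceil(2.0 * smooth_sigma)), 1)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    win = 2 * radius + 1
    if arr.shape[0] < win or arr.shape[1] < win:
        raise ValueError("frame smaller than the suppression window")

    smoothed = ndimage.gaussian_filter(arr, smooth_sigma) if smooth_sigma > 0 else arr
    background = float(np.median(smoothed))
    if threshold is None:
        noise = 1.4826 * float(np.median(np.abs(smoothed - np.median(smoothed))))
        threshold = k_mad * noise
    if threshold <= 0:
        raise ValueError("threshold must be > 0")

    win_max = ndimage.maximum_filter(smoothed, size=win, mode="nearest")
    win_min = ndimage.minimum_filter(smoothed, size=win, mode="nearest")
    cut = background + threshold
    # window max, not flat, above threshold
    cand_mask = (smoothed == win_max) & (win_min < smoothed) & (smoothed > cut)

    out: list[SpotCandidate] = []
    rows, cols = np.nonzero(cand_mask)
    for r, c in zip(rows, cols):
        v = smoothed[r, c]
        r0, r1 = max(r - radius, 0), min(r + radius + 1, arr.shape[0])
        c0, c1 = max(c - radius, 0), min(c + radius + 1, arr.shape[1])
        ok = True
        for rr in range(r0, r1):
            for cc in range(c0, c1):
                if (rr, cc) == (r, c):
                    continue
                w = smoothed[rr, cc]
                if w > v or (w == v and (rr, cc) < (r, c)):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(SpotCandidate(
                frame_index=frame_index, row=int(r), col=int(c),
                peak_value=float(v), local_background=background))
    out.sort(key=lambda s: (-s.peak_value, s.row, s.col))
    return out
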
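"""Turn-key validation experiments on synthetic ground truth.

These reproduce, in simulation, the two quantification settings the
pipeline is built for: degree-of-labeling recovery from spot-intensity
samples at the on-glass sample sizes, and end-to-end intensity recovery
through the detect + fit stages at realistic camera noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import detect, psffit
from .simulate import (
    FluorophoreModel, GFP_CONTEXT, GFP_MODEL, GroundTruthSpot, MixtureSpec,
    TailPolicy, render_frame, sample_intensities, scatter_positions,
)
from .stoichiometry import compare_populations

__all__ = ["dol_recovery_experiment", "fitter_bias_experiment"]


def dol_recovery_experiment(
    copy_weights: tuple[float, ...],
    n_spots: int,
    tail_policy: TailPolicy,
    n_ref: int = 247,
    fluor: FluorophoreModel = GFP_MODEL,
    n_max: int = 6,
    aggregate_at: int = 4,
    n_seeds: int = 20,
    seed: int = 0,
) -> dict:
    """Simulate + decompose one labeling experiment over several seeds.

    Per seed: draw ``n_ref`` single-fluorophore reference intensities
    and ``n_spots`` mixture spot intensities, then recover the DOL
    weights with the convolution decomposition.  Returns mean recovered
    percentages per aggregated class and the mean simulated population
    intensity.
    """
    percents = []
    means = []
    for rep in range(n_seeds):
        rng = np.random.default_rng([seed, rep])
        ref = fluor.draw(rng, n_ref)
        mixture = MixtureSpec(copy_weights, tail_policy)
        samples, _ = sample_intensities(mixture, fluor, n_spots, rng)
        result = compare_populations(ref, samples, n_max=n_max)
        w = result.weights
        agg = np.concatenate([w[: aggregate_at - 1],
                              [w[aggregate_at - 1:].sum()]])
        percents.append(100.0 * agg)
        means.append(samples.mean())
    percents = np.asarray(percents)
    return {
        "percent_mean": percents.mean(axis=0),
        "percent_sd": percents.std(axis=0, ddof=1),
        "population_mean_intensity": float(np.mean(means)),
        "n_seeds": n_seeds,
        "n_spots": n_spots,
    }


def fitter_bias_experiment(
    n_spots: int = 2000,
    psf_sigma: float = 1.3,
    background: float = 1.5,
    fluor: FluorophoreModel = GFP_MODEL,
    context=GFP_CONTEXT,
    frame_shape: tuple[int, int] = (64, 64),
    spots_per_frame: int = 9,
    seed: int = 0,
) -> dict:
    """Render sparse single-fluorophore spots with camera noise, run
    detection and symmetric PSF fitting, and report the mean fitted
    integrated intensity over converged fits."""
    rng = np.random.default_rng([seed, 7])
    intensities = []
    n_frames = int(np.ceil(n_spots / spots_per_frame))
    margin = psffit.default_window_size(psf_sigma) // 2 + 1
    for i in range(n_frames):
        k = min(spots_per_frame, n_spots - i * spots_per_frame)
        pos = scatter_positions(k, frame_shape,
                                min_separation=8 * psf_sigma,
                                rng=rng, margin=margin)
        sig = fluor.draw(rng, k)
        spots = [GroundTruthSpot(x=pos[j, 0], y=pos[j, 1],
                                 true_integrated_signal=float(sig[j]))
                 for j in range(k)]
        frame = render_frame(spots, psf_sigma, background, context,
                             frame_shape, rng)
        cands = detect.nms_candidates(frame, psf_sigma, frame_index=i)
        for fit in psffit.fit_spots(frame.pixels, cands, psf_sigma,
                                    frame_index=i):
            if fit.converged:
                intensities.append(fit.intensity)
    intensities = np.asarray(intensities)
    return {
        "mean_fitted_intensity": float(intensities.mean()),
        "n_fits": int(intensities.size),
        "n_spots_rendered": n_spots,
    }
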
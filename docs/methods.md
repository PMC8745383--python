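# Methods

## Scope and model

`smls` estimates the distribution of fluorophore copy numbers over a
population of sub-diffraction particles from single-molecule wide-field
images. The physical model has three layers:

1. **Per-spot signal.** A spot carrying `n` fluorophores has integrated
   intensity equal to the sum of `n` independent single-fluorophore
   intensities. Single-fluorophore brightness is modeled as a Normal
   distribution truncated at zero. The model is parametrized by the
   *observed* (post-truncation) mean and sd — for the default GFP model
   these are 157 and 65 camera counts — and the parent Normal parameters
   are solved numerically so the truncated moments match. A parent
   Normal(157, 65²) clipped at zero would instead have mean 158.4, a
   small but systematic offset that would propagate linearly into every
   n-fluorophore density.
2. **Image formation.** Spots are rendered with a pixel-integrated 2D
   Gaussian PSF: the expected pixel value is the Gaussian mass over the
   unit pixel square, written as differences of error functions per
   axis. Pixel `(i, j)` spans `[i, i+1) × [j, j+1)`; a spot "at a pixel
   center" has coordinates `i + 0.5`. The same model is used by the
   simulator and the fitter, so fitting noiseless renders is exact up to
   optimizer tolerance.
3. **Camera.** Counts are generated as
   `Poisson(expected photons) × em_gain + Normal(0, read_noise) + baseline`,
   with `photons_per_count` converting counts to photons at unit gain.
   An optional multiplicative EM excess-noise term (variance factor 2)
   is off by default; the effective photon count used in precision
   formulas is halved when it is on.

Defaults mirror the target acquisition regime: 100 nm pixels, 5 ms
illumination at 3.2 kW/cm² for GFP-like imaging (10 ms at 4.4 kW/cm² for
the far-red JF646 context), PSF σ = 1.3 px, background 1.5 counts/px,
read noise 0.7 counts, baseline 100 counts, unit EM gain. With these
values a 157-count spot has a peak of ≈14 counts over a background noise
sd of ≈1.4 counts — peak SNR ≈ 10, the regime used throughout the noisy
validation suites.

## Spot detection

Frames are smoothed with a Gaussian of the PSF width (a matched filter),
and candidates are strict local maxima within a `(2r+1)²` Chebyshev
window, `r = ceil(2σ)` by default, exceeding the frame median by a
threshold. The default threshold is `3 × (1.4826 · MAD)` of the smoothed
image — a robust noise estimate that ignores the sparse spots. Plateau
ties are resolved lexicographically by `(row, col)`: a pixel survives if
every window neighbor is smaller, or equal with a larger index, and at
least one neighbor is strictly smaller. This makes the output
deterministic, guarantees a minimum candidate spacing of `r`, and is
checked against an exhaustive brute-force scan in the test suite.

The threshold constant is the one deliberately free knob in the
detection stage; `k = 3` follows common single-molecule practice. At
peak SNR 10 this recalls ≥ 99% of full-brightness spots but necessarily
loses the dimmest ~2% of a 157 ± 65 population (spots below ≈20
integrated counts). That selection raises the mean fitted intensity of a
detected population by ≈ +2–3 counts; it is partly offset by a small
negative bias of the unweighted least-squares fit under Poisson noise,
leaving the end-to-end mean ≈ +2 counts above the generating mean.

## PSF fitting

Each candidate is fit in a window of `2·ceil(4σ)+1` pixels (13 px for
σ = 1.3) by unweighted least squares over `(x, y, σ, C, B)` — or
`(x, y, σx, σy, C, B)` for astigmatic data — using a rectangular
trust-region dogleg optimizer (`scipy.optimize.least_squares`,
`method="dogbox"`) with an analytic Jacobian, `ftol = 1e-8`, and width
bounds `[0.5, 3] × σ_prior`. Initialization: position at the candidate
pixel center, background from the local estimate, `C` from the
background-subtracted window sum. Fits are flagged non-converged when
the optimizer fails, the width sticks at its bounds, or `C ≤ 0`; only
converged fits feed the stoichiometry stage. Unweighted (rather than
variance-weighted) least squares is the default because it matches the
error-function/least-squares formulation the pipeline is built around;
the practical difference at SNR ≈ 10 is below the per-spot noise.

**Localization precision.** The per-spot lateral precision uses the
least-squares variant of the Thompson pixelation formula (Mortensen's
16/9 + 4τ correction):

    sa² = s² + a²/12,   τ = 2π·sa²·b²/(N·a²)
    var_xy = sa²/N · (16/9 + 4τ)

with `s` the PSF width and `a` the pixel size in nm, `N` the photon
count, and `b²` the background noise variance per pixel in photons (the
fitted background minus the camera baseline, plus read-noise variance).
Monte-Carlo repetition of a 500-photon spot reproduces the reported
value within a few percent. Width uncertainty per axis is taken as half
the position variance with the same corrections (the Gaussian Fisher
information for width is twice that for position); axial precision
propagates these through the calibration slopes,
`var(z) = [ (dσx/dz)²/var(σx) + (dσy/dz)²/var(σy) ]⁻¹`.

## Stoichiometry

Densities live on a uniform intensity grid with step
`min(sd(P1)/10, 5)` counts and range `[0, n_max·(mean + 6·sd)]`, sized
so the n-fold convolutions keep > 99% of their mass (violations raise an
error suggesting a larger `c_max`). `P1` is estimated by Gaussian KDE
with Silverman's bandwidth (a zero-truncated-Normal moment fit is
available as a parametric alternative). Convolutions are discrete
(`numpy.convolve` scaled by the grid step), truncated to the grid, and
renormalized.

**Matched-kernel smoothing.** When an empirical sample is decomposed
against a family built from a reference density, the sample is smoothed
with the *reference's* bandwidth rather than its own Silverman value.
Silverman's rule scales with the sample sd, and a mixture's sd includes
the between-component spread, so applying it to the mixture oversmooths
`Pemp` relative to the family and systematically leaks weight from low
to high `n` (4–6 percentage points off the singly-labeled fraction at
the default study sizes). Matching the kernel widths keeps the
per-component broadening of `Pemp` and of `P1` identical, and the n-fold
family members inherit bandwidth `√n·h`, a second-order mismatch only.

**Decomposition.** The simplex-constrained least-squares problem is
solved by Lawson–Hanson NNLS on the system augmented with a heavily
weighted `Σw = 1` row, then renormalized; on on-grid convex combinations
this is exact to < 1e-6 and agrees with an independent SLSQP solver.
Near-duplicate family members are collapsed into the lowest `n` with a
warning. `n_max = 6` with reporting aggregated at "≥ 4" is the default,
matching how heavily-labeled tails are usually quoted.

**Mode anchoring.** An optional `rescale-to-multiples` mode stretches
each `Pn` along the intensity axis so its mode sits exactly at
`n × mean(P1)` — mimicking analyses that pin the convolution maxima at
integer multiples of the single-fluorophore average. For a
near-symmetric `P1` the modes of the pure convolutions already sit there
(the default is therefore `anchoring="none"`); the mode matters only for
strongly skewed references.

The same machinery serves the "aggregation" analysis in which the
reference unit is not a single fluorophore but a whole single particle
(e.g. the on-glass EV intensity density used as `P1` for in-cell spots):
`compare_populations` accepts any reference sample or density.

Cross-condition brightness comparisons assume signal linear in
illumination time and laser power:
`ratio = (mean_a/(t_a·I_a)) / (mean_b/(t_b·I_b))`.

## Astigmatic 3D localization

The defocus model per axis is a quartic-extended hyperbola
`σ(z) = σ0·√(1 + u² + A·u³ + B·u⁴)`, `u = (z−c)/d`, with `A = B = 0` by
default; the default calibration uses σ0 = 1.3 px, focal offsets
∓200 nm, depth scale 400 nm, valid over ±500 nm. Calibrations are fit
per axis by least squares from ≥ 7 bead planes and re-centered so the
`σx = σy` crossing defines `z = 0` (constructions without exactly one
crossing are rejected). `z` is estimated by minimizing the root-sigma
metric `D(z) = (√σx − √σx_cal(z))² + (√σy − √σy_cal(z))²` on a 1 nm grid
with parabolic refinement; boundary minima are flagged out-of-range and
dropped from reconstructions. Noiseless render→fit→invert round-trips
are accurate to < 5 nm across the calibrated range.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis relies
on — copy-number mixtures with independent additive per-copy signals,
pixel-integrated PSFs, Poisson/EM/read-noise counts, sparse
well-separated spots — at the published study scales (247 reference
spots, 392 and 498 population spots). It does **not** model
photobleaching or blinking kinetics, stage drift, chromatic effects,
structured cellular background, out-of-focus haze, or spot overlap, and
the open-ended "≥ n_max" labeling class must be realized by an explicit
tail policy (fixed `n`, or uniform over `{n, …, n+span}`; the generative
truth there is unknowable from population data). Passing tests
therefore demonstrate correctness of the estimator under the stated
model, not robustness to the full complexity of cellular images; on
real data the dominant extra error sources are background structure and
the unmodeled tail shape.

## Problem sizes and numerical choices

The validation suites use 392/498-spot recoveries averaged over 20–25
seeds, and ~9 000–12 600 rendered spots (9 per 64×64 frame, ≥ 10 px
apart) for the end-to-end intensity-bias experiment — sizes chosen to
hold the Monte-Carlo standard error of each reported mean well below
its acceptance band. All randomness flows from explicit
`numpy.random.Generator` seeds; pipeline stages derive per-stage seeds
from one master seed via CRC32 of the stage name, so a full run is
byte-reproducible and stages can be re-run in isolation. Optimizer
tolerances are `ftol = 1e-8` / `xtol = 1e-8` with at most ~100
iterations; density grids are float64 throughout; degenerate inputs
(empty frames, zero-spot runs, all-identical samples, fewer than 30
intensities) either produce valid empty outputs or raise typed errors
naming the offending quantity.

## Known limitations

- DOL weights are population-level; no per-spot copy-number assignment
  (and none is identifiable from intensity alone at cv ≈ 0.4).
- Recovery accuracy degrades as the single-fluorophore brightness cv
  grows (tested monotone across cv = 0.2/0.4/0.8); at cv ≳ 0.8
  neighboring `Pn` overlap so strongly that only coarse classes are
  meaningful.
- Overlapping emitters are neither detected as pairs nor fit jointly;
  the detector suppresses the dimmer of two peaks closer than the NMS
  radius.
- The EM excess-noise model is a simple variance-doubling
  approximation, not a full gain-register cascade.
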
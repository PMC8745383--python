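# smls — single-molecule labeling stoichiometry

`smls` quantifies how many fluorophores sit on individual sub-diffraction
particles — typically GFP- or dye-tagged extracellular vesicles (EVs)
imaged by wide-field single-molecule fluorescence microscopy. It is aimed
at microscopists who need population-level *degree-of-labeling* (DOL)
statistics from sparse spot images or from tables of spot intensities,
plus astigmatism-based 3D positions of the same particles inside cells.

## The method

A diffraction-limited spot carrying `n` independent fluorophores has an
integrated intensity `C` that is the sum of `n` single-fluorophore
intensities. If `P1(C)` is the single-fluorophore intensity density, the
density for exactly `n` fluorophores follows by iterated convolution

    P2(C) = ∫ P1(C′) · P1(C − C′) dC′
    Pn(C) = ∫ P1(C′) · Pn−1(C − C′) dC′

and the observed density of a sample with unknown labeling is modeled as

    Pemp(C) ≈ Σn wn · Pn(C),   wn ≥ 0,  Σ wn = 1.

The fitted weights `wn` are the probabilities that a spot carries exactly
`n` fluorophores — the DOL fractions. `smls` solves the constrained fit
by nonnegative least squares on a common intensity grid.

Around this core the package provides:

- **simulate** — ground-truth generator: copy-number mixtures, additive
  per-copy signals (zero-truncated Normal), pixel-integrated Gaussian
  PSF rendering, and an EMCCD noise chain (Poisson → EM gain → read
  noise → baseline).
- **detect** — non-maximum-suppression candidate search on smoothed
  frames with a robust (median/MAD) threshold.
- **psffit** — sub-pixel least-squares fitting of the pixel-integrated
  2D Gaussian (error-function) PSF model, symmetric or elliptical, with
  per-spot localization-precision estimates.
- **stoichiometry** — density estimation, the convolution family, and
  the simplex-constrained decomposition above.
- **localize3d** — astigmatic width-vs-z calibration and z inversion
  for 3D positions in nm.
- **pipeline_io** — YAML config, CSV/TIFF schemas, seeded end-to-end
  runs, and the `smls` command line.

## Worked example

Recover the DOL composition of a predominantly single-labeled EV
population (the genome-edited regime: 83% of vesicles carry one tagged
protein) from 392 simulated spot intensities, using 247 single-GFP
reference spots:

```python
import numpy as np
from smls import (FluorophoreModel, MixtureSpec, TailPolicy,
                  compare_populations, dol_report, sample_intensities)

gfp = FluorophoreModel(mean_signal=157.0, sd_signal=65.0)
mixture = MixtureSpec((0.83, 0.11, 0.04, 0.02), TailPolicy("fixed", 4))

rng = np.random.default_rng(1)
reference = gfp.draw(rng, 247)                         # single-GFP spots
spots, _ = sample_intensities(mixture, gfp, 392, rng)  # EV population
print(f"population mean intensity: {spots.mean():.1f} a.u.")

result = compare_populations(reference, spots, n_max=6)
print(dol_report(result, aggregate_at=4).to_string(index=False))
```

Output:

```
population mean intensity: 201.5 a.u.
dol  fraction  percent
  1  0.803760     80.4
  2  0.136086     13.6
  3  0.028413      2.8
>=4  0.031740      3.2
```

With one seed and only 392 spots the recovered fractions scatter a few
points around the generating 83/11/4/2%; averaged over seeds they
converge to it (see the validation below). The population mean
(≈200 a.u.) sits slightly above the single-GFP mean of 157 a.u. because
a ~17% minority of spots carries more than one fluorophore.

The same analysis runs from the shell on intensity CSVs or raw TIFF
stacks:

```sh
smls simulate -o out --seed 7          # synthetic stack + ground truth
smls detect out/stack.tif -o cand.csv
smls fit out/stack.tif cand.csv -o loc.csv
smls stoich ref.csv loc.csv -o dol.json
smls run --seed 7 -o out               # the whole chain + report
```

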
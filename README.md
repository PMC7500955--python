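# centromorph

Nanoscale centriole morphometry for ultrastructure expansion microscopy
(U-ExM).

Centrioles are barrel-shaped organelles built from nine microtubule
triplets, lined along their central core by a helical inner protein
scaffold.  U-ExM physically expands fixed specimens ~4.2-fold in a
swellable gel, so a confocal microscope resolves where individual proteins
sit relative to the microtubule wall.  `centromorph` turns such
multichannel images (one tubulin channel, one protein-of-interest channel)
into the quantities this field reports:

* **radial mapping** (top views) — the offset Δ between the tubulin wall
  intensity maximum and the protein maximum along a spoke through each
  triplet, positive toward the lumen; proteins on the wall read Δ ≈ 0 nm,
  inner-scaffold components read Δ ≈ 15–28 nm;
* **longitudinal metrics** (lateral views) — tubulin and protein signal
  lengths (FWHM of the axial profile), the protein band's coverage
  (% of tubulin length) and position, and the wall-to-wall diameter in
  the proximal / core / distal regions;
* **shape & integrity** (top views) — roundness (minor/major axis of the
  ellipse fitted to the nine wall peaks) and broken-wall detection (the
  largest angular arc without wall signal);
* **foci & intensity** — per-cell dot counting, fixed-area centrosomal
  intensity, and normalization to the control-group mean (A.U.);
* **periodicity** — the dominant repeat distance of decoration along a
  microtubule from a 1-D line profile (autocorrelation with sub-sample
  refinement; periodogram cross-check);
* **statistics** — Mann-Whitney U (exact for small samples), one-way
  ANOVA with Holm-Šidák post-hoc comparisons, Fisher's exact test,
  unpaired t, and a run-level report builder.

Every distance is converted from image pixels (35 nm in expanded space by
default) to **biological nanometres** through the gel's measured expansion
factor, `X = gel size / 12 mm coverslip`.

Because no public raw images accompany the numbers this package is built
around, it ships a first-class **synthetic data generator**: expanded
centrioles in top view (nine Gaussian wall elements on an ellipse, protein
shell at a configurable radial offset) and lateral view (barrel plus
protein band), multi-cell foci fields, and periodic decoration profiles —
all with Gaussian PSF blur, Poisson + read noise, and per-image
ground-truth manifests, so every analysis stage is verifiable by parameter
recovery.  Named presets (`cr-wildtype`, `hs-control`, `hs-siwdr90`,
`wdr90-decoration`) encode the published study conditions.

## Worked example

```python
import numpy as np
from centromorph import ExpansionCalibration, generate_preset_batch
from centromorph.radial_mapping import measure_image, aggregate_offsets
from centromorph.longitudinal_metrics import measure_lateral_image

calib = ExpansionCalibration(gel_size_mm=50.0)
print(f"expansion factor: {calib.x_factor_reported}")

# Radial mapping: 30 synthetic human-control top views, POC5 channel
images, manifest = generate_preset_batch("hs-control", "POC5", "top", 30, seed=1)
results = [measure_image(im, calib) for im in images]
row = aggregate_offsets(results, ["POC5"] * len(results)).iloc[0]
print(f"POC5 radial offset: {row.mean_delta_nm:.1f} +/- {row.sd_delta_nm:.1f} nm "
      f"(n = {row.n} triplets)")

# Longitudinal metrics: 30 lateral views of the same condition
images, _ = generate_preset_batch("hs-control", "POC5", "lateral", 30, seed=2)
lengths, covs = [], []
for im in images:
    tub, prot, cov = measure_lateral_image(im, calib)
    lengths.append(tub.length_nm); covs.append(cov.coverage_pct)
print(f"tubulin length: {np.mean(lengths):.0f} +/- {np.std(lengths, ddof=1):.0f} nm")
print(f"POC5 coverage:  {np.mean(covs):.0f} +/- {np.std(covs, ddof=1):.0f} %")
```

Output:

```
expansion factor: 4.17
POC5 radial offset: 26.8 +/- 3.4 nm (n = 270 triplets)
tubulin length: 451 +/- 62 nm
POC5 coverage:  54 +/- 12 %
```

The recovered offset matches the preset truth (POC5 sits 27 nm interior to
the wall); the length and coverage sample means track the preset
distributions (434 ± 58 nm, 57 ± 13 %) within sampling error of n = 30.

## Command line

```bash
centromorph simulate --preset hs-control --channel POC5 --view top --n 30 --seed 1 --out sim/
centromorph map-radial --images 'sim/image_*.tif' --out radial.csv
centromorph measure-lateral --images 'lat/image_*.tif' --out lateral.csv
centromorph shape --images 'sim/image_*.tif' --out shape.csv
centromorph period --profile profile.csv --range 6 12 --out period.json
centromorph report --tables radial.csv --groups tests.yaml --out report/
```

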
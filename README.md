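# ramancd

Quantification of deuterium incorporation in plant tissue from confocal
Raman micro-spectroscopy (CRM) maps, with lignin mapping and landmark
registration onto high-resolution micrographs.

## The problem

Plants growing in heavy-water (D₂O) medium build deuterium into newly
synthesized biomass.  C–H bonds carrying deuterium shift their Raman
stretching bands from the C–H region (~2800–3100 cm⁻¹) down to the C–D
region (~2040–2300 cm⁻¹), so the fraction of carbon-bound hydrogen replaced
by deuterium can be read off a Raman spectrum as a band-area ratio:

```
CD% = A_CD / (A_CH + A_CD) × 100
```

where each area is a difference of the spectrum's primitive integral
A_I(E) = ∫₀^E I(Ē) dĒ at the window limits.  Scanning a root cross-section
pixel by pixel (2 µm pixels, thousands of spectra per section) turns this
into an isotope map, a direct image of where the root was metabolically
active.  This package implements the complete computational workflow around
that statistic, testable end-to-end on synthetic scenes with known ground
truth:

* **Pre-treatment** — threshold-based cosmic-ray removal (width 2 channels,
  dynamic factor 8), shape-based rolling-ball background subtraction
  (spectral shape size 100 cm⁻¹) for non-uniform autofluorescence, and
  4th-order / 11-channel Savitzky–Golay noise reduction, in that order.
* **Segmentation** — band-sum images ("sum filters") of the C-D, C-H and
  Raman-silent (2450–2650 cm⁻¹) windows; Otsu thresholding of the smoothed
  C-H + C-D structure image into root (cell wall) and void; alternatively a
  seeded two-component spectral decomposition (k-means + non-negative
  least-squares de-mixing) yielding an averaged bulk root spectrum.
* **Quantification** — per-pixel and bulk CD% with silent-region residual
  baseline correction (the integrated area over 2450–2650 cm⁻¹ must vanish,
  so whatever level remains is subtracted under the bands), data-derived
  integration windows (A-ranges) next to the literature L-ranges, a
  deuterated-glucose calibration line, and Gaussian error propagation over
  integration-limit and baseline perturbations.
* **Lignification** — the slope of per-pixel lignin band area
  (1599–1606 cm⁻¹) regressed on C-H band area: a scalar maturity proxy.
* **Registration** — affine/similarity/projective transforms from manually
  matched landmarks; linked registration applies the identical transform
  fitted on a structure-rich C-H map to the low-contrast CD% and lignin
  maps.
* **Synthetic data** — root-like scenes (Voronoi cell walls inside an
  elliptical cross-section) with per-pixel deuteration fraction, lignin
  weight, autofluorescence background, CCD offset, noise and cosmic-ray
  spikes, all reproducible from one seed.  Noise-free scenes make the whole
  pipeline analytically invertible: recovered CD% equals 100 × the true
  fraction to machine precision.

## Worked example

```python
import numpy as np
from ramancd import (generate_root_cube, pretreat, segment_otsu, cd_map,
                     bulk_cd_percent, compute_lignification, classify_maturity,
                     TruthParams)
from ramancd.segment import bulk_root_spectrum

hsmap, truth = generate_root_cube(20, 30,
                                  truth_params=TruthParams(cd_fraction=0.25),
                                  seed=42)
pre = pretreat(hsmap)                       # CRR -> rolling ball -> Savitzky-Golay
mask, _ = segment_otsu(pre)                 # root/void mask
result = cd_map(pre, mask)                  # per-pixel CD% with uncertainty
cd, budget = bulk_cd_percent(bulk_root_spectrum(pre, mask))
lig = compute_lignification(pre, mask)

print(f"root pixels:    {int(mask.sum())} / {mask.size}")
print(f"bulk CD%:       {cd:.2f} +/- {budget.d_cd_percent:.2f}")
print(f"pixel CD% mean: {np.nanmean(result.cd_percent):.2f}")
print(f"lignification:  {lig.slope:.3f} -> {classify_maturity(lig.slope)}")
```

prints

```
root pixels:    223 / 600
bulk CD%:       24.78 +/- 4.38
pixel CD% mean: 24.74
lignification:  0.099 -> young-like
```

The scene was generated with a true deuteration fraction of 0.25 and a
lignin/C-H coupling of 0.1: the bulk ratio lands within a quarter percent of
the 25% ground truth at the default noise level, the quoted ±4.4 is the
propagated worst-case window/baseline uncertainty (not the observed
scatter), and the lignification slope recovers the coupling.  A slope below
0.12 classifies the tissue as young-like (actively growing root tip).

The same pipeline is scriptable from the shell:

```sh
ramancd simulate raw.h5 --rows 20 --cols 30 --cd-fraction 0.25 --seed 42
ramancd preprocess raw.h5 pre.h5
ramancd segment pre.h5 --out-mask mask.tif --out-bulk bulk.csv
ramancd quantify pre.h5 --mask mask.tif --report report.json
ramancd lignify pre.h5 --mask mask.tif --report lignification.json
ramancd register --landmarks lm.csv --target him.tif --structure ch.tif \
                 --linked cd.tif --outdir reg/
```

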
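# fadefit

Pixel-resolved mapping of dye photodegradation on protein fibers from
co-registered hyperspectral reflectance and fluorescence image cubes.

`fadefit` is written for conservation scientists and spectroscopists who
image dyed textiles (the worked case is indigo carmine on wool) with a
hyperspectral camera in two modalities — diffuse reflectance against a white
standard and fluorescence emission — on the same spatial grid. It turns each
cube pair into chemical degradation maps in three steps:

1. **Multiblock preprocessing.** Both cubes are cropped to 500–800 nm.
   Specular glints (reflectance factor > 1) and non-fluorescent background
   (k-means on the emission spectra) are masked. The fluorescence is
   corrected for self-absorption with a Kubelka–Munk escape factor,
   F_true(λ) = F(λ) / ((1 + R(λ))/2), and reflectance is converted to
   pseudoabsorbance A = −log₁₀R. Per-spectrum preprocessing (fluorescence:
   0–1 scaling → SNV → first Savitzky–Golay derivative, order 3 / window 7;
   pseudoabsorbance: closure) is followed by separate block autoscaling and
   low-level fusion into a single F&R pixel matrix.
2. **PCA segmentation.** The fused block is decomposed by PCA; thresholds on
   the PC1 score histogram (two deepest KDE minima, or manual cut points)
   split the pixels into blue / green / red clusters of increasing
   degradation, rendered as a false-color map, and cluster mean spectra are
   extracted.
3. **Skew-normal emission fitting.** Each corrected emission spectrum is
   modelled as wool + dye, each component a skew normal

   f(λ) = A · exp(−(λ − λ_max)² / 2σ²) · ½(1 + erf((λ − p) / (s√2))).

   The wool shape (λ_max,w, σ_w, p_w, s_w) is frozen from an undyed-wool
   fit; cluster-average fits set initial values and bounds; a bounded
   trust-region least-squares fit then runs pixel by pixel, producing the
   two degradation maps: the wool/dye amplitude ratio A_w/A_IC (rises as the
   dye fades) and the dye emission peak λ_max,IC (blue-shifts with
   degradation).

Because real cube pairs of this kind are rarely shareable, the package
includes a synthetic scene generator with fiber geometry, a fading 630 nm
absorption band, a blue-shifting emission band, planted specular outliers
and per-pixel ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from fadefit import (RunConfig, SceneConfig, SkewNormalParams,
                     make_threelevel_scene, run_pipeline)

cfg = SceneConfig(shape=(128, 128), noise_sd=0.02, n_specular=10, seed=1)
R, F, truth = make_threelevel_scene(cfg)          # three degradation zones
run = run_pipeline(RunConfig(
    r_cubes=[R], f_cubes=[F],
    wool_params=SkewNormalParams(1.0, 580.0, 95.0, 550.0, 10.0), seed=1))

for name, fit in run.report.cluster_fits.items():
    print(f"{name:5s} peak {fit['ic']['lambda_max']:.1f} nm "
          f"ratio {fit['amplitude_ratio']:.3f}")
print("PC1 variance: %.1f%%" % (100 * run.report.explained_variance_ratio[0]))
print("convergence:  %.1f%%" % (100 * run.report.convergence_rate))
```

Output:

```
blue  peak 691.9 nm ratio 0.051
green peak 663.6 nm ratio 0.175
red   peak 635.0 nm ratio 0.300
PC1 variance: 71.0%
convergence:  100.0%
```

The blue (well-preserved) cluster's dye emission peaks at ~692 nm with a
wool/dye amplitude ratio of ~0.05; with increasing degradation the peak
shifts hypsochromically toward 635 nm and the ratio climbs toward 0.3 —
exactly the generator's planted endpoints. `run.maps.peak_map` and
`run.maps.ratio_map` hold the per-pixel values; `run.segmentation.rgb` the
false-color cluster image.

The same pipeline is available from a shell:

```sh
fadefit simulate --out scene/ --seed 1 --shape 128 128
fadefit run --work-dir out/ --seed 1 \
    --r-cube scene/reflectance --f-cube scene/fluorescence \
    --wool-params-json wool.json
fadefit report --work-dir out/
```

`preprocess`, `segment` and `fit` run the corresponding stages individually
against a shared work directory.

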
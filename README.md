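# skinfab

From an RGB photograph of human skin to a printer-ready multilayer job.

Human skin colour is dominated by two chromophores: melanin in the epidermis
and hemoglobin in the dermis. Under the modified Lambert–Beer model the
observed optical density of a skin pixel is linear in the two pigment
concentrations,

```
-log ρ_c = m·w_mel,c + h·w_hem,c + bias_c − s·ℓ_c ,   c ∈ {R, G, B}
```

where `w_mel`, `w_hem` are per-channel absorbance vectors, `s` is a shading
(illumination-intensity) offset acting along the unit direction `ℓ`, and
`bias` is the stationary part of skin colour. Shading-free densities
therefore live on a 2-D plane in density space, and the pigment maps `m(x,y)`
and `h(x,y)` can be recovered blindly: PCA of a small, evenly lit region
gives the plane, an oblique projection along `ℓ` removes shading exactly,
and 2-D independent component analysis finds the two pigment axes within the
plane.

`skinfab` implements that separation and everything needed to turn the
recovered maps into a layered print job for a UV inkjet printer that can
stack CMYK, white and clear inks:

* **separation** — colour-plane PCA, exact oblique shading removal,
  stabilised fixed-point ICA (tanh contrast, deflation), concentration
  projection;
* **calibration** — a 30 × 30 grid of pigment-concentration patches (900
  combinations) and three interchangeable concentration→CMYK estimators: a
  nearest-neighbour lookup table, per-channel least squares on log-RGB
  features (`D_i = a_R log R + a_G log G + a_B log B + b`), and a small
  neural network (hidden layers 20/30/20, ReLU, Adam); leave-one-out
  cross-validation and a paired t-test compare them;
* **halftone** — Floyd–Steinberg error diffusion (kernel 7/16, 3/16, 5/16,
  1/16) at the largest dot size, with nearest-neighbour resampling to the
  printer's anisotropic grid (e.g. 720 dpi horizontal × 1200 dpi vertical);
* **layerstack** — the canonical clear/melanin/clear/hemoglobin/clear/white
  stack with configurable clear-spacer thicknesses ({2,4,6} × {2,4,6} gives
  the nine standard samples) and a lossless JSON-manifest job format;
* **synth** — a forward optical model (renderer, sensor noise, phantom
  concentration maps, virtual print-and-capture press) so the whole pipeline
  runs and is tested without a camera or a printer.

## Worked example

```python
import numpy as np
from scipy.stats import pearsonr
import skinfab as sf

basis = sf.default_basis()
truth = sf.make_phantom("palm_like", 128, 128, seed=0)
photo = sf.add_sensor_noise(sf.render_skin(truth, basis), sigma=0.003, seed=1)

# blind separation: PCA plane -> shading removal -> 2-D ICA -> projection
maps, est = sf.separate(photo, seed=0)
for name in ("melanin", "hemoglobin"):
    r = pearsonr(getattr(maps, name).ravel(), getattr(truth, name).ravel())[0]
    print(f"{name:11s} recovery r = {r:.3f}")
print("estimated hemoglobin direction:", np.round(est.hemoglobin_vector, 3))

# calibrate concentration -> CMYK on a virtual patch chart
patches = sf.measure_patch_set(sf.build_patch_set(30, 30, est), seed=0)
rmse_reg, err_reg = sf.loocv(patches, "regression")
rmse_lut, err_lut = sf.loocv(patches, "lut")
print(f"LOOCV RMSE  regression = {rmse_reg:.4f}   lut = {rmse_lut:.4f}")
test = sf.compare_methods(err_reg, err_lut)
print(f"paired t-test p = {test.p_value:.2e}  significant: {test.significant}")

# full run: separate -> CMYK -> resample -> halftone -> stack -> write job
cfg = sf.PipelineConfig(seed=0, method="regression",
                        src_dpi=(360, 360), dst_dpi=(720, 1200))
manifest = sf.run_pipeline(cfg, photo, out_dir="scratch/job")
print("layers:", [l["name"] for l in manifest["layers"]])
print("printer grid:", manifest["dims"], "at", manifest["dpi"], "dpi")
```

Output:

```
melanin     recovery r = 0.971
hemoglobin  recovery r = 0.986
estimated hemoglobin direction: [0.331 0.747 0.577]
LOOCV RMSE  regression = 0.0007   lut = 0.0044
paired t-test p = 0.00e+00  significant: True
layers: ['clear1', 'melanin', 'clear2', 'hemoglobin', 'clear3', 'white']
printer grid: [427, 256] at [720, 1200] dpi
```

The recovery correlations say the blind separation reproduced the generating
pigment maps almost exactly despite sensor noise; the estimated hemoglobin
direction absorbs green most strongly, as it should. Regression beats the
lookup table on these patches and the paired t-test confirms the difference.
The job directory holds one 1-bit PNG per ink channel per colour layer plus
a manifest with the layer order, spacer thicknesses and the exact
configuration that produced it — running the same config and seed again
reproduces it byte for byte.

The same stages are available from the shell:

```
skinfab synth --kind palm_like --size 128x128 --out skin.png
skinfab separate --image skin.png --out maps/
skinfab run --image skin.png --out job/
```

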
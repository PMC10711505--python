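# lungt2star

Quantitative T2* relaxometry of the developing fetal lung, as a tested,
reusable Python pipeline. Fetal lung maturity is normally assessed by size
alone; T2* mapping from multi-echo gradient-echo MRI adds a functional signal
that tracks tissue perfusion and composition, and both the mean lung T2* and
its spread increase across gestation. This package is for imaging scientists
who want that analysis chain — and its calibration — reproducible end to end
without access to scanner data: every stage can be driven by a built-in
digital thorax phantom and synthetic cohort generator with known ground truth.

What it does:

* **Simulation** — thorax phantoms (two lung ellipsoids, heart, body) whose
  analytic lung volume grows with gestational age (GA), multi-echo magnitude
  signals `S(TE) = S0·exp(−TE/T2*)` with Rician noise at the standard 3 T
  protocol (5 echoes, 13.8–240.2 ms, 3 mm isotropic), and cohort tables whose
  GA distribution matches a target summary (29.9 ± 4.3 weeks on
  [20.6, 38.3]).
* **Relaxometry** — voxelwise mono-exponential fitting (closed-form
  log-linear and bounded NLLS with log-linear initialisation), with clamping,
  status flags and R² maps.
* **ROI metrics** — per-lung and pooled mean/SD/median T2*, volumes (mL),
  voxel histograms, paired right-vs-left comparison.
* **Lacunarity** — gliding-box Λ(r) = E[M²]/E[M]² of masked T2* intensities
  as a heterogeneity score, verified against brute-force enumeration.
* **Normative modelling** — linear GA trends (optionally cluster-robust over
  subjects for serial scans), a packaged published reference
  `mean(GA) = 1.488884·GA + 21.997645`, `SD(GA) = 1.488884·GA − 18.451005`
  (ms), and z-scores `z = (observed − mean(GA))/SD(GA)` with exact-normal
  centiles and reference bands.
* **Reliability** — absolute-agreement two-way ICC(A,1)/(A,k) with
  McGraw–Wong 95% confidence intervals.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

```python
import numpy as np
from lungt2star import (
    make_phantom, simulate_multiecho, fit_map, summarize_roi,
    lacunarity_curve, published_model, zscore,
)

phantom = make_phantom(30.0, grid_shape=(48, 48, 48), seed=0)   # 30-week fetus
image = simulate_multiecho(phantom, noise_model="none")
mask = phantom.lung_mask()
t2map = fit_map(image, mask=mask.labels > 0, method="nlls")

s = summarize_roi(t2map, mask, "both")
print(f"both lungs: {s.n_voxels} voxels, mean T2* {s.mean_t2star:.2f} ms, "
      f"volume {s.volume_ml:.1f} mL")
res = zscore(s.mean_t2star, 30.0, published_model())
print(f"z = {res.z:.4f}, centile = {res.centile:.1f}")
curve = lacunarity_curve(t2map, mask, "both", box_sizes=(2, 3, 4))
print("lacunarity:", np.round(curve.lambda_values, 4))
```

prints

```
both lungs: 2092 voxels, mean T2* 66.66 ms, volume 56.5 mL
z = 0.0000, centile = 50.0
lacunarity: [1.     1.0003 1.0011]
```

The phantom's lung T2* defaults to the normative mean at its GA
(1.488884·30 + 21.997645 = 66.66 ms), so the noiseless loop closes: the fitted
combined-lung mean lands back on the reference curve (z = 0, 50th centile),
the 56.5 mL digitised volume tracks the analytic 56 mL ellipsoid volume, and
lacunarity sits at 1 (homogeneous field; the tiny excess at larger boxes comes
from partially covered boxes at the lung boundary).

A command-line interface exposes the same stages
(`lungt2star simulate-phantom | simulate-cohort | fit-t2star | roi-metrics |
lacunarity | normative-fit | normative-apply | icc | run`); `lungt2star run
--n 20 --seed 1 --out run/` executes the whole synthetic study and writes
per-scan metrics, histograms, lacunarity curves, z-scores and the resolved
configuration, byte-identically reproducible for a given seed.

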
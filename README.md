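# ccflow

Quantification of **choriocapillaris flow deficits** from en-face
swept-source OCT-angiography image pairs.

The choriocapillaris — the capillary monolayer feeding the outer retina
— appears on an en-face OCTA flow projection as a bright granular mesh
interrupted by dark non-perfused gaps ("flow deficits", FDs). Overlying
deposits cast shadows that masquerade as deficits, so quantification
proceeds in stages:

1. **Compensation** — the flow image is multiplied by the inverted,
   Gaussian-smoothed structure image (both channels carry the same
   shadow), then rescaled by its global maximum.
2. **Binarization** — Phansalkar local adaptive thresholding, the
   standard for low-contrast capillary images:
   `T = m · (1 + p·e^(−q·m) + k·(s/r − 1))`, with window mean `m` and
   SD `s` over a square window of radius 4 or 8 px, and the canonical
   constants `k = 0.25, r = 0.5, p = 2, q = 10` on [0, 1] intensities.
   A pixel is a deficit iff its intensity ≤ T.
3. **Particle metrics** — within four 1 × 1 mm squares flush with the
   corners of the 6 × 6 mm scan (clear of any central neovascular
   lesion), connected components of deficit pixels (8-connectivity, no
   size/circularity exclusion) give **FD%**, **FD count**, **mean FD
   size (µm²)** and **total FD area (mm²)**; per-eye values are the
   means over the four corners.
4. **Group comparison** — mean ± SD per group with two-sided
   nonparametric tests (Wilcoxon signed-rank or Mann–Whitney U; exact
   small-sample paths by full enumeration).

Because no public choriocapillaris dataset exists, the package ships a
**synthetic generator**: correlated-Gaussian-field void textures with
exactly known void fraction, multiplicative shadow blobs shared between
the flow and structure channels, speckle noise, and whole two-group
cohorts with per-eye derived seeds.

## Worked example

Generate a 27 + 27 eye synthetic cohort (controls: void fraction
0.39 ± 0.06; diseased eyes: 0.48 ± 0.08 with coarser texture) and run
the full pipeline:

```python
from ccflow import (CONTROL_PARAMS, DISEASE_PARAMS, PipelineConfig,
                    generate_cohort, run_pipeline)

manifest, _ = generate_cohort(CONTROL_PARAMS, DISEASE_PARAMS,
                              n_per_group=27, seed=1, out_dir="cohort/")
result = run_pipeline(manifest, PipelineConfig(), out_dir="results/")
print(result.tables["metrics_r4"])
```

which prints (radius-4 and radius-8 rows shown together):

```
r4  mean FD%                    streaks    47.33 ±     7.25   control    38.73 ±     6.64   p = 2.73e-04
r4  mean number of FDs          streaks    12.01 ±     3.55   control    26.19 ±     6.16   p = 6.64e-06
r4  mean FD size (um2)          streaks 51062.37 ± 26340.69   control 16901.13 ±  7165.11   p = 1.16e-05
r4  mean total FD area (mm2)    streaks     0.48 ±     0.07   control     0.39 ±     0.07   p = 2.73e-04
r8  mean FD%                    streaks    47.77 ±     7.37   control    38.99 ±     6.71   p = 2.48e-04
r8  mean number of FDs          streaks    12.00 ±     3.53   control    26.19 ±     6.16   p = 6.64e-06
r8  mean FD size (um2)          streaks 51565.83 ± 26636.69   control 17016.34 ±  7217.80   p = 1.04e-05
r8  mean total FD area (mm2)    streaks     0.48 ±     0.07   control     0.39 ±     0.07   p = 2.48e-04
```

Diseased eyes show a higher deficit fraction and total area, larger but
fewer deficits — the mean FD% per group recovers the generator's void
fractions (≈ 48% vs ≈ 39%) because measured FD% tracks true void
fraction to within a few percentage points.

The same analysis is available from the shell:

```sh
ccflow synth --out cohort/ --n 27 --seed 1
ccflow run --manifest cohort/manifest.csv --out results/
```

`results/` then contains `per_eye_metrics.csv`, per-radius group tables
(`group_metrics_r4.csv`, `group_corners_r4.csv`, ...), optional QC
panels, and `run_log.txt` with every parameter of the run.

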
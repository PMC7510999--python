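# tempopet

Temporal-domain radiomics for dynamic PET.

Conventional PET radiomics quantifies the *spatial* heterogeneity of tracer
uptake in a tumour from a single static image.  Dynamic [¹⁸F]FDG
acquisitions add a time axis: how uptake evolves frame-to-frame may carry
information about tumour biology that no static feature sees.  `tempopet`
implements the full toolchain needed to ask that question quantitatively:

* **Static/parametric features** — the standard 90-feature set
  (intensity 18, shape 13, GLCM 22, GLRLM 16, GLSZM 16, NGTDM 5) per IBSI
  definitions, with 13-direction merged texture matrices, computable on the
  static SUV image and on Patlak parametric metabolic-rate images through
  the same code path.
* **Temporal (dynamic) features** — 38 novel features (22 GLCM + 16 GLRLM)
  from texture matrices built along the time axis only, direction
  (x, y, z, t) = (0, 0, 0, 1).  Time is causal, so voxel pairs are counted
  in one direction and the temporal co-occurrence matrix is *not*
  symmetrised: stable uptake concentrates mass on the diagonal, monotone
  uptake above it.
* **Patlak graphical analysis** — for irreversible uptake,
  C_t(t)/C_p(t) = K_i·x(t) + V₀ with x(t) = ∫₀ᵗC_p dτ / C_p(t) the
  normalised Patlak time; a least-squares line through the late points
  (x ≥ t*, default 15 min) yields the influx constant K_i (min⁻¹) per
  voxel, and MR_glc = K_i · [glucose] / LC.
* **Fixed-bin-width discretisation** — population-based Freedman–Diaconis
  widths, w = 2·IQR·N^(−1/3), applied per image and per dynamic frame with
  bin edges anchored at 0 so a grey level means the same absolute intensity
  in every lesion and frame.
* **Redundancy and robustness analysis** — Spearman rank correlations:
  a dynamic feature is redundant when |ρ| > 0.7 with *any* static feature;
  a parametric feature when its same-name static counterpart has ρ > 0.7;
  a dynamic feature is robust to frame duration when its 150 s- and
  300 s-frame versions correlate at ρ > 0.7 across a cohort.
* **Synthetic 4D phantoms** — lesions with known voxelwise Patlak kinetics
  (analytic exponential-mixture plasma input, exact frame averages), so the
  whole pipeline is testable without any data download and Patlak recovery
  is exact on noiseless data.

## Worked example

```python
import numpy as np
from tempopet import generate_phantom
from tempopet.patlak import ParametricSettings, compute_parametric_image
from tempopet.discretise import DiscretisationScheme, population_width
from tempopet.grid_io import extract_voi_values
from tempopet.static_radiomics import extract_static_feature_set
from tempopet.temporal_radiomics import extract_dynamic_feature_set

# a 16 x 150 s dynamic acquisition (10-50 min p.i.) of one synthetic lesion
ph = generate_phantom(seed=11, noise_sd=0.02)
print("VOI voxels:", ph.voi_mask.n_voxels)

mrglc, ki = compute_parametric_image(
    ph.series, ph.plasma, ParametricSettings(plasma_glucose=ph.truth.plasma_glucose))
m = ph.voi_mask.mask
print(f"median fitted Ki: {np.median(ki.values[m]):.4f} min^-1 "
      f"(truth {np.median(ph.truth.ki_map[m]):.4f})")

values, _ = extract_voi_values(ph.series.frame(15), ph.voi_mask)
w = population_width([values])           # Freedman-Diaconis, cohort of one
static = extract_static_feature_set(ph.series.frame(15), ph.voi_mask,
                                    DiscretisationScheme(w))
widths = [population_width([ph.series.data[..., t][m]])
          for t in range(ph.series.n_frames)]
dynamic = extract_dynamic_feature_set(ph.series, ph.voi_mask, widths)
print("static:", len(static), " dynamic:", len(dynamic))
print(f"dyn_glcm/Contrast = {dynamic[('dyn_glcm', 'Contrast')]:.3f}")
```

prints

```
VOI voxels: 1272
median fitted Ki: 0.0127 min^-1 (truth 0.0127)
static: 90  dynamic: 38
dyn_glcm/Contrast = 1.412
```

The fitted K_i map recovers the simulated kinetics (exactly so at zero
noise).  The 90 static features and 38 temporal features per lesion, plus
90 parametric features from the MR_glc image, give the combined 218-feature
set the redundancy analysis operates on.  The small temporal Contrast
(1.41, versus 24.8 spatially) reflects that frame-to-frame grey-level
changes are gradual: mass sits near the matrix diagonal.

## Command line

```bash
tempopet phantom --out ph/ --seed 3 --noise 0.02 --frames 16x150
tempopet extract-static --image ph/frame_015.nii.gz --mask ph/mask.nii.gz \
    --bin-width 0.05 --out static.tsv
tempopet patlak --frames ph/ --plasma ph/plasma.csv --glucose 5.0 --out ki.nii.gz
tempopet run-cohort --config cohort.yaml --out results/
```

where `cohort.yaml` may simply read
`synthetic: {n_lesions: 20, seed: 1, noise_sd: 0.02}`.  `run-cohort` writes
the four feature tables, the robustness and redundancy reports and the bin
widths used.

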
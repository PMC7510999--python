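# Methods

This note documents the models, numerical conventions and design choices
behind `tempopet`, and what the synthetic phantom does and does not emulate.

## Kinetic model and phantom

Tissue activity follows the irreversible-uptake linear form that Patlak
graphical analysis assumes,

    C_t(t) = K_i · ∫₀ᵗ C_p(τ) dτ + v_b · C_p(t),

with per-voxel influx constant K_i (min⁻¹) and blood-volume fraction v_b.
We simulate this form directly rather than integrating a two-tissue
compartment ODE: it is exactly the model the parametric analysis assumes,
so the phantom provides exact recovery targets (the Patlak fit has zero
residual on noiseless data by construction).

The plasma input is a sum of exponentials, by default
`25·e^(−3.0t) + 5·e^(−0.12t) + 2·e^(−0.01t)` (t in minutes, amplitudes in
arbitrary activity-concentration units): a fast early decay plus a slow
washout, qualitatively FDG-like.  All running integrals are closed-form,
so each frame stores the exact *time average* of C_t over its window — the
activity-concentration convention of reconstructed PET.  Consequently
frame summing is a duration-weighted mean and durations add.

Default lesion geometry: an ellipsoid (random semi-axes 5.5–8.5 voxels on
a 24³ grid at 3 mm isotropic spacing, ≥ ~700 voxels) with a smooth ±30 %
K_i gradient along a random direction plus a focal sub-region
(K_i × 1.6–2.4), in a low-uptake background (K_i = 5·10⁻⁴ min⁻¹).  Lesion
parameters (K_i base 0.012–0.030 min⁻¹, v_b 0.02–0.08, plasma glucose
4.5–6.5 mmol/L, plasma amplitude ±20 %) vary per lesion, which is what
gives cohort-level rank correlations something to rank.

Noise is zero-mean Gaussian with standard deviation `noise_sd × |signal|`,
fully determined by an integer seed (phantom regeneration is bit-identical
per seed).  The cohort default is `noise_sd = 0.02`, a low-noise regime
appropriate for frame-duration robustness checks.

What the phantom does **not** emulate: Poisson projection noise and
reconstruction correlations, attenuation/scatter, partial-volume blur,
patient motion, metabolite-corrected input functions, or anatomically
realistic shapes.  Passing tests therefore demonstrate correctness of the
computational pipeline and its invariants on model-true data — not
clinical performance on scanner data.

The dynamic window is 10–50 min post-injection as sixteen 150 s frames;
eight 300 s frames are their pairwise duration-weighted sums (both framings
derive from the same simulated acquisition, as rebinned listmode data
would).  The static image is a separately simulated 50–60 min frame.

## Patlak analysis

Normalised Patlak time is x(t) = ∫₀ᵗC_p/C_p(t); the fit is ordinary least
squares of y = C_t/C_p on x over points with t* ≤ x ≤ t_end (defaults 15
and 60 min, in normalised time).  Because frames store time averages, the
transform evaluates ⟨C_p⟩ and ⟨∫C_p⟩ as frame-window averages too; on
model-true data this keeps y = K_i·x + v_b exact (no midpoint
approximation), while the frame midpoint remains the sample's nominal
time.  For sampled (CSV) plasma curves the integrals use trapezoid
quadrature on a dense grid; for analytic curves they are closed-form.
Frames with non-positive averaged plasma are dropped with a log entry;
voxels left with fewer than two usable points would fail the fit, which is
reported as an error at image level (the shared design matrix means the
condition is global, not per voxel).  MR_glc = K_i·[glucose]/LC with the
lumped constant LC defaulting to 1; with glucose in mmol/L the MR_glc unit
is mmol·L⁻¹·min⁻¹ (numerically µmol·mL⁻¹·min⁻¹).

## Grids, resampling, discretisation

Images are axis-aligned (spacing + origin); NIfTI via nibabel.  Trilinear
resampling aligns the input and output grid *centres* in world
coordinates; the output extent covers the span between outermost voxel
centres (fence-post convention), so an integer spacing ratio places output
samples exactly on input centres.  Out-of-support samples clamp to the
nearest edge value, which avoids injecting zeros into tumour-adjacent
bins.  Masks are interpolated as real fields and binarised at 0.5 (the
volume-preserving choice); dynamic frames are resampled independently and
restacked.

Discretisation is fixed-bin-width: level = ⌊x/w⌋ + 1 with edges anchored
at 0, so levels are comparable across lesions and frames on an absolute
intensity scale.  Widths come from the Freedman–Diaconis rule
w = 2·IQR·N^(−1/3) using cohort-mean IQR and voxel count; dynamic frames
each get their own population width, and the *global* Ng (max over frames)
dimensions the temporal matrices so one level means one bin everywhere.
Negative intensities inside the VOI (possible in reconstructed
backgrounds) are clamped to 0 with a logged count; widths are used at full
floating precision (printed 2-decimal widths are for reporting only).

## Texture matrices and features

Spatial GLCM/GLRLM accumulate over the 13 unique non-opposite unit offsets
(the 26 neighbours modulo sign) and are merged into one matrix; the GLCM
counts both senses of every pair and is symmetric.  GLSZM uses
26-connected zones; NGTDM uses in-mask 26-neighbourhood means.  Matrix
dimension Ng is the highest occupied level; empty rows contribute nothing.
No distance weighting, no intensity normalisation, no grey-level
dependence family.

Temporal matrices use the single causal direction (0,0,0,1): the temporal
GLCM pools (level_t, level_{t+1}) pairs over all voxels and transitions —
one direction only, never symmetrised (total count N_vox·(T−1)); the
temporal GLRLM scans maximal constant-level runs along each voxel's time
course (weighted total N_vox·T).  Temporal GLSZM/NGTDM are deliberately
absent: their neighbourhoods would mix spatial and temporal steps, which
are not interchangeable.  Pairs are pooled across all transitions into one
matrix (per-transition averaging would be the alternative; pooling keeps
counts integral and the conservation laws exact).

GLCM feature formulas are written with explicit row/column marginals
(μ_x, μ_y, σ_x, σ_y), so one implementation serves the symmetric spatial
matrix and the asymmetric temporal one; they reduce to the textbook
definitions when the matrix is symmetric.  Cluster features use
(i + j − μ_x − μ_y); JointAverage and SumSquares use the row marginal.

The 90-feature static set is partitioned 18/13/22/16/16/5:

* intensity (18): Energy, TotalEnergy, Entropy, Minimum, Percentile10,
  Percentile90, Maximum, Mean, Median, InterquartileRange, Range,
  MeanAbsoluteDeviation, RobustMeanAbsoluteDeviation, RootMeanSquared,
  Skewness, Kurtosis (non-excess), Variance (population), Uniformity.
  Entropy/Uniformity use the discretised histogram.
* shape (13): MeshVolume, SurfaceArea, SurfaceVolumeRatio, Sphericity,
  Maximum3DDiameter, Maximum2DDiameter (axial/coronal/sagittal),
  Major/Minor/LeastAxisLength, Elongation, Flatness.  The voxel-counting
  volume is excluded to keep the family at 13.  The surface comes from
  marching cubes on the zero-padded mask at iso-level 0.5 in mm
  coordinates; planar diameters are maximal pairwise distances of
  convex-hull surface vertices projected onto the respective plane; axis
  lengths are 4·√λ from the PCA of voxel-centre coordinates.
* glcm (22): the standard set without SumAverage, MCC and the deprecated
  homogeneity/dissimilarity duplicates.
* glrlm/glszm (16 each), ngtdm (5): standard definitions;
  RunPercentage = N_runs/(N_vox·13) spatially and N_runs/(N_vox·T)
  temporally.

Degenerate conventions (single grey level): Correlation → 1, IMC1 → 0,
IMC2 → 0, InverseVariance omits i = j terms, Skewness/Kurtosis of a
constant sample → 0, NGTDM Coarseness with zero tone difference → 10⁶.
These make constant VOIs produce finite, deterministic vectors instead of
NaN.

## Correlation analysis

Spearman ρ is the Pearson correlation of mid-ranks (average ranks on
ties), computed via `scipy.stats.spearmanr`; a constant column has
undefined ρ and is excluded from max reductions with a warning, never
treated as 0.  The dynamic-vs-static redundancy rule uses max |ρ| over all
static features (> 0.7 ⇒ redundant); the parametric rule compares only
same-name pairs with signed ρ > 0.7 (the definitions of the features are
identical, so the association of interest is positive).  Strength labels:
|ρ| < 0.3 negligible, 0.3–0.5 low, 0.5–0.7 moderate, > 0.7 high.

## Problem sizes and determinism

The built-in cohort used by the tests and the acceptance script has 20
lesions on 24³ grids with 16 × 150 s frames at `noise_sd = 0.02`; a full
cohort analysis (static + parametric + two dynamic tables + all reports)
takes a few seconds.  All randomness flows from integer seeds through
`numpy.random.default_rng`; a cohort run is byte-reproducible for a fixed
(n_lesions, seed, noise_sd).

## Known limitations

* Shape features follow the mesh conventions above; other packages'
  per-slice 2D diameters can differ slightly from the projected-hull
  definition on strongly concave lesions.
* The analytic plasma model has no metabolite correction or dispersion;
  t* in normalised time is exposed as a setting because its mapping to
  real acquisition time depends on the input function.
* The file-based cohort path of the CLI covers synthetic blocks; mixed
  file/synthetic cohorts are assembled through the library API.
* Correlation reports at n = 20 lesions are analogues of cohort-scale
  behaviour, not estimates of any clinical dataset's values.
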
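# Methods

## The prediction problem

A cortical voxel's measured CBF (ASL or nuclear-medicine) is a
partial-volume mixture: with gray-matter occupancy g ∈ [0, 1],

    measured ≈ g · CBF_GM + (1 − g) · CBF_WM,

so a voxel that is half white matter reports roughly the average of
gray-matter perfusion (~60 mL/100g/min) and the much lower white-matter
perfusion (~20 mL/100g/min). The predictor learned here maps each voxel's
resting-state BOLD spectral features *plus its occupancy* to measured CBF;
withholding the occupancy feature (setting it to 0, the "original" mode)
reproduces the uncorrected baseline the corrected model is compared
against. The comparison is the package's central claim: the occupancy-aware
model predicts held-out regional CBF better because occupancy carries the
anatomical component of the measurement that spectral features cannot.

## Spectral features

- Estimator: plain one-sided periodogram of the linearly detrended series
  on the raw DFT grid — no Welch segmentation, no taper. The scaling makes
  the ordinates sum to the detrended sum of squares (Parseval), so "band
  power" is literally the share of signal energy in the band. Band power is
  the *sum* of ordinates in the half-open bin [midpoint − 0.04, midpoint +
  0.04) Hz; a per-bin *mean* (density convention) is available via
  `average=True` and differs only by a per-bin constant. The 0 Hz ordinate
  is always excluded; detrending removes the DC and linear-drift components
  anyway.
- Bins: midpoints 0.04–0.60 Hz in steps of 0.08, width 0.08 — a contiguous
  partition of (0, 0.64) Hz. Frequencies above 0.64 Hz are discarded.
- Nyquist handling: with TR = 0.8 s the Nyquist frequency is 0.625 Hz, so
  the top bin is only partially sampled — exactly as in real multiband
  fMRI. `band_powers` refuses such data unless `allow_partial=True`, in
  which case bins lying entirely above Nyquist are zero-filled and flagged
  in the matrix metadata; partially covered bins sum whatever ordinates
  exist. The pipeline runs with `allow_partial=True`.
- Neighbour stacking: the six face neighbours in the fixed order x−, x+,
  y−, y+, z−, z+. A neighbour outside the mask or grid is replaced by the
  centre voxel's 8-vector (default; avoids a spurious power deficit at mask
  borders) or by zeros (`neighbor_policy="zero"`).
- No per-voxel normalization of band powers: the model's z-standardization
  (below) handles scale.
- Occupancy preparation mirrors the standard T1 pipeline: clip to [0, 1],
  Gaussian smooth at 5 mm FWHM (σ = FWHM/2.3548 per axis, reflective
  boundaries), resample to 2 mm — by exact block averaging when the target
  is an integer multiple of the native spacing, linear interpolation
  otherwise — and clip again.

## The regression model

RBF-kernel SVR (scikit-learn/libsvm) on z-standardized features and
targets; standardization statistics always come from the training rows
only. Defaults: C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 1/57, 0.1, 1, 10} (on
standardized features), ε = 0.1 standardized units, 10-fold CV grouped by
subject (so one subject's voxels never straddle a fold boundary; a flag
disables grouping). The grid point with the smallest mean fold RMSE wins;
ties break toward smaller C, then smaller γ; a non-finite fold loss
disqualifies the grid point. Kernel SVR cannot ingest every cortical voxel
of every subject (~2×10⁵ per subject), so training pools a seeded uniform
subsample per subject (`voxels_per_subject`, default 2000) — this
subsample size is the main practical knob and is recorded in the model
metadata. Cohort splitting draws seeded 2/3–1/3 splits until a two-sample
age t-test and a Fisher exact sex test both give p > 0.2 (max 1000 draws),
reporting the achieved p-values.

## Regional and group statistics

Regional values are means over in-mask voxels per atlas region, pooling
left and right hemispheres by default (34 values for a Desikan–Killiany
cortical atlas; per-hemisphere output via `bilateral=False`). Correlation
p-values use the exact t-transform with df = n − 2. Model comparison uses
the independent-samples Fisher r-to-z formula — both correlations come
from the same test subjects, but the published Z values follow the
independent form, so it is the default and a Steiger dependent-correlations
variant is provided. Cohen's d uses the pooled SD with Student's t
(Welch behind a flag); sign convention is cases minus controls, so
hypoperfusion in cases is negative. No covariate adjustment by default; an
optional residualize-on-covariates step exists. Multiple comparisons use
Bonferroni only (α/34 for the regional tables).

## Bundled reference tables

Two published per-region tables ship as TSVs: regional predicted-vs-
measured correlations for both modes with their Fisher comparisons
(~100 test subjects with paired ASL), and regional MDD case–control
effect sizes from rsfMRI-predicted CBF (biobank cohort) and SPECT CBF
(clinical cohort). Their headline statistics (column means 0.43/0.14,
significance counts 31/32/18, whole-brain Z = 1.95, agreement r) are
recomputed, not stored. One caveat: the tables print d and r to 2
decimals, and the agreement correlation over the rounded d pairs comes out
0.72 where the unrounded published value is 0.74; the difference is purely
printed precision.

## The synthetic forward model

The generator defines the study conditions the method is validated under.

- **Phantom.** An ellipsoidal-shell "cortex" on a 24×24×12 grid of 2 mm
  voxels: occupancy is a Gaussian bump of radial distance to the shell
  mid-surface (peak 0.95, thickness 2 voxels), the analysis mask is
  occupancy > 0.1 (~3100 voxels), and the ribbon is carved into 8
  bilateral parcels by angular sector.
- **Subject CBF.** Regional true GM CBF = 60 (population mean) + a fixed
  regional pattern (SD 6, shared by all subjects of a study) + a
  per-subject regional fluctuation (SD 5) + a smooth voxel field (SD 4,
  3-voxel Gaussian). Latent band powers are a fixed positive band profile
  scaled per voxel so that the linear link true = a·powers holds *exactly*
  (weights a decreasing from 1.0 to 0.15 across bands), times a smooth
  per-band log-normal jitter (SD 0.10) so the 8 features are not
  collinear. The causal direction (powers → CBF) is a modelling
  convenience; the method only requires that a learnable link exists.
- **Time series.** T = 240 samples at TR = 0.8 s. Each band's power is
  injected as complex Gaussian rFFT coefficients confined to the band
  (clipped at Nyquist) and rescaled so the periodogram band power equals
  the latent target exactly; a broadband floor of 5% relative power is
  added. This makes the generator oracle-friendly: the analysis estimator
  recovers the latent powers to a median relative error of ~7%.
- **Measurement.** Per-subject occupancy is the phantom ribbon times a
  per-region "thickness" factor ~N(1, 0.10), clipped to [0, 1]; measured
  CBF = occ·true + (1 − occ)·20 + N(0, (0.2·SD_spatial(true))²). At zero
  noise the mixing identity is exact by construction.
- **Group effects.** `effect_map` gives per-region case shifts in Cohen's
  d units *on the measurement scale*: the generator estimates each
  region's between-subject SD of measured regional CBF once (300
  effect-free subjects, fixed internal seed, cached) and shifts the case
  group's true regional CBF by d·SD_r/mean-occupancy, so the injected d is
  recovered without attenuation. At n = 200/200 the d estimator's own
  sampling SD is ~0.1, which bounds how precisely any single cohort can
  reproduce the injected value.
- What the generator does *not* emulate: hemodynamic response shape,
  physiological (cardiac/respiratory) noise, motion, scanner drift,
  spatial autocorrelation of measurement noise, or realistic cortical
  geometry. Passing tests therefore show the pipeline recovers the
  structure it assumes, not that real BOLD data carry this much CBF
  information.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end study at
reduced size — 16×16×10 phantom (6 parcels, ~1200 mask voxels), 18
subjects (12 train / 6 test), 150 training voxels per subject, T = 160,
C ∈ {1, 10} × γ ∈ {1/57, 0.1}, 3 folds — chosen so one replicate takes a
few seconds while preserving every stage of the computation; ten seeded
replicates of the original-vs-corrected contrast give gaps of ~0.1–0.7 in
mean regional r, far larger than replicate noise. Determinism: one master
seed fans out to named substreams (cohort, split, per-mode subsampling and
CV) via CRC-derived `SeedSequence` children; reruns are bit-identical.
Affine equality for alignment checking is hashed at 1e-4 mm. Result TSVs
print floats at 6 significant digits.

## Known limitations

Kernel SVR scales quadratically in pooled training voxels, so very large
`voxels_per_subject` is impractical. Subcortex is out of scope (the
predictor is trained for cortical voxels). The Fisher comparison treats
the two modes' correlations as independent samples even though they share
test subjects (matching the published convention); the Steiger variant is
the statistically stricter alternative. The synthetic ribbon's parcels are
angular sectors, not anatomically shaped regions; bilateral symmetry is
exact by construction.
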
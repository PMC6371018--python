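# Methods

This note records the models, parameter choices and numerical decisions
behind `y90quant`, and what the synthetic experiments do and do not show.

## Image model and conventions

A `VoxelGrid` is a 3-D lattice with isotropic-or-not voxel spacing (mm), a
voxel-centred world origin (world = origin + index × spacing) and a units
tag (`cps`, `MBq`, `MBq_s`, `mGy`, `Gy`, `unitless`). Units are checked at
every operation boundary — converting counts to activity is an explicit
division by a calibration factor, never an implicit cast. Masks must share
their image's exact grid; statistics never resample implicitly. The
canonical on-disk format is NIfTI (masks as 0/1 uint8); a DICOM series
reader is provided as a convenience import only. The default voxel size
throughout is 4.664 mm isotropic, the reconstruction grid of the SPECT/CT
protocol this workflow targets. CT-space contours are assumed rasterised to
the SPECT grid by nearest-neighbour resampling (`resample_to`, order 0).

## Richardson–Lucy contrast recovery

The collimator–detector response is an isotropic Gaussian with
σ = FWHM/√(8 ln 2), sampled at voxel centres, truncated at 4σ and
normalised to unit sum; convolutions are separable with reflective
boundaries (best count conservation near edges). The RL update keeps the
PSF fixed; the observed image is the initial estimate. The ratio
denominator is floored at 1e−12 — standard RL stabilisation for empty
regions. Defaults: FWHM 12 mm (representative of a medium-energy collimator
at ~90 keV; the protocol itself does not fix a value), 15 iterations
maximum.

The stopping rule selects the 1-based iteration with the global maximum of
the 34 mm-sphere Q_H among iterations whose whole-image RMSE declined
relative to the previous iterate; the first iteration is vacuously eligible
(it has no predecessor to rise from), which also makes a constant-Q_H trace
select iteration 1. Ties break to the smaller index. RMSE is computed over
the whole image, not a VOI. Patient images, which have no phantom VOIs, use
the phantom-calibrated iteration (default 6) rather than a per-patient
rule. The `central_slice` Q_H variant restricts the sphere mean to the
axial slice through the mask centroid (the background mean stays 3-D); it
yields systematically higher values than matched-VOI Q_H and exists for
comparability with the wider literature.

## Calibration and activity

The CF is the slope of an ordinary least-squares fit of count rate on
administered activity, with a free intercept by default (the intercept is
diagnostic; a `through_origin` switch exists because the original analysis
does not state which was used). CI95 = slope ± t₀.₀₂₅,n−2·SE. Report tables
round half-away-from-zero to integers. p-values are reported, never used
for automated decisions.

## Mutual information

Joint histograms use 64 bins by default, linear binning over each image's
own min–max (a constant image degrades to a single bin), and by default
sample only voxels where either image is positive: large empty backgrounds
would otherwise dominate the joint distribution and inflate apparent
alignment. Entropies are in bits; any base gives the same argmax, bits are
for interpretability. Full deformable/affine spatial normalisation is out
of scope — candidates arrive already resampled to a common grid, and the
built-in aligner is an exhaustive integer-translation MI search intended
for closed-loop synthetic tests.

## Chan–Vese segmentation

The two-phase piecewise-constant Chan–Vese energy is minimised over binary
partitions of the liver support, with the contour-length term discretised
as the count of 6-connected faces between phases. The solver is a red–black
iterated-conditional-modes relaxation: a voxel flips phase only if the flip
lowers the energy, opposite-parity neighbours are untouched within a
half-sweep (so simultaneous flips account exactly), and phase means are
refreshed each sweep. Both steps are descent steps, so the recorded energy
trace is non-increasing by construction — this is the property the tests
assert. A checkerboard initialisation starts with near-equal phase means,
under which the boundary term alone would collapse it; a short data-only
(2-means) warm start separates the phases first. Defaults: μ = 0.25 on
min–max-normalised intensities, λ₁ = λ₂ = 1, ≤ 200 sweeps, tolerance 1e−4
on the phase-mean shift, threshold-at-mean initialisation. Intensities are
normalised inside the liver so the same parameters transfer between the
very different MAA and ⁹⁰Y count scales. The higher-mean phase is labelled
tumor; all its connected components are kept (multi-focal disease); a
contrast-free liver returns an empty tumor with `converged=False`. Necrotic
cores receive no special handling — a zero-uptake core falls in the low
phase like any other low-uptake tissue.

## Dosimetry

Cumulated activity assumes a permanent implant with physical decay only:
Ã = A₀·T½/ln 2, T½ = 64.05 h (configurable). Kernel tables declare their
units; the canonical choice is mGy/(MBq·s) paired with Ã in MBq·s — i.e.
"dose per unit cumulated activity", with the time integral carried by Ã
rather than folded into S. Kernels for intermediate voxel sizes are
obtained by per-offset-index linear interpolation between the 3 mm and
6 mm parents (matching how such tables are commonly bridged); this is a
numerical convenience, not transport physics, and a distance-based radial
resampling is available via `method="distance"`. Extrapolated entries are
clipped at zero. Convolution offers a direct spatial engine and an FFT
engine that agree to ~1e−12 relative; both zero-pad, so dose "escaping" the
grid is lost — activity should sit at least one kernel extent inside the
volume for energy bookkeeping to close.

The repo ships only *synthetic* kernels (`make_synthetic_kernel`, and the
two CSVs under `src/y90quant/data/`): an exponential fall-off with distance
(scale 2.5 mm, of the order of the ⁹⁰Y β range) normalised so all emitted
energy (mean 0.9337 MeV per decay) is absorbed within the kernel support.
Magnitudes are therefore plausible for ⁹⁰Y, but real dosimetry requires
published Monte-Carlo kernel tables supplied as CSV.

cDVHs evaluate the fraction of VOI volume at ≥ each of n+1 edges spanning
[0, max]; the trapezoidal area under the curve reproduces the mean VOI dose
to ≤ 1% at 512 bins. Isodose levels threshold at percent-of-maximum and are
nested by construction.

## Synthetic data: what it emulates, what it does not

The digital phantom is a ~6.1 L cylinder (radius 102 mm, height 186 mm)
holding eight spheres of diameter 2–34 mm at 0.52 MBq/ml over a 0.04 MBq/ml
background (13:1). Concentrations are the primary ground truth — per-region
activities follow as concentration × volume, with boundary partial volume
handled by supersampled occupancy fractions (default 4³ sub-voxels;
rasterised sphere activities match closed-form volumes within 1%). A sphere
too small to reach 50% occupancy anywhere (the 2 mm insert at 4.664 mm
voxels) is represented by the voxel containing its centre. Liver studies
are ellipsoids (default semi-axes 90/60/50 mm) with ellipsoidal tumors of
known uptake multiplier, optional zero-uptake necrotic core, and optional
rigid translation between the members of a pair; the healthy-liver
concentration is solved so the total equals the administered activity
exactly. The synthetic cohort (default n = 12) draws administered
activities from 550–2100 MBq and true TLRs from 2–15, spanning the
clinically reported ranges.

The forward model is CF scaling (default 9049 cps/MBq, a phantom-regime
count level), Gaussian blur, and optional Poisson counts at a 35 s
acquisition scaling — there is no projector, attenuation, scatter,
septal penetration or backscatter. Consequently the synthetic studies are
*cleaner* than real bremsstrahlung data: contrast recovery performs better
here than clinically (e.g. the 8–10 mm spheres show some Q_H improvement
that real data does not grant, and the selected iteration tends to the end
of the trace rather than an interior optimum). Passing tests demonstrate
the correctness of the algorithms and the internal consistency of the
chain, not clinical-grade accuracy under unmodelled degradations.

Default grids are 96×96×64 (phantom) and 64×64×48 (liver) at 4.664 mm —
sizes chosen so the full phantom QC run takes ~1–2 s and the 12-patient
cohort run a few seconds, keeping the whole suite fast while leaving the
132³ clinical matrix available through the specs.

## Known limitations

* No tomographic reconstruction: inputs are already-reconstructed volumes.
* The translation-only aligner is not a clinical registration engine.
* The masked truth TLR of a rasterised study deviates from the nominal
  uptake multiplier by a few percent (boundary voxels mix tumor and healthy
  signal); tests use a 5% rasterisation tolerance at 4.664 mm voxels.
* Kernel interpolation across voxel size inherits the acknowledged error of
  bridging tabulated S-values linearly.
* Grubbs' test assumes approximate normality; with heavy-tailed TLR
  distributions it flags the extreme point descriptively, not inferentially.
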
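# y90quant

Quantitative analysis of ⁹⁰Y bremsstrahlung SPECT/CT for liver
radiomicrosphere therapy (radioembolization), with the paired
⁹⁹ᵐTc-MAA planning study as comparator.

## The problem

After ⁹⁰Y microsphere therapy the only routinely available image of where
the spheres actually lodged is bremsstrahlung SPECT/CT. ⁹⁰Y emits no
photopeak photon — the detector sees a continuous bremsstrahlung spectrum —
so the images are low-contrast and badly blurred by the collimator-detector
response, which undermines activity quantification and voxel dosimetry.
This package implements a post-reconstruction processing chain that makes
those images quantitatively usable, and every stage needed to go from a
reconstructed count-rate volume to absorbed-dose reports:

1. **Contrast recovery** — Richardson–Lucy (RL) deconvolution with a fixed
   isotropic Gaussian PSF,

       A′ᵢ = [ A / (A′ᵢ₋₁ ⊗ PSF) ⊗ PSF ] · A′ᵢ₋₁ ,  A′₀ = A,

   where σ = FWHM / √(8 ln 2). The stopping iteration is calibrated on a
   digital hot-sphere (Jaszczak) phantom: the iteration with the maximum
   contrast recovery coefficient Q_H = 100·(C_S/C_B − 1)/(R − 1) for the
   largest sphere, among iterations where the RMSE between consecutive
   estimates declines. Patient images use CNR = (M_T − M_B)/M_B.
2. **Calibration and activity** — the calibration factor CF (cps/MBq) is
   the OLS slope of reconstructed counts vs administered activity (whole
   field of view, or liver VOI only); dividing the image by the CF yields
   MBq, reported with %Error = (true − estimated)/true × 100.
3. **Registration selection** — candidate co-registrations of the
   planning/post-therapy pair are scored by mutual information
   I(A,B) = H(A) + H(B) − H(A,B) (bits, joint intensity histogram) and the
   argmax is kept; a translation-only MI search supports closed-loop tests.
4. **Segmentation and TLR** — a two-phase 3-D Chan–Vese partition of the
   liver VOI labels the high-uptake phase tumor; the tumor-to-liver ratio
   is the ratio of tumor to healthy-liver mean counts per voxel.
5. **Dosimetry** — MIRD voxel S-value convolution D = Ã ⊗ S with
   Ã = A₀·T½/ln 2 (permanent implant, T½ = 64.05 h), kernels linearly
   interpolated between tabulated 3 mm and 6 mm voxel sizes, plus cDVH,
   isodose levels and tumor/healthy dose summaries.

A synthetic-data module generates the digital phantom and paired liver
studies with known ground truth (true activities, TLR, misalignment), so
the whole chain is testable without clinical data. Cohort statistics
(Pearson r, paired t, Grubbs outlier test) close the loop.

Intended users: medical-physics and imaging researchers who want a scripted,
reproducible version of this workflow. The package is a library first
(`import y90quant`, see `examples/`); a thin `y90quant` CLI wraps the same
calls for shell use.

## Worked example

```sh
python examples/phantom_contrast_recovery.py
```

prints (seed 0, 64×64×48 phantom at 4.664 mm, FWHM 12 mm, Poisson noise):

```
selected RL iteration: 15 (max Q_H among RMSE-declining iterations, 34 mm sphere)
calibration factor from phantom counts: 8567 cps/MBq (forward model used 9049)
      sphere  Q_H before  Q_H after  activity err %
 sphere_34mm       67.8%      86.3%            12.6
 sphere_16mm       32.5%      62.7%            29.3
  sphere_8mm        8.1%      18.7%            90.2
  sphere_2mm        0.6%       0.5%          -168.6
```

(abridged). Q_H = 100% would mean the full 13:1 sphere-to-background
contrast survived imaging: deconvolution recovers most of the contrast for
spheres ≥ 16 mm, while sub-voxel inserts remain partial-volume and noise
dominated — and their activity estimates are correspondingly unreliable.
The phantom-derived CF sits a few percent below the forward-model value
because counts blurred across the phantom boundary leave the calibration
VOI. The other `examples/*.py` scripts walk through calibration/activity,
registration selection, segmentation/TLR and dosimetry the same way.

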
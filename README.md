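# dmar — metal artifact reduction for dental CT

Metal implants, crowns and fillings streak and shadow CT images badly
enough to compromise implant planning, and dental CT is the hard case:
teeth attenuate x-rays almost as strongly as metal, so the image- or
projection-domain thresholds that find metal elsewhere misfire on teeth.
`dmar` implements a projection-domain correction built around **adaptive
local thresholding** of the metal trace, for researchers studying MAR
algorithms on simulated CT data.

The method, end to end:

1. Seed the metal trace on the peak-normalized projection data with a
   conservative global threshold `T` (metal where transmission ≤ `T`,
   i.e. `P ≥ -ln T` on attenuation data).
2. Expand each island of seed pixels to the true metal boundary: with
   per-island statistics (min `B`, max `A`, standard deviation `σ`),
   annex window pixels whose value falls in `[B - aσ, A + aσ]`
   within `[s₁ - W, s₂ + W]` (defaults `T = 0.05`, `W = 30`, `a = 2`).
3. Build the prior image from a streak-free reconstruction `I_sf`
   (SART of the linearly in-painted sinogram) and a metal-free image
   `I_mf` (uncorrected FBP with metal nullified), blended by

       w(x, y) = 1 / (1 + (D_n / c)^p),
       I_p = w · I_mf + (1 - w) · I_sf,

   where `D_n` is the min–max-normalized difference of the two images
   (`p = 10`, `c = 0.1` by default).
4. Replace the trace with the forward projection of the prior,
   `P̂ = M · P_orig + (1 - M) · P_prior`, reconstruct with SART, and fill
   the metal back from the uncorrected image.

The package also contains everything needed to study the method without
scanner data: two synthetic phantoms (bilateral titanium prostheses in a
muscle/bone body, and a dental arch with teeth and implants), an
energy-resolved polychromatic projector with published attenuation tables,
FBP/SART reconstruction, and ROI-based SSIM evaluation against an
artifact-free monochromatic reference. A comparison mode (`fp_mar`) runs
the same pipeline with global-threshold-only segmentation.

## Worked example

`examples/03_correct_artifacts.py` simulates the bilateral-prostheses scan
at 256 px / 360 views and corrects it both ways:

```
method       SSIM ROI A SSIM ROI B
uncorrected      0.4372     0.8818
fp_mar           0.8423     0.9329
proposed         0.9067     0.9356
```

ROI A lies between the two implants, where beam-hardening streaks and the
dark band are worst: the uncorrected image scores 0.44 against the
artifact-free reference. Global-threshold FP-MAR at the same `T = 0.05`
recovers much of it (0.84) but leaves residual streaks from the
unsegmented trace fringe; the adaptive expansion captures that fringe and
lifts ROI A to 0.91. ROI B (a ring around one implant) improves from 0.88
to 0.94. The other examples print the transmission contrast that makes
the thresholds work (`01`), the seed-vs-expanded segmentation quality
(`02`: recall 0.91 → 0.98 at precision 0.91), and the full four-method
table on both phantoms (`04`).

A thin CLI wraps the same library calls:

```sh
dmar simulate --phantom bilateral_prostheses --size 256 --views 360 --out sim/
dmar run --sinogram sim/sinogram.tif --mode proposed --threshold 0.05 --out run/
dmar evaluate --img run/final.tif --ref sim/reference.tif --phantom sim/phantom.tif
```

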
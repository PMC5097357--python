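# Methods

`dmar` implements projection-domain metal artifact reduction (MAR) for
dental/micro CT: the metal trace is segmented on the projection data by
global thresholding followed by adaptive local thresholding, a prior image
is fused from a streak-free and a metal-free reconstruction, and the trace
is replaced by the forward projection of that prior before the final
iterative reconstruction.  The package also carries the simulation study
around the method: polychromatic phantoms, parallel-beam projection and
reconstruction, and ROI-based SSIM evaluation.

## The correction pipeline

Inputs are peak-normalized attenuation sinograms `P(s, θ)` (detector bin ×
view).  The stages, in order:

1. **Global-threshold seed.**  Thresholds are quoted on the normalized
   transmission scale, where the unattenuated ray is 1.0 and the metal
   trace is dark: metal where `exp(-P_unnorm) ≤ T`, equivalently
   `P_unnorm ≥ -ln T` (ties inclusive).  A single number such as `T = 0.05`
   then separates metal from even the densest tissue ray, and lowering `T`
   shrinks the segmented set — the seed deliberately *under*-segments,
   because rays grazing a metal edge carry a vanishing metal chord and
   land on the tissue side of any safe threshold.
2. **Adaptive local-threshold expansion** (`proposed` mode only).  Islands
   are maximal runs of seed pixels along the detector axis of each view.
   Per island, the minimum `B`, maximum `A` and population standard
   deviation `σ` of the normalized attenuation are computed, and pixels
   within the search window `[s₁ - W, s₂ + W]` whose value falls in the
   widened band `[B - aσ, A + aσ]` (ties inclusive) are annexed; the final
   mask is the union of seed and annexed pixels.  The lower band edge is
   what reaches below the seed threshold and recovers the trace fringe
   while staying above the local background; when metal overlaps dense
   anatomy the island statistics shift up with it, lifting the band so the
   region does not grow into tissue.  Defaults `T = 0.05`, `W = 30` (at a
   512-bin detector, scaled proportionally), `a = 2`.
   For (s, t) projection images the same rule runs on 4-connected 2-D
   islands, horizontally and then once vertically with recomputed
   statistics; no fixed-point iteration.
3. **Boundary closure.**  Each metal run is widened by a small margin
   along the detector axis (3 bins per 256, scaling with the detector
   count) before in-painting and replacement.  Rationale: the outermost
   trace pixels clip sub-pixel slivers of metal; their values lie *below*
   any intensity band by construction (the band is anchored at the island
   minimum, and these pixels sit between background and threshold), yet
   they still carry metal corruption of up to several tenths of the
   normalized scale.  Instrumented runs show the shoulder is 1–3 bins wide;
   the margin covers it at the cost of replacing a thin ring of
   near-clean pixels, which in-painting reproduces almost exactly.
4. **Streak-free image `I_sf`.**  The trace is in-painted by per-view
   linear interpolation along the detector axis (runs touching the
   detector edge get a one-sided constant extension) and reconstructed
   with SART.
5. **Metal-free image `I_mf`.**  The uncorrected FBP image with metal
   nullified by an image-domain threshold.  The default threshold is 0.3 of
   the image maximum — low enough to also nullify the bright halo hugging
   the metal: halo pixels left in `I_mf` dominate the difference-image
   normalization below and numb the fusion.
6. **Fusion prior.**  `D = |I_sf - I_mf|` is normalized to
   `D_n = (D - D_min)/(D_max - D_min)` over the whole image (all-constant
   `D` degenerates to `D_n ≡ 0`, i.e. the prior falls back to the
   metal-free image), weighted by `w = 1 / (1 + (D_n/c)^p)` and blended as
   `I_p = w·I_mf + (1 - w)·I_sf`.  Where the two parents agree the
   metal-free image wins (preserving edges); where they disagree — streaks,
   shadows, the nullified metal itself — the streak-free image wins.  The
   magnitude `|D|` matters: with a signed difference, bright streaks (where
   `I_mf > I_sf`) drag `D_min` far negative, the whole-image normalization
   shifts, agreement pixels land far above `c`, and the weight collapses to
   zero everywhere.  Defaults `p = 10`, `c = 0.1` (small metal objects;
   `c ≈ 0.45` suits large ones): larger `p` sharpens the switch, smaller
   `c` biases toward the streak-free image.
7. **Replacement and final reconstruction.**  The prior is forward
   projected (same ray model as the reconstructions, so it is commensurate
   with the normalized data without rescaling), the trace is replaced by
   `P̂ = M·P_orig + (1 - M)·P_prior` (metal = 0 convention; original data
   kept bitwise outside the trace), and `P̂` is reconstructed with SART.
   Metal visibility is restored by filling metal pixels back from the
   uncorrected image, using a *tight* image threshold (0.6 of the image
   maximum) so that only true metal pixels are overwritten and the
   corrected pixels around the implant are kept.

`fp_mar` mode is identical except the trace stops at the seed (no adaptive
expansion); boundary closure applies in both modes, as it compensates the
projector's discretization rather than belonging to either segmentation
strategy.

## Forward model and reconstruction

2-D parallel beam on the inscribed-circle geometry of scikit-image's
interpolating radon transform, one detector bin per image pixel; projection,
FBP and SART therefore share one ray model and
`forward_project(reconstruct(P)) ≈ P` holds to a few percent on smooth
data.  Polychromatic projection computes per-material path lengths `L_m`
(radon of the material indicator scaled by the pixel size) and

    P(s, θ) = -ln Σ_E w(E) · exp(-Σ_m μ_m(E) · L_m(s, θ)),

with the transmitted intensity floored at 1e-12 (photon starvation; the
sinogram records whether the floor fired).  Attenuation tables are built
from published mass-attenuation compilations (elemental titanium and
aluminium, ICRU-44 tissues, hydroxyapatite-dominated dental hard tissues)
sampled at 20–150 keV and interpolated log-log; at every energy
titanium > enamel ≥ bone > dentin > muscle ≈ soft tissue.  The tube
spectrum is Kramers' thin-target bremsstrahlung hardened by an aluminium
filter; the study default is 70 kVp with 4 mm Al (mean energy ≈ 40 keV).
Optional noise stages are off: the study is noiseless and fully
deterministic.

SART: sequential full sweeps (scikit-image `iradon_sart`), relaxation 0.25,
20 iterations, nonnegativity clamp and inscribed-circle support mask after
every sweep, residual-growth guard (abort beyond 10× the initial residual).
FBP: ramp filter (Hann optional), linear detector interpolation.

## The simulation phantoms

Geometry is expressed in fractions of the grid so any size ≥ 64 px yields
the same topology, and the physical pixel pitch scales inversely with the
grid so the phantom is the same object at every resolution.

* **Bilateral prostheses** (0.13 mm/px at 512): a near-circular muscle body
  (half-axes 0.40/0.42 of the grid) with two bone disks (r = 0.065) at
  ±0.15 of center, each holding a titanium disk (r = 0.05).
* **Dental** (0.105 mm/px at 512): a soft-tissue head section, a mandibular
  bone arch (radius 0.27, half-thickness 0.008), ten arch positions with
  eight teeth (dentin disk strictly inside an enamel shell, enamel
  r = 0.024) and two titanium implants (r = 0.044) at the second position
  from each end, which places both implants on one horizontal profile line.

These constants realize the contrast regime the segmentation thresholds
presuppose: every non-metal ray keeps normalized transmission above ~0.08
(bilateral; the dental arch tangents reach ~0.07, teeth being nearly as
opaque as metal is precisely the dental difficulty), while the metal-trace
core falls below 5e-3.  ROI A is a box midway between the implants (the
streak/shadow zone); ROI B is a box ring around the left implant with a
7-px standoff — the SSIM window support — so ring pixels are scored on the
tissue around the metal rather than on the fill-back pixels; neither ROI
contains metal.

## Evaluation

The artifact-free reference is the FBP of the *monochromatic* scan of the
same phantom at the spectrum's tissue-effective energy (the energy whose
muscle attenuation equals the spectrum-weighted mean), on the polychromatic
data's normalization scale.  Monochromatic data are consistent, so this
reference has no beam-hardening artifacts, contains the metal (its value
anchors the SSIM dynamic range) and shares the reconstructions' resolution.

SSIM uses the reference implementation's defaults (Gaussian window
σ = 1.5, K1 = 0.01, K2 = 0.03, no sample-covariance correction); the
dynamic range is the reference's full-image max − min; the local SSIM map
is computed on the ROI's padded bounding box and averaged over exactly the
ROI's member pixels, so ring-shaped ROIs are scored on their own pixels.
Line profiles are sampled with bilinear interpolation; the
overshoot/undershoot comparison excludes the metal and a 5-px (per 256)
partial-volume boundary, where the fill-back seam and the reference's own
edge ringing would otherwise dominate the maximum.

## Study scale and observed behavior

The comparison study (`dmar.study.run_study`, also driven by
`scripts/acceptance.py`) runs both phantoms at 256 × 256 with 360 views and
20 SART iterations — the smoke scale of the full 512/720 protocol, chosen
to keep a complete two-phantom, four-method study within minutes on one
core; all study parameters scale with the grid (window `W`, closure margin,
profile exclusions), so the configuration is the same experiment at reduced
sampling.

At these conditions the bilateral phantom reproduces the expected method
ordering in both ROIs — uncorrected < FP-MAR(T = 0.05, mis-segmented) <
FP-MAR(T = 0.07, well-segmented) ≤ proposed(T = 0.05) — and the proposed
method's profile deviation is about a third of the uncorrected
overshoot/undershoot.  The dental phantom reproduces the ROI-A ordering and
the profile criterion.  Two gaps against the published study are known and
deliberate rather than bugs:

* Absolute SSIM of the corrected images saturates around 0.91–0.97 (ROI A)
  instead of ≈0.99.  The residual is the replaced-trace error itself:
  linear in-painting and the fused prior cannot restore the exact
  polychromatic values the metal displaced, and under this noiseless,
  sharply-discretized forward model those structured residuals remain
  visible to SSIM.
* Dental ROI B: the corrected ring scores below the uncorrected one.  The
  dental implants are shallow enough (tooth spacing bounds their radius)
  that the uncorrected near-field is nearly artifact-free, so replacement
  imperfections around the implant cost more than the artifacts they
  remove.

## Limitations

The generator emulates noiseless 2-D parallel-beam scans of piecewise-
constant phantoms with ideal point sampling: no detector blur, scatter,
noise, cone-beam divergence, or anatomical texture.  Passing tests
demonstrate the algorithm's behavior under exactly these conditions;
performance on real projection data (where edges are blurred over several
bins and islands carry noise) is informed but not established by them.
Automatic selection of the fusion scale `c` by metal size is out of scope
(exposed as configuration); the correction is single-pass.
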
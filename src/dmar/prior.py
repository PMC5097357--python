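"""Prior-image generation: in-painting, streak-free / metal-free images,
and the fusion weighting that blends them.

The prior is the pixelwise blend I_p = w * I_mf + (1 - w) * I_sf, where
I_sf is an iterative reconstruction of the trace-in-painted sinogram, I_mf
the uncorrected reconstruction with metal nullified, and w a sharp sigmoid
of the normalized difference D_n between the two: w = 1 / (1 + (D_n/c)^p).
Where the images agree (D_n small) the metal-free image wins, preserving
edges; where they disagree (streaks, shadows) the streak-free image wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import Sinogram
from .recon import ReconImage, sart
from .segmentation import MetalMask

__all__ = [
    "FusionParams",
    "DifferenceField",
    "inpaint_linear",
    "streak_free_image",
    "metal_free_image",
    "normalize_difference",
    "weight_map",
    "fuse_prior",
    "build_prior",
]


@dataclass(frozen=True)
class FusionParams:
    """Weighting controls: exponent p (sharpness) and scale c (crossover).

    w drops from 1 toward 0 as D_n passes c; w(c) = 0.5 exactly.  p in
    [10, 20] gives a near-binary switch; c ~ 0.1 suits small metal objects,
    c ~ 0.45 large ones.
    """

    p: float = 10.0
    c: float = 0.1

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("exponent p must be positive")
        if not 0.0 < self.c <= 1.0:
            raise ValueError("scale c must lie in (0, 1]")


@dataclass(frozen=True)
class DifferenceField:
    """Difference D = I_sf - I_mf with its normalization to [0, 1]."""

    D: np.ndarray
    D_min: float
    D_max: float
    D_n: np.ndarray


def inpaint_linear(sino: Sinogram, mask: MetalMask) -> Sinogram:
    """Replace each metal run with the linear ramp between its flanking values.

    Interpolation runs along the detector axis within every view.  Runs
    touching a detector edge get a one-sided constant extension.  Non-metal
    pixels are returned bitwise unchanged.
    """
    if mask.values.shape != sino.values.shape:
        raise ValueError("mask must be congruent with the sinogram")
    values = sino.values.copy()
    metal = mask.values == 0
    idx = np.arange(values.shape[0])
    for view in range(values.shape[1]):
        m = metal[:, view]
        if not m.any() or m.all():
            continue  # a fully-metal view has no flanking data to ramp from
        keep = ~m
        values[m, view] = np.interp(idx[m], idx[keep], values[keep, view])
    from dataclasses import replace

    return replace(sino, values=values)


def streak_free_image(
    inpainted: Sinogram, n_iterations: int = 20, relaxation: float = 0.25
) -> ReconImage:
    """I_sf: SART reconstruction of the in-painted sinogram."""
    return sart(inpainted, n_iterations=n_iterations, relaxation=relaxation)


def metal_free_image(uncorrected: ReconImage, image_mask: MetalMask) -> ReconImage:
    """I_mf: the uncorrected reconstruction with metal pixels set to zero."""
    if image_mask.values.shape != uncorrected.values.shape:
        raise ValueError("image mask must be congruent with the image")
    values = uncorrected.values * image_mask.values
    return ReconImage(values=values, algorithm=uncorrected.algorithm + "+metal_free", params=uncorrected.params)


def normalize_difference(I_sf: ReconImage, I_mf: ReconImage, absolute: bool = True) -> DifferenceField:
    """Difference D between I_sf and I_mf normalized to [0, 1] over the image.

    By default D is the magnitude |I_sf - I_mf|: the weighting needs
    "agreement -> D_n near 0 -> w near 1" regardless of the disagreement's
    sign, and signed streak residuals (bright streaks make I_mf exceed
    I_sf) would otherwise shift the whole normalization and defeat the
    blend.  ``absolute=False`` gives the signed difference.

    Degenerate case D_max = D_min: D_n is defined as all zeros (no streak
    signal; the weight is then 1 everywhere and the prior reduces to the
    metal-free image).
    """
    if I_sf.values.shape != I_mf.values.shape:
        raise ValueError("images must be congruent")
    D = I_sf.values - I_mf.values
    if absolute:
        D = np.abs(D)
    d_min, d_max = float(D.min()), float(D.max())
    if d_max > d_min:
        D_n = (D - d_min) / (d_max - d_min)
    else:
        D_n = np.zeros_like(D)
    return DifferenceField(D=D, D_min=d_min, D_max=d_max, D_n=D_n)


def weight_map(D_n: np.ndarray, params: FusionParams) -> np.ndarray:
    """Fusion weight w = 1 / (1 + (D_n / c)^p), elementwise on D_n in [0, 1]."""
    D_n = np.asarray(D_n, dtype=np.float64)
    if D_n.min() < 0 or D_n.max() > 1:
        raise ValueError("D_n must lie in [0, 1]")
    return 1.0 / (1.0 + (D_n / params.c) ** params.p)


def fuse_prior(I_mf: ReconImage, I_sf: ReconImage, w: np.ndarray) -> ReconImage:
    """Prior image I_p = w * I_mf + (1 - w) * I_sf (pixelwise convex blend)."""
    if I_mf.values.shape != I_sf.values.shape or w.shape != I_mf.values.shape:
        raise ValueError("inputs must be congruent")
    values = w * I_mf.values + (1.0 - w) * I_sf.values
    return ReconImage(values=values, algorithm="prior_fusion", params={})


def build_prior(
    I_mf: ReconImage, I_sf: ReconImage, params: FusionParams
) -> tuple[ReconImage, DifferenceField, np.ndarray]:
    """Full fusion chain: difference, weight and blended prior."""
    diff = normalize_difference(I_sf, I_mf)
    w = weight_map(diff.D_n, params)
    return fuse_prior(I_mf, I_sf, w), diff, w
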
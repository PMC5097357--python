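"""Evaluation: ROI-restricted SSIM, line profiles, difference images."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .phantoms import ProfileLine, ROISpec
from .recon import ReconImage

__all__ = ["MetricReport", "ssim_roi", "line_profile", "difference_image"]

# Gaussian SSIM window: sigma 1.5 truncated at 3.5 sigma -> 11x11 support
_SSIM_PAD = 5


@dataclass(frozen=True)
class MetricReport:
    phantom: str
    method: str
    ssim_roi_a: float
    ssim_roi_b: float
    profile: np.ndarray
    diff_l1: float
    diff_linf: float


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, ReconImage) else np.asarray(img)


def ssim_roi(img, ref, roi: ROISpec, data_range: float | None = None) -> float:
    """SSIM between ``img`` and ``ref`` restricted to an ROI.

    The reference-implementation defaults are used (Gaussian window with
    sigma 1.5, K1 = 0.01, K2 = 0.03); the dynamic range defaults to the
    reference image's full-image max - min.  The local SSIM map is computed
    on the ROI's bounding box padded by the window support and averaged over
    the ROI's member pixels, so non-rectangular ROIs (e.g. a box ring around
    an implant) are scored on exactly their own pixels.
    """
    img, ref = _values(img), _values(ref)
    if img.shape != ref.shape:
        raise ValueError("images must be congruent")
    if roi.mask.shape != ref.shape:
        raise ValueError("ROI must be defined on the image grid")
    if data_range is None:
        data_range = float(ref.max() - ref.min())
    r0, r1, c0, c1 = roi.bbox
    if r1 - r0 < 11 or c1 - c0 < 11:
        raise ValueError("ROI smaller than the SSIM window")
    r0, c0 = max(0, r0 - _SSIM_PAD), max(0, c0 - _SSIM_PAD)
    r1, c1 = min(ref.shape[0], r1 + _SSIM_PAD), min(ref.shape[1], c1 + _SSIM_PAD)
    _, ssim_map = structural_similarity(
        ref[r0:r1, c0:c1],
        img[r0:r1, c0:c1],
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        data_range=data_range,
        full=True,
    )
    return float(ssim_map[roi.mask[r0:r1, c0:c1]].mean())


def line_profile(img, line: ProfileLine, n: int | None = None) -> np.ndarray:
    """Pixel values along a line, linearly interpolated at sub-pixel positions."""
    values = _values(img)
    if n is None:
        length = np.hypot(line.end[0] - line.start[0], line.end[1] - line.start[1])
        n = int(np.ceil(length)) + 1
    rows, cols = line.sample_points(n)
    if rows.min() < 0 or cols.min() < 0 or rows.max() > values.shape[0] - 1 or cols.max() > values.shape[1] - 1:
        raise ValueError("profile line leaves the image")
    return ndimage.map_coordinates(values, np.vstack([rows, cols]), order=1, mode="nearest")


def difference_image(img, ref, exclude: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """Signed difference img - ref with L1/Linf summary over included pixels.

    ``exclude`` is an optional boolean mask of pixels (e.g. metal) left out
    of the summary; the returned difference image is always full-frame.
    """
    img, ref = _values(img), _values(ref)
    if img.shape != ref.shape:
        raise ValueError("images must be congruent")
    diff = img - ref
    sel = np.ones_like(diff, dtype=bool) if exclude is None else ~exclude
    picked = diff[sel]
    summary = {
        "l1": float(np.abs(picked).mean()) if picked.size else 0.0,
        "linf": float(np.abs(picked).max()) if picked.size else 0.0,
    }
    return diff, summary
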
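"""Simulation phantoms: material label maps, evaluation ROIs, profile lines.

Two 2-D phantoms mirror the classic metal-artifact test cases: a bilateral
prostheses phantom (muscle body, two bone regions, each holding a titanium
implant) and a dental phantom (soft-tissue head section with a mandibular
bone arch, teeth built as a dentin core inside an enamel shell, and two
titanium implants in the arch).

Geometry is fixed in units of the image size so any grid >= 64 px produces
the same topology.  The physical scale (pixel size) is chosen so that, with
the default tube spectrum, every soft-tissue/bone/tooth ray keeps a
normalized transmission comfortably above the segmentation thresholds while
rays through titanium fall far below them — the contrast regime in which
projection-domain metal thresholding is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .materials import MATERIAL_IDS

__all__ = [
    "PhantomImage",
    "ROISpec",
    "ProfileLine",
    "make_bilateral_prostheses_phantom",
    "make_dental_phantom",
    "replace_metal_with_surrounding",
]


@dataclass(frozen=True)
class PhantomImage:
    """2-D material-label map with physical pixel size."""

    labels: np.ndarray  # integer material ids, square grid
    pixel_size_mm: float
    name: str = "phantom"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.shape[0] != lab.shape[1]:
            raise ValueError("label map must be a square 2-D grid")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "labels", lab)

    @property
    def size(self) -> int:
        return self.labels.shape[0]

    def material_mask(self, name: str) -> np.ndarray:
        return self.labels == MATERIAL_IDS[name]


@dataclass(frozen=True)
class ROISpec:
    """Named evaluation region as a boolean membership mask."""

    name: str
    mask: np.ndarray  # boolean, same grid as the phantom

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.mask)
        return set(zip(rows.tolist(), cols.tolist()))

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open."""
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1


@dataclass(frozen=True)
class ProfileLine:
    """Sampling line through the image, in (row, col) pixel coordinates."""

    start: tuple[float, float]
    end: tuple[float, float]

    def sample_points(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, 1.0, n)
        rows = self.start[0] + t * (self.end[0] - self.start[0])
        cols = self.start[1] + t * (self.end[1] - self.start[1])
        return rows, cols


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse(shape, center, half_axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / half_axes[0]) ** 2 + ((cc - center[1]) / half_axes[1]) ** 2 <= 1.0


def _box_roi(size: int, center: tuple[float, float], half: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    r0 = max(0, int(round(center[0] - half)))
    r1 = min(size, int(round(center[0] + half)) + 1)
    c0 = max(0, int(round(center[1] - half)))
    c1 = min(size, int(round(center[1] + half)) + 1)
    mask[r0:r1, c0:c1] = True
    return mask


#: ROI B stands off the implant edge by the SSIM window support, so the ring
#: scores the tissue zone around the metal rather than the fill-back pixels
ROI_B_STANDOFF_PX = 7


def _ring_roi(size: int, center: tuple[float, float], r_metal: float) -> np.ndarray:
    """Box ring surrounding (but excluding) one metal object."""
    inner = int(round(r_metal)) + ROI_B_STANDOFF_PX
    width = max(4, int(round(10 * size / 512)))
    outer_box = _box_roi(size, center, inner + width)
    inner_box = _box_roi(size, center, inner)
    return outer_box & ~inner_box


#: physical pixel pitch of the reference 512-px grid, mm.  Chosen, together
#: with the geometry fractions below and the default tube spectrum, so that
#: every soft-tissue/bone/tooth ray keeps a normalized transmission above the
#: segmentation thresholds (0.05-0.07) while rays through titanium fall far
#: below them -- the contrast regime in which projection-domain metal
#: thresholding separates metal from anatomy.
BASE_PIXEL_MM_512 = {"bilateral_prostheses": 0.13, "dental": 0.105}

#: geometry constants, as fractions of the grid size
BILATERAL_GEOM = {
    "body_half_axes": (0.40, 0.42),  # (row, col) half-axes of the muscle body
    "implant_dx": 0.15,  # implant offset from center along the columns
    "r_bone": 0.065,
    "r_ti": 0.05,
}
DENTAL_GEOM = {
    "head_half_axes": (0.42, 0.40),
    "arch_radius": 0.27,
    "arch_band": 0.008,  # half-thickness of the bone arch
    "r_enamel": 0.024,
    "r_ti": 0.044,
}


def make_bilateral_prostheses_phantom(
    size: int = 512, pixel_size_mm: float | None = None
) -> tuple[PhantomImage, tuple[ROISpec, ROISpec], ProfileLine]:
    """Bilateral prostheses phantom: muscle ellipse, two bones, two Ti implants.

    Returns the phantom, (ROI A, ROI B) and the horizontal profile line
    through both implant centers.  ROI A sits midway between the implants;
    ROI B is a box ring surrounding (but excluding) the left implant.
    """
    if size < 64:
        raise ValueError("phantom grid must be at least 64 px")
    if pixel_size_mm is None:
        # keep the physical phantom invariant under grid-size changes
        pixel_size_mm = BASE_PIXEL_MM_512["bilateral_prostheses"] * 512.0 / size
    ids = MATERIAL_IDS
    g = BILATERAL_GEOM
    lab = np.zeros((size, size), dtype=np.uint8)
    c = (size - 1) / 2.0
    body = _ellipse((size, size), (c, c), (g["body_half_axes"][0] * size, g["body_half_axes"][1] * size))
    lab[body] = ids["muscle"]
    implant_dx = g["implant_dx"] * size
    r_bone = g["r_bone"] * size
    r_ti = g["r_ti"] * size
    for sgn in (-1.0, 1.0):
        center = (c, c + sgn * implant_dx)
        lab[_disk((size, size), center, r_bone)] = ids["bone"]
        lab[_disk((size, size), center, r_ti)] = ids["titanium"]
    phantom = PhantomImage(labels=lab, pixel_size_mm=pixel_size_mm, name="bilateral_prostheses")

    roi_a = ROISpec("A", _box_roi(size, (c, c), max(4, int(round(0.05 * size)))))
    roi_b = ROISpec("B", _ring_roi(size, (c, c - implant_dx), r_ti))
    profile = ProfileLine(start=(c, 0.0), end=(c, float(size - 1)))
    return phantom, (roi_a, roi_b), profile


def make_dental_phantom(
    size: int = 512, pixel_size_mm: float | None = None, n_teeth: int = 10
) -> tuple[PhantomImage, tuple[ROISpec, ROISpec], ProfileLine]:
    """Dental phantom: head section, bone arch, teeth, two Ti implants.

    Teeth are a dentin disk strictly inside an enamel disk, so every dentin
    component is ringed by enamel.  Implants replace the second tooth from
    each end of the arch and therefore share a horizontal profile line.
    """
    if size < 64:
        raise ValueError("phantom grid must be at least 64 px")
    if n_teeth < 4:
        raise ValueError("need at least 4 arch positions")
    if pixel_size_mm is None:
        pixel_size_mm = BASE_PIXEL_MM_512["dental"] * 512.0 / size
    ids = MATERIAL_IDS
    g = DENTAL_GEOM
    lab = np.zeros((size, size), dtype=np.uint8)
    c = (size - 1) / 2.0
    lab[_ellipse((size, size), (c, c), (g["head_half_axes"][0] * size, g["head_half_axes"][1] * size))] = ids["soft_tissue"]

    arch_center = (c - 0.06 * size, c)  # (row, col); arch opens upward
    arch_r = g["arch_radius"] * size
    band = g["arch_band"] * size
    rr, cc = np.ogrid[:size, :size]
    rad = np.sqrt((rr - arch_center[0]) ** 2 + (cc - arch_center[1]) ** 2)
    below = rr >= arch_center[0]  # lower half-plane: the mandibular arch
    lab[(rad >= arch_r - band) & (rad <= arch_r + band) & below] = ids["bone"]

    r_enamel = g["r_enamel"] * size
    r_dentin = r_enamel - max(1.5, 0.009 * size)
    r_ti = g["r_ti"] * size
    phis = np.deg2rad(np.linspace(20.0, 160.0, n_teeth))
    implant_slots = {1, n_teeth - 2}
    implant_centers = []
    for k, phi in enumerate(phis):
        center = (arch_center[0] + arch_r * np.sin(phi), arch_center[1] + arch_r * np.cos(phi))
        if k in implant_slots:
            lab[_disk((size, size), center, r_ti)] = ids["titanium"]
            implant_centers.append(center)
        else:
            lab[_disk((size, size), center, r_enamel)] = ids["enamel"]
            lab[_disk((size, size), center, r_dentin)] = ids["dentin"]
    phantom = PhantomImage(labels=lab, pixel_size_mm=pixel_size_mm, name="dental")

    (r_left, c_left), (r_right, c_right) = sorted(implant_centers, key=lambda p: p[1])
    mid = ((r_left + r_right) / 2.0, (c_left + c_right) / 2.0)
    roi_a = ROISpec("A", _box_roi(size, mid, max(4, int(round(0.05 * size)))))
    roi_b = ROISpec("B", _ring_roi(size, (r_left, c_left), r_ti))
    profile = ProfileLine(start=(r_left, 0.0), end=(r_right, float(size - 1)))
    return phantom, (roi_a, roi_b), profile


def replace_metal_with_surrounding(phantom: PhantomImage) -> PhantomImage:
    """Ground-truth companion: metal components relabeled as their surroundings.

    Each connected metal component is replaced by the most common non-metal
    label in a thin ring just outside it, yielding the ideal artifact-free
    phantom used as the reference for evaluation.
    """
    lab = phantom.labels.copy()
    metal = lab == MATERIAL_IDS["titanium"]
    if not metal.any():
        return phantom
    comp, n = ndimage.label(metal)
    for i in range(1, n + 1):
        m = comp == i
        ring = ndimage.binary_dilation(m, iterations=3) & ~metal
        vals = lab[ring]
        vals = vals[vals != MATERIAL_IDS["air"]]
        fill = np.bincount(vals).argmax() if vals.size else MATERIAL_IDS["air"]
        lab[m] = fill
    return PhantomImage(labels=lab, pixel_size_mm=phantom.pixel_size_mm, name=phantom.name + "_metal_replaced")
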
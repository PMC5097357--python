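"""Forward models: per-material path lengths, polychromatic projection,
pixel-image line integrals, peak normalization.

The projector is 2-D parallel-beam on the inscribed-circle geometry of
scikit-image's interpolating radon transform, so simulate -> reconstruct ->
reproject is self-consistent by construction: ``forward_project_image`` and
the reconstruction module share one ray model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import radon

from .materials import EnergySpectrum, MaterialTable, single_bin_spectrum
from .phantoms import PhantomImage

__all__ = [
    "Geometry",
    "Sinogram",
    "path_lengths",
    "polychromatic_project",
    "monochromatic_project",
    "forward_project_image",
    "peak_normalize",
    "denormalize",
]

#: transmitted-intensity floor modeling photon starvation
INTENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class Geometry:
    """2-D parallel-beam scan geometry.

    Detectors span the image's inscribed circle (one detector bin per image
    pixel); ``n_views`` angles cover ``angular_range`` degrees end-exclusive.
    """

    n_detectors: int
    n_views: int
    angular_range: float = 360.0
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_detectors < 1:
            raise ValueError("geometry needs at least one view and one detector")

    @property
    def thetas(self) -> np.ndarray:
        return np.linspace(0.0, self.angular_range, self.n_views, endpoint=False)

    @classmethod
    def for_image(cls, size: int, n_views: int = 720, angular_range: float = 360.0,
                  pixel_size_mm: float = 1.0) -> "Geometry":
        return cls(n_detectors=size, n_views=n_views, angular_range=angular_range,
                   pixel_size_mm=pixel_size_mm)


@dataclass(frozen=True)
class Sinogram:
    """Projection data P(s, theta): detector bins along rows, views along columns.

    ``peak_norm`` is the divisor applied by :func:`peak_normalize` (None while
    unnormalized); ``saturated`` flags rays that hit the photon-starvation
    intensity floor during simulation.
    """

    values: np.ndarray
    geometry: Geometry
    peak_norm: float | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("sinogram values must be 2-D (detector x view)")
        if v.shape != (self.geometry.n_detectors, self.geometry.n_views):
            raise ValueError(
                f"sinogram shape {v.shape} does not match geometry "
                f"({self.geometry.n_detectors}, {self.geometry.n_views})"
            )
        object.__setattr__(self, "values", v)

    @property
    def is_normalized(self) -> bool:
        return self.peak_norm is not None

    def unnormalized_values(self) -> np.ndarray:
        """Attenuation line integrals on the original (pre-normalization) scale."""
        if self.peak_norm is None:
            return self.values
        return self.values * self.peak_norm


def _check_geometry(image_size: int, geometry: Geometry) -> None:
    if geometry.n_detectors != image_size:
        raise ValueError(
            f"geometry has {geometry.n_detectors} detectors but the image is "
            f"{image_size} px; this projector uses one detector bin per pixel"
        )


def path_lengths(phantom: PhantomImage, geometry: Geometry) -> dict[str, np.ndarray]:
    """Per-material intersection lengths (cm) for every ray of the scan.

    Returns a sinogram-shaped array per material present in the label map.
    Lengths are the interpolating line integrals of the material's indicator
    image scaled by the pixel size, so they sum (over materials) to the ray's
    chord length through the image support.
    """
    _check_geometry(phantom.size, geometry)
    from .materials import MATERIAL_IDS

    theta = geometry.thetas
    px_cm = phantom.pixel_size_mm / 10.0
    out: dict[str, np.ndarray] = {}
    for name, mid in MATERIAL_IDS.items():
        if name == "air":
            continue
        mask = (phantom.labels == mid).astype(np.float64)
        if not mask.any():
            continue
        out[name] = radon(mask, theta=theta, circle=True) * px_cm
    return out


def polychromatic_project(
    phantom: PhantomImage,
    table: MaterialTable,
    spectrum: EnergySpectrum,
    geometry: Geometry,
    intensity_floor: float = INTENSITY_FLOOR,
) -> Sinogram:
    """Energy-weighted attenuation line integrals of a material phantom.

    P(s, theta) = -ln( sum_E w(E) exp(-sum_m mu_m(E) L_m(s, theta)) ).
    Transmitted intensity is clamped at ``intensity_floor`` (photon
    starvation); the returned sinogram records whether the clamp fired.
    No normalization is applied.
    """
    lengths = path_lengths(phantom, geometry)
    unknown = [n for n in lengths if n not in table.mu]
    if unknown:
        raise KeyError(f"phantom materials missing from table: {unknown}")
    shape = (geometry.n_detectors, geometry.n_views)
    transmitted = np.zeros(shape, dtype=np.float64)
    for energy, weight in zip(spectrum.energies, spectrum.weights):
        if weight == 0.0:
            continue
        line_integral = np.zeros(shape, dtype=np.float64)
        for name, length in lengths.items():
            line_integral += table.mu_at(name, energy) * length
        transmitted += weight * np.exp(-line_integral)
    saturated = bool(np.any(transmitted < intensity_floor))
    values = -np.log(np.maximum(transmitted, intensity_floor))
    # interpolation can leave tiny negative integrals on air rays
    np.clip(values, 0.0, None, out=values)
    return Sinogram(values=values, geometry=geometry, saturated=saturated)


def monochromatic_project(
    phantom: PhantomImage, table: MaterialTable, energy: float, geometry: Geometry
) -> Sinogram:
    """Single-energy line integrals (one-bin spectrum)."""
    return polychromatic_project(phantom, table, single_bin_spectrum(energy), geometry)


def forward_project_image(image: np.ndarray, geometry: Geometry) -> Sinogram:
    """Line integrals of a pixel attenuation map (unit detector spacing).

    Linear in the image and sharing the reconstruction module's ray model,
    so forward-projecting a reconstruction approximately reproduces the
    sinogram it came from.
    """
    image = np.asarray(image, dtype=np.float64)
    _check_geometry(image.shape[0], geometry)
    values = radon(image, theta=geometry.thetas, circle=True)
    return Sinogram(values=values, geometry=geometry)


def peak_normalize(sino: Sinogram) -> Sinogram:
    """Divide by the global maximum over all views so max(P) = 1."""
    peak = float(sino.values.max())
    if peak <= 0:
        raise ValueError("cannot peak-normalize an all-zero sinogram")
    prior_peak = sino.peak_norm if sino.peak_norm is not None else 1.0
    return replace(sino, values=sino.values / peak, peak_norm=prior_peak * peak)


def denormalize(sino: Sinogram) -> Sinogram:
    """Undo peak normalization (round-trip inverse of :func:`peak_normalize`)."""
    if sino.peak_norm is None:
        return sino
    return replace(sino, values=sino.values * sino.peak_norm, peak_norm=None)
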
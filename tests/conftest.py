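"""Shared fixtures: small simulated scans and analytic disk phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from dmar.materials import build_material_table, single_bin_spectrum
from dmar.phantoms import PhantomImage
from dmar.projector import Geometry, Sinogram, peak_normalize, polychromatic_project
from dmar.study import simulate_case


def disk_phantom(size: int, radius_frac: float = 0.3, material: str = "muscle",
                 pixel_size_mm: float = 1.0) -> PhantomImage:
    """Centered single-material disk in air."""
    from dmar.materials import MATERIAL_IDS

    lab = np.zeros((size, size), dtype=np.uint8)
    rr, cc = np.ogrid[:size, :size]
    c = size // 2
    lab[(rr - c) ** 2 + (cc - c) ** 2 <= (radius_frac * size) ** 2] = MATERIAL_IDS[material]
    return PhantomImage(labels=lab, pixel_size_mm=pixel_size_mm, name="disk")


@pytest.fixture(scope="session")
def disk_case():
    """Monochromatic scan of a muscle disk: the analytic reconstruction oracle."""
    size = 128
    phantom = disk_phantom(size, radius_frac=0.3, pixel_size_mm=0.5)
    geometry = Geometry.for_image(size, n_views=180, pixel_size_mm=0.5)
    table = build_material_table(np.linspace(20.0, 70.0, 11))
    energy = 50.0
    sino = polychromatic_project(phantom, table, single_bin_spectrum(energy), geometry)
    return {
        "phantom": phantom,
        "geometry": geometry,
        "table": table,
        "energy": energy,
        "mu": table.mu_at("muscle", energy),
        "radius_px": 0.3 * size,
        "sinogram": sino,
    }


@pytest.fixture(scope="session")
def bilateral_small():
    """Bilateral prostheses scan at smoke scale (128 px, 180 views)."""
    return simulate_case("bilateral_prostheses", size=128, n_views=180, sart_iterations=8)


@pytest.fixture(scope="session")
def dental_small():
    return simulate_case("dental", size=128, n_views=180, sart_iterations=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_sinogram(rng):
    """Peak-normalized random sinogram for elementwise oracles."""
    geometry = Geometry.for_image(32, n_views=12)
    values = rng.uniform(0.0, 1.0, size=(32, 12))
    values[3, 7] = 1.0  # pin the peak
    return peak_normalize(Sinogram(values=values, geometry=geometry))
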
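import numpy as np
import pytest

from dmar.materials import EnergySpectrum, build_material_table, single_bin_spectrum
from dmar.projector import (
    Geometry,
    Sinogram,
    denormalize,
    forward_project_image,
    monochromatic_project,
    path_lengths,
    peak_normalize,
    polychromatic_project,
)
from dmar.recon import fbp

from conftest import disk_phantom


def test_disk_chord_lengths(disk_case):
    """Central ray's intersection with a centered disk equals its diameter."""
    lengths = path_lengths(disk_case["phantom"], disk_case["geometry"])["muscle"]
    px_cm = disk_case["phantom"].pixel_size_mm / 10.0
    expected = 2 * disk_case["radius_px"] * px_cm
    center_bin = disk_case["geometry"].n_detectors // 2
    assert np.allclose(lengths[center_bin, :], expected, atol=1.5 * px_cm)
    # rays missing the phantom see nothing
    assert np.allclose(lengths[0, :], 0.0)
    assert np.allclose(lengths[-1, :], 0.0)


def test_path_lengths_partition_support():
    """Per-material lengths sum to the chord length through the support."""
    from dmar.materials import MATERIAL_IDS

    size = 96
    lab = np.zeros((size, size), dtype=np.uint8)
    rr, cc = np.ogrid[:size, :size]
    c = size // 2
    outer = (rr - c) ** 2 + (cc - c) ** 2 <= (0.3 * size) ** 2
    inner = (rr - c) ** 2 + (cc - c) ** 2 <= (0.15 * size) ** 2
    lab[outer] = MATERIAL_IDS["muscle"]
    lab[inner] = MATERIAL_IDS["bone"]
    from dmar.phantoms import PhantomImage

    ph = PhantomImage(labels=lab, pixel_size_mm=1.0, name="nested")
    geometry = Geometry.for_image(size, n_views=24, pixel_size_mm=1.0)
    lengths = path_lengths(ph, geometry)
    total = lengths["muscle"] + lengths["bone"]
    support = path_lengths(
        PhantomImage(labels=(outer * MATERIAL_IDS["muscle"]).astype(np.uint8),
                     pixel_size_mm=1.0, name="support"),
        geometry,
    )["muscle"]
    assert np.allclose(total, support, atol=1e-9)


def test_single_bin_equals_monochromatic(disk_case):
    """A one-bin spectrum reduces the polychromatic sum to mu * L exactly."""
    poly = polychromatic_project(
        disk_case["phantom"], disk_case["table"],
        single_bin_spectrum(disk_case["energy"]), disk_case["geometry"],
    )
    lengths = path_lengths(disk_case["phantom"], disk_case["geometry"])["muscle"]
    assert np.allclose(poly.values, disk_case["mu"] * lengths, atol=1e-9)


def test_air_only_rays_zero(disk_case):
    sino = disk_case["sinogram"]
    assert sino.values[0, :].max() == pytest.approx(0.0, abs=1e-9)


def test_beam_hardening_monotonicity():
    """P(t)/t strictly decreases with thickness for a two-bin spectrum."""
    table = build_material_table(np.linspace(20.0, 70.0, 11))
    spectrum = EnergySpectrum(energies=np.array([30.0, 60.0]), weights=np.array([0.5, 0.5]))
    geometry = None
    ratios = []
    for frac in (0.1, 0.2, 0.3, 0.4):
        ph = disk_phantom(96, radius_frac=frac, material="bone", pixel_size_mm=1.0)
        geometry = Geometry.for_image(96, n_views=4, pixel_size_mm=1.0)
        sino = polychromatic_project(ph, table, spectrum, geometry)
        t = 2 * frac * 96 * 0.1  # cm
        ratios.append(sino.values[96 // 2, 0] / t)
    assert np.all(np.diff(ratios) < 0)


def test_effective_mu_within_spectral_bounds():
    """mu_eff inferred from a polychromatic ray lies between the spectral extremes."""
    table = build_material_table(np.linspace(20.0, 70.0, 11))
    spectrum = EnergySpectrum(energies=np.array([30.0, 60.0]), weights=np.array([0.5, 0.5]))
    ph = disk_phantom(96, radius_frac=0.3, material="bone", pixel_size_mm=1.0)
    geometry = Geometry.for_image(96, n_views=4, pixel_size_mm=1.0)
    sino = polychromatic_project(ph, table, spectrum, geometry)
    L = path_lengths(ph, geometry)["bone"][96 // 2, 0]
    mu_eff = sino.values[96 // 2, 0] / L
    assert table.mu_at("bone", 60.0) < mu_eff < table.mu_at("bone", 30.0)


def test_peak_normalize_and_round_trip(random_sinogram):
    assert random_sinogram.values.max() == pytest.approx(1.0, abs=1e-9)
    back = denormalize(random_sinogram)
    again = peak_normalize(back)
    assert np.allclose(again.values, random_sinogram.values, atol=1e-12)
    assert again.peak_norm == pytest.approx(random_sinogram.peak_norm)
    with pytest.raises(ValueError):
        peak_normalize(Sinogram(values=np.zeros((8, 4)),
                                geometry=Geometry.for_image(8, n_views=4)))


def test_forward_project_linearity():
    geometry = Geometry.for_image(64, n_views=30)
    rng = np.random.default_rng(7)
    img = rng.uniform(size=(64, 64))
    rr, cc = np.ogrid[:64, :64]
    img[(rr - 32) ** 2 + (cc - 32) ** 2 > 30**2] = 0.0
    zero = forward_project_image(np.zeros((64, 64)), geometry)
    assert np.allclose(zero.values, 0.0)
    one = forward_project_image(img, geometry)
    three = forward_project_image(3.0 * img, geometry)
    assert np.allclose(three.values, 3.0 * one.values, atol=1e-9)


def test_single_pixel_traces_sinusoid():
    """A point source traces s(theta) = c + dx cos(theta) - dy sin(theta)."""
    size = 64
    img = np.zeros((size, size))
    r0, c0 = 20, 44
    img[r0, c0] = 1.0
    geometry = Geometry.for_image(size, n_views=90)
    sino = forward_project_image(img, geometry)
    am = sino.values.argmax(axis=0)
    c = size // 2
    t = np.deg2rad(geometry.thetas)
    predicted = c + (c0 - c) * np.cos(t) - (r0 - c) * np.sin(t)
    assert np.abs(am - predicted).max() < 1.5


def test_project_reconstruct_reproject_consistency(disk_case):
    """forward_project(FBP(sino)) stays within 5% relative L2 of sino."""
    sino = disk_case["sinogram"]
    recon = fbp(sino)
    re = forward_project_image(recon.values, disk_case["geometry"])
    rel = np.linalg.norm(re.values - sino.values) / np.linalg.norm(sino.values)
    assert rel < 0.05


def test_titanium_attains_sinogram_peak(bilateral_small):
    """The global maximum of the sinogram lies on the metal trace."""
    sino = bilateral_small.sinogram
    peak = np.unravel_index(np.argmax(sino.values), sino.values.shape)
    assert bilateral_small.metal_trace[peak]


def test_geometry_mismatch_rejected(disk_case):
    with pytest.raises(ValueError):
        forward_project_image(np.zeros((32, 32)), disk_case["geometry"])
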
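"""Material attenuation tables and x-ray spectra for the simulation phantoms.

Linear attenuation coefficients are built from published mass attenuation
compilations (NIST XCOM-style tables for elemental titanium and aluminium,
ICRU-44 tissue compositions, and hydroxyapatite-dominated dental hard
tissues) sampled on a coarse diagnostic-energy grid and interpolated
log-log onto the requested grid.  Values are in 1/cm on a keV grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MATERIAL_IDS",
    "MaterialTable",
    "EnergySpectrum",
    "build_material_table",
    "default_spectrum",
    "single_bin_spectrum",
]

#: canonical integer label for each material in a phantom label map
MATERIAL_IDS = {
    "air": 0,
    "muscle": 1,
    "soft_tissue": 2,
    "bone": 3,
    "dentin": 4,
    "enamel": 5,
    "titanium": 6,
}

METALS = frozenset({"titanium"})

# base grid (keV) for the tabulated mass attenuation coefficients
_BASE_E = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0])

# mass attenuation mu/rho in cm^2/g at _BASE_E, and density in g/cm^3
_MU_RHO = {
    "muscle": [0.8205, 0.3783, 0.2685, 0.2262, 0.2048, 0.1823, 0.1693, 0.1492],
    "soft_tissue": [0.8222, 0.3756, 0.2683, 0.2264, 0.2048, 0.1823, 0.1693, 0.1492],
    "bone": [4.001, 1.331, 0.6655, 0.4242, 0.3148, 0.2229, 0.1855, 0.1480],
    "dentin": [2.757, 0.935, 0.477, 0.308, 0.2336, 0.1659, 0.1402, 0.1145],
    "enamel": [4.935, 1.591, 0.781, 0.4859, 0.3516, 0.2400, 0.1944, 0.1504],
    "titanium": [15.85, 4.972, 2.214, 1.213, 0.7661, 0.4052, 0.2721, 0.1649],
    # aluminium is not a phantom material; it models tube filtration
    "aluminium": [3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378],
}

_DENSITY = {
    "muscle": 1.05,
    "soft_tissue": 1.06,
    "bone": 1.92,
    "dentin": 2.14,
    "enamel": 2.96,
    "titanium": 4.506,
    "aluminium": 2.699,
}


def _interp_mu(name: str, energies: np.ndarray) -> np.ndarray:
    """Linear attenuation (1/cm) of ``name`` at ``energies`` (keV), log-log."""
    if name not in _MU_RHO:
        raise KeyError(f"unknown material {name!r}")
    mu = np.asarray(_MU_RHO[name]) * _DENSITY[name]
    loge = np.log(np.asarray(energies, dtype=float))
    # log-log interpolation with linear extrapolation at the grid ends
    logmu = np.interp(loge, np.log(_BASE_E), np.log(mu))
    lo = loge < np.log(_BASE_E[0])
    if np.any(lo):  # extrapolate 10-20 keV from the first two points
        slope = (np.log(mu[1]) - np.log(mu[0])) / (np.log(_BASE_E[1]) - np.log(_BASE_E[0]))
        logmu[lo] = np.log(mu[0]) + slope * (loge[lo] - np.log(_BASE_E[0]))
    return np.exp(logmu)


@dataclass(frozen=True)
class MaterialTable:
    """Per-material linear attenuation coefficients on a shared energy grid."""

    energies: np.ndarray  # keV, strictly increasing
    mu: dict[str, np.ndarray]  # material name -> mu(E) in 1/cm

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or len(e) < 1 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be 1-D and strictly increasing")
        object.__setattr__(self, "energies", e)

    @property
    def names(self) -> list[str]:
        return list(self.mu)

    def material_id(self, name: str) -> int:
        return MATERIAL_IDS[name]

    def is_metal(self, name: str) -> bool:
        return name in METALS

    def mu_at(self, name: str, energy: float) -> float:
        """Attenuation of ``name`` at a single energy, interpolated on the grid."""
        if name not in self.mu:
            raise KeyError(f"material {name!r} not in table")
        return float(np.interp(energy, self.energies, self.mu[name]))

    def mu_by_id(self) -> dict[int, np.ndarray]:
        return {MATERIAL_IDS[n]: m for n, m in self.mu.items()}


def build_material_table(energy_grid) -> MaterialTable:
    """Tabulate mu(E) for all phantom materials on ``energy_grid`` (keV).

    The grid must lie within 10-150 keV.  Air is carried with mu = 0: at
    diagnostic energies its attenuation is ~4 orders of magnitude below soft
    tissue and irrelevant at phantom scale.
    """
    e = np.atleast_1d(np.asarray(energy_grid, dtype=float))
    if e.min() < 10.0 or e.max() > 150.0:
        raise ValueError("energy grid must lie within 10-150 keV")
    mu = {"air": np.zeros_like(e)}
    for name in ("muscle", "soft_tissue", "bone", "dentin", "enamel", "titanium"):
        mu[name] = _interp_mu(name, e)
    return MaterialTable(energies=e, mu=mu)


@dataclass(frozen=True)
class EnergySpectrum:
    """Discrete x-ray spectrum: keV bin centers with normalized weights."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.shape != w.shape or e.ndim != 1:
            raise ValueError("energies and weights must be congruent 1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        s = w.sum()
        if s <= 0:
            raise ValueError("spectrum has zero total weight")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / s)

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))


def default_spectrum(kvp: float, filtration_mm_al: float = 2.5) -> EnergySpectrum:
    """Filtered-bremsstrahlung tube spectrum at ``kvp`` tube voltage.

    Kramers' thin-target emission, N(E) proportional to (kvp - E)/E, hardened
    by an aluminium filter of the given thickness.  This is a deliberately
    simple parametric model: it reproduces the qualitative shape (low-energy
    cutoff from filtration, zero emission at the tube voltage) that drives
    beam hardening, without characteristic lines.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError("tube voltage must be within 40-150 kVp")
    n_bins = max(9, int(round((kvp - 20.0) / 5.0)) + 1)
    e = np.linspace(20.0, kvp, n_bins)
    w = (kvp - e) / e
    mu_al = _interp_mu("aluminium", e)
    w = w * np.exp(-mu_al * (filtration_mm_al / 10.0))
    # the top bin has zero Kramers weight; keep the grid strictly increasing
    return EnergySpectrum(energies=e, weights=w)


def single_bin_spectrum(energy: float) -> EnergySpectrum:
    """Degenerate monochromatic spectrum (one bin, unit weight)."""
    return EnergySpectrum(energies=np.array([float(energy)]), weights=np.array([1.0]))
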
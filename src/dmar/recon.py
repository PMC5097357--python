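"""Tomographic reconstruction: filtered backprojection and SART.

Thin, deterministic wrappers over scikit-image's ``iradon`` and
``iradon_sart`` with the package's conventions: sequential view order, a
nonnegativity clamp after every SART sweep, and a divergence guard on the
data residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon, iradon_sart, radon

from .projector import Geometry, Sinogram

__all__ = ["ReconImage", "fbp", "sart"]


@dataclass(frozen=True)
class ReconImage:
    """2-D reconstructed attenuation map with its provenance."""

    values: np.ndarray
    algorithm: str
    params: dict

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("reconstruction must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("reconstruction contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return self.values.shape[0]


def _circle_mask(n: int) -> np.ndarray:
    """Inscribed reconstruction circle of an n x n grid."""
    rr, cc = np.ogrid[:n, :n]
    center = n // 2
    return (rr - center) ** 2 + (cc - center) ** 2 <= (n // 2) ** 2


def _check(sino: Sinogram, geometry: Geometry | None) -> Geometry:
    geometry = geometry or sino.geometry
    if (geometry.n_detectors, geometry.n_views) != sino.values.shape:
        raise ValueError("sinogram does not match the requested geometry")
    return geometry


def fbp(sino: Sinogram, geometry: Geometry | None = None, filter_name: str = "ramp") -> ReconImage:
    """Filtered backprojection with a ramp (default) or windowed-ramp filter."""
    geometry = _check(sino, geometry)
    if filter_name not in ("ramp", "hann"):
        raise ValueError("filter must be 'ramp' or 'hann'")
    img = iradon(
        sino.values,
        theta=geometry.thetas,
        circle=True,
        filter_name=filter_name,
        output_size=geometry.n_detectors,
    )
    img *= _circle_mask(img.shape[0])
    return ReconImage(values=img, algorithm="fbp", params={"filter": filter_name})


def sart(
    sino: Sinogram,
    geometry: Geometry | None = None,
    n_iterations: int = 20,
    relaxation: float = 0.25,
    init: np.ndarray | None = None,
    nonnegative: bool = True,
    divergence_factor: float = 10.0,
    divergence_check_every: int = 5,
) -> ReconImage:
    """Simultaneous algebraic reconstruction technique.

    Each iteration is one full sequential sweep over the views with
    ray-normalized residual updates, followed by a nonnegativity clamp.
    Deterministic for fixed inputs.  If the data residual ||Ax - p|| grows
    beyond ``divergence_factor`` times the initial residual the run aborts.
    """
    geometry = _check(sino, geometry)
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    if not 0.0 < relaxation <= 1.0:
        raise ValueError("relaxation must lie in (0, 1]")
    theta = geometry.thetas
    p = np.ascontiguousarray(sino.values, dtype=np.float64)
    x = None if init is None else np.asarray(init, dtype=np.float64).copy()
    residual0 = float(np.linalg.norm(p))
    circle = _circle_mask(geometry.n_detectors)
    for it in range(n_iterations):
        x = iradon_sart(p, theta=theta, image=x, relaxation=relaxation)
        if nonnegative:
            np.clip(x, 0.0, None, out=x)
        x *= circle  # the parallel-beam data determine only the inscribed circle
        check_now = divergence_check_every and ((it + 1) % divergence_check_every == 0)
        if check_now and residual0 > 0:
            residual = float(np.linalg.norm(radon(x, theta=theta, circle=True) - p))
            if residual > divergence_factor * residual0:
                raise RuntimeError(
                    f"SART diverged at iteration {it + 1}: residual {residual:.3g} "
                    f"vs initial {residual0:.3g}"
                )
    return ReconImage(
        values=x,
        algorithm="sart",
        params={
            "n_iterations": n_iterations,
            "relaxation": relaxation,
            "nonnegative": nonnegative,
        },
    )
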
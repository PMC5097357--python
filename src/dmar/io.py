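"""TIFF + structured-text sidecar I/O for phantoms, sinograms, images, masks.

Arrays go to 32-bit float (or 8/16-bit integer) TIFF; everything that is not
the pixel grid — geometry, normalization constants, pixel size, ROI boxes —
goes to a YAML sidecar next to the TIFF (same stem, ``.yml``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .phantoms import PhantomImage
from .projector import Geometry, Sinogram
from .recon import ReconImage
from .segmentation import MetalMask

__all__ = [
    "save_sinogram",
    "load_sinogram",
    "save_image",
    "load_image",
    "save_phantom",
    "load_phantom",
    "save_mask",
    "load_mask",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yml")


def _write_sidecar(path: Path, meta: dict) -> None:
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def _read_sidecar(path: Path) -> dict:
    return yaml.safe_load(_sidecar(path).read_text())


def save_sinogram(path, sino: Sinogram) -> None:
    path = Path(path)
    tifffile.imwrite(path, sino.values.astype(np.float32))
    g = sino.geometry
    _write_sidecar(path, {
        "kind": "sinogram",
        "geometry": {
            "n_detectors": g.n_detectors,
            "n_views": g.n_views,
            "angular_range": g.angular_range,
            "pixel_size_mm": g.pixel_size_mm,
        },
        "peak_norm": None if sino.peak_norm is None else float(sino.peak_norm),
        "saturated": bool(sino.saturated),
    })


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    meta = _read_sidecar(path)
    g = meta["geometry"]
    geometry = Geometry(n_detectors=g["n_detectors"], n_views=g["n_views"],
                        angular_range=g["angular_range"], pixel_size_mm=g["pixel_size_mm"])
    return Sinogram(values=values, geometry=geometry,
                    peak_norm=meta.get("peak_norm"), saturated=meta.get("saturated", False))


def save_image(path, image: ReconImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float32))
    _write_sidecar(path, {"kind": "image", "algorithm": image.algorithm,
                          "params": _plain(image.params)})


def load_image(path) -> ReconImage:
    path = Path(path)
    meta = _read_sidecar(path)
    return ReconImage(values=tifffile.imread(path).astype(np.float64),
                      algorithm=meta.get("algorithm", "unknown"), params=meta.get("params", {}))


def save_phantom(path, phantom: PhantomImage, rois=None) -> None:
    path = Path(path)
    tifffile.imwrite(path, phantom.labels.astype(np.uint16))
    meta = {"kind": "phantom", "name": phantom.name, "pixel_size_mm": phantom.pixel_size_mm}
    if rois:
        meta["rois"] = {r.name: [int(v) for v in r.bbox] for r in rois}
    _write_sidecar(path, meta)


def load_phantom(path) -> PhantomImage:
    path = Path(path)
    meta = _read_sidecar(path)
    return PhantomImage(labels=tifffile.imread(path).astype(np.uint8),
                        pixel_size_mm=meta["pixel_size_mm"], name=meta.get("name", "phantom"))


def save_mask(path, mask: MetalMask) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.values.astype(np.uint8))
    _write_sidecar(path, {"kind": "mask", "stage": mask.stage})


def load_mask(path) -> MetalMask:
    path = Path(path)
    meta = _read_sidecar(path)
    return MetalMask(values=tifffile.imread(path), stage=meta.get("stage", "seed"))


def _plain(obj):
    """Recursively coerce numpy scalars for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
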
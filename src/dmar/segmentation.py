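"""Metal-trace segmentation on projection data.

The trace is seeded by global thresholding and refined by adaptive local
thresholding.  Thresholds are quoted on the peak-normalized transmission
scale (unattenuated ray = 1.0, metal dark), the scale on which a single
number like T = 0.05 separates metal from even the densest tissue ray.  On
attenuation line integrals the seed rule is the exactly equivalent
P >= -ln(T): high attenuation means metal, ties inclusive.

Seeding deliberately under-segments: rays grazing a metal edge carry a
vanishing metal chord, so the trace fringe always falls on the tissue side
of any safe global threshold.  The adaptive step recovers that fringe from
local statistics of the attenuation data.  For every island of seed pixels,
the observed intensity spread [B, A] (min/max of the peak-normalized
attenuation P over the island) is widened by a multiple of the island's
standard deviation, and pixels within a search window of the island whose
value falls inside the widened band [B - a*sigma, A + a*sigma] are
annexed; the lower edge of the band is what reaches below the seed
threshold and recovers the fringe, while it stays above the local tissue
background.  When a metal object overlaps other dense anatomy the island's
statistics shift up with it, raising the band so the region does not grow
into tissue.  The final mask is the union of seed and annexed pixels;
masks use the metal = 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .projector import Sinogram
from .recon import ReconImage

__all__ = [
    "MetalMask",
    "Island",
    "IslandStats",
    "SegmentationParams",
    "global_threshold_mask",
    "transmission_image",
    "seed_mask",
    "find_islands",
    "find_islands_2d",
    "island_statistics",
    "adaptive_expand",
    "expand_projection_image",
    "image_metal_mask",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Control parameters of the metal-trace segmentation.

    T is the global threshold on the peak-normalized transmission scale,
    W the half-width (in detector bins) of the search window around each
    island, and a the scaling factor applied to the island's standard
    deviation when widening the acceptance band.
    """

    T: float = 0.05
    W: int = 30
    a: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.T < 1.0:
            raise ValueError("threshold T must lie in (0, 1)")
        if self.W < 1:
            raise ValueError("window half-width W must be >= 1")
        if self.a <= 0:
            raise ValueError("scaling factor a must be positive")


@dataclass(frozen=True)
class MetalMask:
    """Binary mask congruent with projection data; metal = 0, background = 1."""

    values: np.ndarray
    stage: str = "seed"  # "seed" or "expanded"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "values", v)

    @property
    def metal(self) -> np.ndarray:
        return self.values == 0

    def metal_count(self) -> int:
        return int((self.values == 0).sum())


@dataclass(frozen=True)
class Island:
    """A connected metal region with its per-line detector intervals.

    For a 2-D sinogram an island is a maximal run of metal pixels along the
    detector axis of one view: ``intervals`` then holds a single entry
    {view: (s1, s2)}.  For an (s, t) projection image an island is a
    4-connected component and ``intervals`` maps each row t to its [s1, s2].
    """

    island_id: int
    view: int | None
    pixels: tuple[np.ndarray, np.ndarray]  # (s indices, line indices)
    intervals: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.pixels[0])


@dataclass(frozen=True)
class IslandStats:
    """Pixel-intensity statistics of one island: min B, max A, std sigma."""

    island_id: int
    view: int | None
    sigma: float
    A: float
    B: float

    def __post_init__(self) -> None:
        if self.B > self.A or self.sigma < 0:
            raise ValueError("inconsistent island statistics")


def global_threshold_mask(values: np.ndarray, T: float) -> MetalMask:
    """Elementwise global threshold: metal (0) where values >= T, else 1."""
    if not 0.0 < T < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    values = np.asarray(values)
    return MetalMask(values=(values < T).astype(np.uint8), stage="seed")


def transmission_image(sino: Sinogram) -> np.ndarray:
    """Peak-normalized transmitted intensity exp(-P) of an attenuation sinogram.

    Unattenuated rays map to 1.0; the metal trace is dark.  Uses the
    pre-normalization attenuation scale, so the result is independent of
    whether the sinogram was peak-normalized.
    """
    return np.exp(-sino.unnormalized_values())


def seed_mask(sino: Sinogram, T: float) -> MetalMask:
    """Global-threshold seed of the metal trace at transmission threshold T.

    Equivalent attenuation rule: metal where P_unnormalized >= -ln(T).
    """
    if not 0.0 < T < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    p = sino.unnormalized_values()
    t_att = -np.log(T)
    return MetalMask(values=(p < t_att).astype(np.uint8), stage="seed")


def find_islands(mask: MetalMask, view: int) -> list[Island]:
    """Maximal runs of metal pixels along the detector axis of one view."""
    col = mask.values[:, view]
    metal = col == 0
    if not metal.any():
        return []
    padded = np.concatenate(([False], metal, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    islands = []
    for i, (s1, s2) in enumerate(zip(starts, stops - 1)):
        s_idx = np.arange(s1, s2 + 1)
        islands.append(
            Island(
                island_id=i,
                view=view,
                pixels=(s_idx, np.full_like(s_idx, view)),
                intervals={view: (int(s1), int(s2))},
            )
        )
    return islands


def find_islands_2d(mask: MetalMask) -> list[Island]:
    """4-connected metal components of an (s, t) projection image."""
    metal = mask.values == 0
    labeled, n = ndimage.label(metal, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    islands = []
    for i in range(1, n + 1):
        s_idx, t_idx = np.nonzero(labeled == i)
        intervals = {}
        for t in np.unique(t_idx):
            srow = s_idx[t_idx == t]
            intervals[int(t)] = (int(srow.min()), int(srow.max()))
        islands.append(Island(island_id=i - 1, view=None, pixels=(s_idx, t_idx), intervals=intervals))
    return islands


def island_statistics(values: np.ndarray, island: Island) -> IslandStats:
    """sigma (population), max A and min B of the data over the island's pixels."""
    if island.size == 0:
        raise ValueError("island is empty")
    vals = np.asarray(values)[island.pixels]
    return IslandStats(
        island_id=island.island_id,
        view=island.view,
        sigma=float(vals.std()),  # population convention (N divisor)
        A=float(vals.max()),
        B=float(vals.min()),
    )


def _expand_lines(values, seed_metal, islands, stats, params, axis):
    """Annex band-matching pixels within W of each island interval.

    ``axis`` 0 expands along s (within a line of constant second index);
    ``axis`` 1 expands along the other direction using the transposed view.
    """
    new_metal = np.zeros_like(seed_metal)
    n_s = values.shape[0] if axis == 0 else values.shape[1]
    for island, st in zip(islands, stats):
        lo, hi = st.B - params.a * st.sigma, st.A + params.a * st.sigma
        for line, (s1, s2) in island.intervals.items():
            w0, w1 = max(0, s1 - params.W), min(n_s - 1, s2 + params.W)
            segment = values[w0 : w1 + 1, line] if axis == 0 else values[line, w0 : w1 + 1]
            hit = (segment >= lo) & (segment <= hi)
            if axis == 0:
                new_metal[w0 : w1 + 1, line] |= hit
            else:
                new_metal[line, w0 : w1 + 1] |= hit
    return new_metal


def adaptive_expand(
    values: np.ndarray | Sinogram, seed: MetalMask, params: SegmentationParams
) -> MetalMask:
    """Adaptive local-threshold expansion of a seed mask on a 2-D sinogram.

    ``values`` is the projection-intensity image on which the island
    statistics are taken: for a :class:`Sinogram` this is its peak-normalized
    attenuation data (the same P the seed rule thresholds); any congruent
    array may be passed for synthetic inputs.  Islands are per-view runs
    along the detector axis; statistics are taken per island, the acceptance
    band is [B - a*sigma, A + a*sigma] (ties inclusive) and the search
    window [s1 - W, s2 + W] is clipped at the detector edges.  The result is
    the union of seed and annexed pixels.
    """
    if isinstance(values, Sinogram):
        v = values.values
        values = v if values.is_normalized else v / v.max()
    values = np.asarray(values)
    if values.shape != seed.values.shape:
        raise ValueError("values and seed mask must be congruent")
    seed_metal = seed.values == 0
    islands: list[Island] = []
    for view in range(values.shape[1]):
        islands.extend(find_islands(seed, view))
    stats = [island_statistics(values, isl) for isl in islands]
    annexed = _expand_lines(values, seed_metal, islands, stats, params, axis=0)
    return MetalMask(values=(~(seed_metal | annexed)).astype(np.uint8), stage="expanded")


def expand_projection_image(
    values: np.ndarray, seed: MetalMask, params: SegmentationParams
) -> MetalMask:
    """Two-pass expansion for an (s, t) projection image.

    Horizontal pass along s on the 2-D connected-component islands, then one
    vertical pass along t with islands and statistics recomputed on the
    intermediate mask.  No iteration to a fixed point.
    """
    values = np.asarray(values)
    if values.shape != seed.values.shape:
        raise ValueError("values and seed mask must be congruent")

    def one_pass(mask: MetalMask, axis: int) -> MetalMask:
        metal = mask.values == 0
        islands = find_islands_2d(mask)
        if axis == 1:  # per-column intervals for the vertical pass
            islands = [
                Island(
                    island_id=isl.island_id,
                    view=None,
                    pixels=isl.pixels,
                    intervals={
                        int(s): (int(isl.pixels[1][isl.pixels[0] == s].min()),
                                 int(isl.pixels[1][isl.pixels[0] == s].max()))
                        for s in np.unique(isl.pixels[0])
                    },
                )
                for isl in islands
            ]
        stats = [island_statistics(values, isl) for isl in islands]
        annexed = _expand_lines(values, metal, islands, stats, params, axis=axis)
        return MetalMask(values=(~(metal | annexed)).astype(np.uint8), stage="expanded")

    return one_pass(one_pass(seed, axis=0), axis=1)


def image_metal_mask(image: ReconImage | np.ndarray, threshold: float) -> MetalMask:
    """Image-domain metal mask: metal (0) where pixel attenuation >= threshold."""
    values = image.values if isinstance(image, ReconImage) else np.asarray(image)
    return MetalMask(values=(values < threshold).astype(np.uint8), stage="image")
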
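import numpy as np
import pytest

from dmar.projector import Geometry, Sinogram
from dmar.segmentation import (
    Island,
    MetalMask,
    SegmentationParams,
    adaptive_expand,
    expand_projection_image,
    find_islands,
    find_islands_2d,
    global_threshold_mask,
    image_metal_mask,
    island_statistics,
    seed_mask,
    transmission_image,
)


def brute_force_expand(values, seed_metal, W, a):
    """Independent per-pixel evaluation of the expansion criterion.

    For every island (maximal run of seed-metal pixels along the detector
    axis of each view): stats over the island, band [B - a*sigma, A + a*sigma]
    inclusive, window [s1 - W, s2 + W] clipped; final set is the union.
    """
    n_s, n_views = values.shape
    out = seed_metal.copy()
    for view in range(n_views):
        col = seed_metal[:, view]
        s = 0
        while s < n_s:
            if not col[s]:
                s += 1
                continue
            s1 = s
            while s + 1 < n_s and col[s + 1]:
                s += 1
            s2 = s
            vals = values[s1 : s2 + 1, view]
            B, A, sig = vals.min(), vals.max(), vals.std()
            lo, hi = B - a * sig, A + a * sig
            for t in range(max(0, s1 - W), min(n_s - 1, s2 + W) + 1):
                if lo <= values[t, view] <= hi:
                    out[t, view] = True
            s += 1
    return out


def test_global_threshold_elementwise(rng):
    values = rng.uniform(size=(40, 9))
    values[5, 3] = 0.6  # exact-tie pixel
    mask = global_threshold_mask(values, 0.6)
    expected = np.where(values >= 0.6, 0, 1)
    assert np.array_equal(mask.values, expected)
    assert mask.values[5, 3] == 0  # value equal to T is metal


def test_global_threshold_validation():
    with pytest.raises(ValueError):
        global_threshold_mask(np.zeros((4, 4)), 1.5)
    with pytest.raises(ValueError):
        global_threshold_mask(np.zeros((4, 4)), 0.0)


def test_seed_mask_is_transmission_threshold(random_sinogram):
    """Seed rule P >= -ln(T) is the transmission rule exp(-P) <= T."""
    T = 0.45
    mask = seed_mask(random_sinogram, T)
    trans = transmission_image(random_sinogram)
    assert np.array_equal(mask.metal, trans <= T)


def test_find_islands_runs():
    values = np.ones((60, 3), dtype=np.uint8)
    values[10:21, 1] = 0
    values[40:46, 1] = 0
    mask = MetalMask(values=values)
    islands = find_islands(mask, view=1)
    assert [isl.intervals[1] for isl in islands] == [(10, 20), (40, 45)]
    assert find_islands(mask, view=0) == []


def test_find_islands_random_against_labeling(rng):
    values = (rng.uniform(size=(50, 6)) > 0.3).astype(np.uint8)
    mask = MetalMask(values=values)
    for view in range(6):
        got = set()
        for isl in find_islands(mask, view):
            got.update(zip(isl.pixels[0].tolist(), isl.pixels[1].tolist()))
        expected = {(s, view) for s in np.flatnonzero(values[:, view] == 0)}
        assert got == expected


def test_island_statistics_conventions():
    vals = np.array([[0.6], [0.8], [1.0]])
    isl = Island(island_id=0, view=0, pixels=(np.arange(3), np.zeros(3, int)),
                 intervals={0: (0, 2)})
    st = island_statistics(vals, isl)
    assert st.A == 1.0 and st.B == 0.6
    # population convention: sqrt(((.2)^2 + 0 + (.2)^2)/3)
    assert st.sigma == pytest.approx(np.sqrt(0.08 / 3))
    # order invariance
    shuffled = island_statistics(vals[::-1], Island(
        island_id=0, view=0, pixels=(np.arange(3), np.zeros(3, int)), intervals={0: (0, 2)}))
    assert shuffled.sigma == pytest.approx(st.sigma)
    const = island_statistics(np.full((3, 1), 0.7), isl)
    assert const.sigma == pytest.approx(0.0, abs=1e-12)
    assert const.A == const.B == 0.7


def test_expand_sigma_zero_band_collapses():
    """Uniform island: only exactly-equal neighbors are annexed."""
    values = np.full((30, 1), 0.2)
    values[10:15, 0] = 0.9
    values[16, 0] = 0.9  # equal to the island value, within W
    values[18, 0] = 0.9 - 1e-6  # epsilon below: outside the collapsed band
    seed = np.zeros((30, 1), bool)
    seed[10:15, 0] = True
    mask = MetalMask(values=(~seed).astype(np.uint8))
    out = adaptive_expand(values, mask, SegmentationParams(T=0.5, W=5, a=2.0))
    assert out.metal[16, 0]
    assert not out.metal[18, 0]
    assert out.stage == "expanded"


def test_expand_matches_brute_force_oracle(rng):
    """Trapezoidal and random profiles: criterion equals per-pixel evaluation."""
    # trapezoidal metal profile in one view
    ramp = np.concatenate([
        np.full(20, 0.1), np.linspace(0.1, 0.9, 10), np.full(15, 0.9),
        np.linspace(0.9, 0.1, 10), np.full(25, 0.1),
    ])[:, None]
    seed = ramp >= 0.7
    params = SegmentationParams(T=0.7, W=8, a=2.0)
    got = adaptive_expand(ramp, MetalMask(values=(~seed).astype(np.uint8)), params)
    expected = brute_force_expand(ramp, seed, W=8, a=2.0)
    assert np.array_equal(got.metal, expected)
    # random case
    values = rng.uniform(size=(64, 7))
    seed = values >= 0.85
    got = adaptive_expand(values, MetalMask(values=(~seed).astype(np.uint8)),
                          SegmentationParams(T=0.85, W=6, a=1.5))
    expected = brute_force_expand(values, seed, W=6, a=1.5)
    assert np.array_equal(got.metal, expected)


def test_expand_superset_and_locality(rng):
    values = rng.uniform(size=(80, 10))
    seed = values >= 0.9
    W = 4
    mask = MetalMask(values=(~seed).astype(np.uint8))
    out = adaptive_expand(values, mask, SegmentationParams(T=0.9, W=W, a=2.0))
    # superset: every seed pixel stays metal
    assert np.all(out.metal[seed])
    # locality: pixels farther than W from every island are never annexed
    for view in range(10):
        islands = find_islands(mask, view)
        allowed = np.zeros(80, bool)
        for isl in islands:
            s1, s2 = isl.intervals[view]
            allowed[max(0, s1 - W) : s2 + W + 1] = True
        assert not np.any(out.metal[:, view] & ~allowed)


def test_expand_overlap_robustness():
    """Raising island intensities raises the band: low pixels are not added."""
    base = np.full((40, 1), 0.3)
    base[15:20, 0] = np.array([0.75, 0.8, 0.85, 0.8, 0.75])
    seed = base >= 0.75
    params = SegmentationParams(T=0.75, W=6, a=2.0)
    mask = MetalMask(values=(~seed).astype(np.uint8))
    out_low = adaptive_expand(base, mask, params)
    lifted = base.copy()
    lifted[15:20, 0] += 0.1  # overlap with dense anatomy
    out_high = adaptive_expand(lifted, MetalMask(values=(~(lifted >= 0.75)).astype(np.uint8)), params)
    low_threshold = 0.5
    new_low = lambda out, vals: np.sum(out.metal & ~seed & (vals < low_threshold))
    assert new_low(out_high, lifted) <= new_low(out_low, base)


def test_expand_projection_image_two_passes():
    """The vertical pass annexes pixels the horizontal pass cannot reach."""
    values = np.full((20, 20), 0.1)
    values[8:12, 8:12] = 0.9  # metal block
    values[14, 9] = 0.9  # below the block: only reachable along t
    seed = values >= 0.8
    seed[14, 9] = False
    params = SegmentationParams(T=0.8, W=3, a=2.0)
    out = expand_projection_image(values, MetalMask(values=(~seed).astype(np.uint8)), params)
    assert out.metal[14, 9]


def test_find_islands_2d_components():
    values = np.ones((10, 10), np.uint8)
    values[1:4, 1:4] = 0
    values[6:9, 6:9] = 0
    islands = find_islands_2d(MetalMask(values=values))
    assert len(islands) == 2
    assert islands[0].intervals[1] == (1, 3)


def test_image_metal_mask_basics(rng):
    img = rng.uniform(size=(32, 32))
    mask = image_metal_mask(img, img.max() + 1.0)
    assert np.all(mask.values == 1)
    mask2 = image_metal_mask(img, 0.5)
    assert set(np.unique(mask2.values)) <= {0, 1}
    assert np.array_equal(mask2.values == 0, img >= 0.5)


def test_image_metal_mask_captures_true_metal(bilateral_small):
    """The default-style image threshold recovers >=95% of true metal pixels."""
    unc = bilateral_small.uncorrected
    mask = image_metal_mask(unc, 0.3 * float(unc.values.max()))
    true_metal = bilateral_small.phantom.material_mask("titanium")
    captured = (mask.values == 0) & true_metal
    assert captured.sum() / true_metal.sum() >= 0.95


def test_mask_validation():
    with pytest.raises(ValueError):
        MetalMask(values=np.array([[0, 2]]))
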
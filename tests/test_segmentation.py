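import itertools
import warnings

import numpy as np
import pytest

from flowdissect import apply_masks, otsu_multithreshold, segment_vessels
from flowdissect.angiography import AngiogramFrame
from flowdissect.segmentation import VesselMaskSet


def _histogram_cut_score(w, centers, cut):
    """Between-class variance proxy (sum of w_k mu_k^2) for bin cut indices."""
    bounds = (0,) + tuple(cut) + (len(w),)
    score = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        wk = w[lo:hi].sum()
        if wk == 0:
            return -np.inf
        mu = (w[lo:hi] * centers[lo:hi]).sum() / wk
        score += wk * mu ** 2
    return score


def brute_force_multiotsu(values, n_classes=3, nbins=256):
    """Exhaustive between-class-variance maximization (independent oracle).

    Returns (best score, histogram weights, bin centers) so a candidate
    threshold set can be scored with the same criterion.
    """
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    best_score = max(_histogram_cut_score(w, centers, cut)
                     for cut in itertools.combinations(range(1, nbins),
                                                       n_classes - 1))
    return best_score, w, centers


def test_multiotsu_matches_brute_force_on_toy_histogram():
    rng = np.random.default_rng(3)
    values = np.concatenate([rng.normal(0.1, 0.02, 300),
                             rng.normal(0.5, 0.03, 80),
                             rng.normal(0.95, 0.03, 40)])
    frame = AngiogramFrame(values=np.abs(values).reshape(20, 21))
    got = otsu_multithreshold(frame, n_classes=3, nbins=32)
    best_score, w, centers = brute_force_multiotsu(frame.values, 3, nbins=32)
    # the returned thresholds induce the exhaustively optimal histogram cut
    cut = tuple(int(np.searchsorted(centers, t, side="right")) for t in got)
    assert _histogram_cut_score(w, centers, cut) == pytest.approx(best_score)


def test_thresholds_fall_between_well_separated_clusters():
    rng = np.random.default_rng(7)
    values = np.abs(np.concatenate([rng.normal(0.0, 0.01, 500),
                                    rng.normal(0.5, 0.01, 100),
                                    rng.normal(1.0, 0.01, 50)]))
    t = otsu_multithreshold(values.reshape(25, 26), n_classes=3)
    # thresholds split the sample into the three generating clusters
    labels = np.digitize(values, t)
    assert np.bincount(labels, minlength=3).tolist() == [500, 100, 50]


def test_two_class_threshold_on_binary_image():
    img = np.zeros((10, 10))
    img[:, 5:] = 1.0
    t = otsu_multithreshold(img, n_classes=2)
    assert 0.0 < t[0] < 1.0


def test_constant_frame_has_no_thresholds():
    with pytest.raises(ValueError):
        otsu_multithreshold(np.ones((8, 8)), n_classes=3)


def _disk(frame, center, diameter_um, value, px_um=4.0):
    """Paint a filled disk (coverage-weighted) onto a frame array."""
    r = diameter_um / 2.0
    zz = (np.arange(frame.shape[0])[:, None] + 0.5) * px_um
    xx = (np.arange(frame.shape[1])[None, :] + 0.5) * px_um
    inside = (zz - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r
    frame[inside] = value


def _three_disk_frame(seed=0):
    rng = np.random.default_rng(seed)
    values = np.abs(rng.normal(0.05, 0.01, size=(60, 80)))
    _disk(values, (100.0, 60.0), 8.0, 0.45)
    _disk(values, (120.0, 160.0), 16.0, 0.9)
    _disk(values, (80.0, 260.0), 28.0, 0.9)
    return AngiogramFrame(values=values, pixel_size_um=(4.0, 4.0))


def test_disks_classified_small_medium_large():
    frame = _three_disk_frame()
    masks = segment_vessels(frame)
    med = [c for c in masks.components if c.vessel_class == "medium"]
    lar = [c for c in masks.components if c.vessel_class == "large"]
    assert len(med) == 1 and 10.0 <= med[0].equivalent_diameter_um <= 20.0
    assert len(lar) == 1 and lar[0].equivalent_diameter_um > 20.0
    # equivalent diameter near truth, within pixel quantization
    assert lar[0].equivalent_diameter_um == pytest.approx(28.0, abs=4.0)
    assert med[0].equivalent_diameter_um == pytest.approx(16.0, abs=3.0)
    # the 8-um disk is captured by the small mask, not the resolved masks
    assert masks.masks["small"][25, 15]          # center px of the 8-um disk
    assert not masks.masks["medium"][25, 15]
    assert not masks.masks["large"][25, 15]


def test_classification_invariant_to_intensity_rescale():
    frame = _three_disk_frame()
    scaled = AngiogramFrame(values=frame.values * 7.5,
                            pixel_size_um=frame.pixel_size_um)
    m1 = segment_vessels(frame)
    m2 = segment_vessels(scaled)
    for cls in ("small", "medium", "large"):
        assert np.array_equal(m1.masks[cls], m2.masks[cls])


def test_all_zero_frame_warns_and_returns_empty_masks():
    frame = AngiogramFrame(values=np.zeros((20, 20)))
    with pytest.warns(UserWarning):
        masks = segment_vessels(frame)
    assert all(not masks.masks[c].any() for c in ("small", "medium", "large"))
    assert masks.components == []


def test_masks_are_pairwise_disjoint():
    masks = segment_vessels(_three_disk_frame())
    for a, b in itertools.combinations(("small", "medium", "large"), 2):
        assert not np.any(masks.masks[a] & masks.masks[b])


def test_overlapping_masks_rejected_at_construction():
    m = np.zeros((4, 4), dtype=bool)
    m[0, 0] = True
    with pytest.raises(ValueError, match="overlap"):
        VesselMaskSet(masks={"small": m, "medium": m, "large": ~m},
                      components=[], thresholds=np.array([]),
                      pixel_size_um=(4.0, 4.0))


def test_apply_masks_constant_frame_and_loop_oracle():
    masks = segment_vessels(_three_disk_frame())
    const = np.full(masks.shape, 2.5)
    sums = apply_masks([const], masks)
    for cls in ("small", "medium", "large"):
        assert sums[cls][0] == pytest.approx(2.5 * masks.masks[cls].sum())

    rng = np.random.default_rng(1)
    frame = rng.uniform(0, 1, size=masks.shape)
    sums = apply_masks([frame], masks)
    for cls in ("small", "medium", "large"):
        oracle = sum(frame[i, j] for i in range(frame.shape[0])
                     for j in range(frame.shape[1]) if masks.masks[cls][i, j])
        assert sums[cls][0] == pytest.approx(oracle)
    # disjointness implies subadditivity against the whole frame
    assert sum(sums[c][0] for c in ("small", "medium", "large")) <= frame.sum()


def test_apply_masks_geometry_mismatch():
    masks = segment_vessels(_three_disk_frame())
    with pytest.raises(ValueError, match="match"):
        apply_masks([np.ones((5, 5))], masks)
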
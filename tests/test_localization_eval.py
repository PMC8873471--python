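import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holodsn.localization_eval import (
    CentroidSet,
    binarize_volume,
    depthwise_ji,
    detect_centroids,
    filter_clusters,
    jaccard_index,
    match_and_classify,
    weight_statistics,
)


# -- binarization ------------------------------------------------------------

def test_otsu_threshold_separates_bimodal_slice(rng):
    sl = np.full((20, 20), 0.1)
    sl.ravel()[rng.choice(400, size=40, replace=False)] = 0.9
    vol = sl[:, :, None]
    binary = binarize_volume(vol)
    assert np.array_equal(binary[:, :, 0], (sl > 0.5).astype(np.uint8))


def test_otsu_constant_slice_is_background():
    vol = np.full((10, 10, 3), 0.4)
    assert not binarize_volume(vol).any()


def test_otsu_matches_exhaustive_between_class_variance(rng):
    """Slice-wise threshold equals brute-force search over 256 bin edges."""
    sl = rng.uniform(size=(32, 32))
    binary = binarize_volume(sl[:, :, None])[:, :, 0]

    # brute-force oracle: maximize between-class variance over histogram edges
    counts, edges = np.histogram(sl, bins=256)
    best_t, best_var = None, -1.0
    centers = (edges[:-1] + edges[1:]) / 2
    for cut in range(1, 256):
        w0 = counts[:cut].sum()
        w1 = counts[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:cut] * centers[:cut]).sum() / w0
        m1 = (counts[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, edges[cut]
    oracle = (sl > best_t - 1e-12).astype(np.uint8)
    # thresholds may differ by one bin width; compare resulting masks
    assert (binary != oracle).mean() < 0.01


# -- cluster filtering -------------------------------------------------------

def _block_volume(shape, blocks):
    vol = np.zeros(shape, dtype=np.uint8)
    for sl in blocks:
        vol[sl] = 1
    return vol


def test_cluster_filter_boundary_9_removed_10_kept():
    nine = _block_volume((20, 20, 5), [(slice(0, 3), slice(0, 3), slice(0, 1))])
    assert nine.sum() == 9
    assert not filter_clusters(nine).any()
    ten = _block_volume((20, 20, 5), [(slice(5, 10), slice(5, 7), slice(2, 3))])
    assert ten.sum() == 10
    assert np.array_equal(filter_clusters(ten), ten)


def test_cluster_filter_against_flood_fill_oracle(rng):
    vol = (rng.uniform(size=(16, 16, 6)) > 0.7).astype(np.uint8)
    kept = filter_clusters(vol, min_voxels=5)

    # independent 26-connectivity flood fill
    visited = np.zeros(vol.shape, dtype=bool)
    survivors = 0
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for start in zip(*np.nonzero(vol)):
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = tuple(np.add(p, off))
                if all(0 <= q[i] < vol.shape[i] for i in range(3)) \
                        and vol[q] and not visited[q]:
                    visited[q] = True
                    stack.append(q)
        if len(comp) >= 5:
            survivors += 1

    from scipy import ndimage
    _, n_kept = ndimage.label(kept, structure=np.ones((3, 3, 3)))
    assert n_kept == survivors


# -- centroids ---------------------------------------------------------------

def test_centroid_of_block_is_geometric_center(toy_cfg):
    vol = _block_volume((32, 32, 10), [(slice(4, 6), slice(8, 10), slice(2, 3))])
    cs = detect_centroids(vol, toy_cfg)
    assert len(cs) == 1
    # voxel centers at (i+0.5)*0.5 um laterally, (k+1)*5 um axially
    assert cs.points_um[0] == pytest.approx([2.5, 4.5, 15.0])


def test_centroids_empty_volume(toy_cfg):
    assert len(detect_centroids(np.zeros((32, 32, 10), dtype=np.uint8), toy_cfg)) == 0


def test_centroids_two_blocks_match_mean_oracle(toy_cfg, rng):
    vol = _block_volume((32, 32, 10), [
        (slice(2, 5), slice(2, 5), slice(1, 2)),
        (slice(20, 24), slice(20, 22), slice(7, 9)),
    ])
    cs = detect_centroids(vol, toy_cfg)
    assert len(cs) == 2
    for sl in [(slice(2, 5), slice(2, 5), slice(1, 2)),
               (slice(20, 24), slice(20, 22), slice(7, 9))]:
        coords = np.array(np.nonzero(_block_volume(vol.shape, [sl]))).T
        expected = np.array([
            (coords[:, 0].mean() + 0.5) * 0.5,
            (coords[:, 1].mean() + 0.5) * 0.5,
            (coords[:, 2].mean() + 1.0) * 5.0,
        ])
        assert np.min(np.linalg.norm(cs.points_um - expected, axis=1)) < 1e-9


# -- matching ----------------------------------------------------------------

def test_perfect_prediction_all_tp(rng):
    pts = rng.uniform(0, 40, size=(7, 3))
    m = match_and_classify(CentroidSet(pts.copy()), CentroidSet(pts.copy()))
    assert (m.tp, m.fp, m.fn) == (7, 0, 0)


def test_gate_boundary_axial_displacement():
    truth = CentroidSet(np.array([[10.0, 10.0, 20.0]]))
    inside = CentroidSet(np.array([[10.0, 10.0, 25.0]]))   # dz = 5 < 6 semi-axis
    outside = CentroidSet(np.array([[10.0, 10.0, 32.5]]))  # dz = 12.5 > 6
    assert match_and_classify(inside, truth).tp == 1
    m = match_and_classify(outside, truth)
    assert (m.tp, m.fp, m.fn) == (0, 1, 1)


def test_elliptical_gate_mixes_axes():
    truth = CentroidSet(np.array([[0.0, 0.0, 0.0]]))
    # (dx/2)^2 + (dz/6)^2 = 0.5 + 0.49 < 1 -> TP
    near = CentroidSet(np.array([[np.sqrt(2.0), 0.0, 4.2]]))
    assert match_and_classify(near, truth).tp == 1
    # same dz but dx pushed outside the ellipse
    far = CentroidSet(np.array([[1.9, 0.0, 4.2]]))
    assert match_and_classify(far, truth).tp == 0


def test_assignment_matches_bruteforce_for_small_sets(rng):
    """Total matched distance equals the exhaustive minimum over injections."""
    for trial in range(3):
        n_p, n_t = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        p = rng.uniform(0, 20, size=(n_p, 3))
        t = rng.uniform(0, 20, size=(n_t, 3))
        m = match_and_classify(CentroidSet(p), CentroidSet(t),
                               gate_um=(1e9, 1e9, 1e9))
        got = sum(np.linalg.norm(p[i] - t[j]) for i, j in m.tp_pairs)

        k = min(n_p, n_t)
        best = np.inf
        for rows in itertools.permutations(range(n_p), k):
            for cols in itertools.permutations(range(n_t), k):
                cost = sum(np.linalg.norm(p[r] - t[c]) for r, c in zip(rows, cols))
                best = min(best, cost)
        assert got == pytest.approx(best, abs=1e-9)


def test_conservation_of_counts(rng):
    for trial in range(5):
        p = rng.uniform(0, 30, size=(rng.integers(0, 10), 3))
        t = rng.uniform(0, 30, size=(rng.integers(0, 10), 3))
        m = match_and_classify(CentroidSet(p), CentroidSet(t))
        assert m.tp + m.fp == len(p)
        assert m.tp + m.fn == len(t)


def test_shrinking_gate_never_increases_tp(rng):
    p = rng.uniform(0, 30, size=(8, 3))
    t = p + rng.normal(scale=2.0, size=p.shape)
    scales = [2.0, 1.5, 1.0, 0.7, 0.4, 0.2]
    tps = [match_and_classify(CentroidSet(p), CentroidSet(t),
                              gate_um=(4 * s, 4 * s, 12 * s)).tp
           for s in scales]
    assert all(a >= b for a, b in zip(tps, tps[1:]))


# -- Jaccard index -----------------------------------------------------------

@pytest.mark.parametrize("tp,fp,fn,expected", [
    (10, 0, 0, 1.0),
    (8, 1, 1, 0.8),
    (0, 3, 5, 0.0),
])
def test_jaccard_arithmetic(tp, fp, fn, expected):
    assert jaccard_index(tp, fp, fn) == pytest.approx(expected)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000))
def test_jaccard_bounds_and_monotonicity(tp, fp, fn):
    ji = jaccard_index(tp, fp, fn)
    if tp + fp + fn == 0:
        assert ji is None
    else:
        assert 0.0 <= ji <= 1.0
        # adding a false positive can never raise the score
        assert jaccard_index(tp, fp + 1, fn) <= ji


def test_jaccard_all_zero_is_flagged_null():
    assert jaccard_index(0, 0, 0) is None
    with pytest.raises(ValueError):
        jaccard_index(-1, 0, 0)


# -- depth bins --------------------------------------------------------------

def _match_from_points(p, t):
    return match_and_classify(CentroidSet(p), CentroidSet(t))


def test_depthwise_ji_hand_computed(toy_cfg):
    # toy geometry: 10 slices of 5 um -> 2 bins of 25 um with bin_slices=5
    # volume 1: bin0 has 2 TP; bin1 has 1 TP + 1 FN
    t1 = np.array([[5, 5, 10.0], [8, 8, 20.0], [5, 5, 35.0], [9, 9, 45.0]])
    p1 = np.vstack([t1[:3], ])
    # volume 2: bin0 1 TP + 1 FP (predicted-only, depth 12); bin1 1 TP
    t2 = np.array([[4, 4, 8.0], [6, 6, 40.0]])
    p2 = np.vstack([t2, [10, 10, 12.0]])
    report = depthwise_ji([_match_from_points(p1, t1), _match_from_points(p2, t2)],
                          toy_cfg, bin_slices=5)
    expected = np.array([[1.0, 0.5], [0.5, 1.0]])
    assert np.allclose(report.per_volume_bin_ji, expected)
    assert np.allclose(report.bin_mean, [0.75, 0.75])
    assert np.allclose(report.bin_std, [0.25, 0.25])


def test_depthwise_ji_single_bin_and_null(toy_cfg):
    t = np.array([[5.0, 5.0, 10.0]])
    report = depthwise_ji([_match_from_points(t, t)], toy_cfg, bin_slices=5)
    assert report.per_volume_bin_ji[0, 0] == 1.0
    assert np.isnan(report.per_volume_bin_ji[0, 1])


def test_depthwise_identical_volumes_zero_std(toy_cfg):
    t = np.array([[5.0, 5.0, 10.0], [8.0, 8.0, 40.0]])
    matches = [_match_from_points(t, t), _match_from_points(t, t)]
    report = depthwise_ji(matches, toy_cfg, bin_slices=5)
    assert np.allclose(report.bin_std, 0.0)


# -- synthesis weight statistics ---------------------------------------------

def test_weight_statistics_identical_samples_zero_std():
    stats = weight_statistics({"d1": np.tile([0.2, 0.5, 0.3], (6, 1))})
    assert np.allclose(stats["std"], 0.0)
    assert np.allclose(stats["mean"], [0.2, 0.5, 0.3])


def test_weight_statistics_one_hot_mixture():
    samples = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]] * 3)
    stats = weight_statistics({"c": samples})
    assert np.allclose(stats["mean"], [0.5, 0.5, 0.0])


def test_weight_statistics_means_sum_to_one(rng):
    raw = rng.uniform(size=(20, 3))
    samples = raw / raw.sum(axis=1, keepdims=True)
    stats = weight_statistics({"a": samples})
    assert stats["mean"].sum() == pytest.approx(1.0, abs=1e-6)


def test_weight_statistics_rejects_bad_groups():
    with pytest.raises(ValueError, match="no samples"):
        weight_statistics({"empty": np.empty((0, 3))})
    with pytest.raises(ValueError, match="summing"):
        weight_statistics({"bad": np.array([[0.5, 0.1, 0.1]])})
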
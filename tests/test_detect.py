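import math

import numpy as np
import pytest

import centroquant as cq
from centroquant.detect import Peak, CentrosomeRegion, _sorted_pixels
from centroquant.errors import ContractError, FormatError, ParameterError


# ---------------------------------------------------------------- oracles

def flood_fill_oracle(raster, peak, mask, fraction):
    """Naive breadth-first flood over qualifying pixels (8-connected)."""
    threshold = fraction * raster[peak]
    seen = {peak}
    queue = [peak]
    while queue:
        r, c = queue.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nb = (r + dr, c + dc)
                if nb in seen or not (0 <= nb[0] < raster.shape[0]
                                      and 0 <= nb[1] < raster.shape[1]):
                    continue
                if mask[nb] and raster[nb] >= threshold:
                    seen.add(nb)
                    queue.append(nb)
    return sorted(seen)


def peak_scan_oracle(raster, mask, min_distance, max_peaks):
    """Exhaustive local-maximum scan + plateau collapse + greedy distance
    filter, in plain Python."""
    h, w = raster.shape
    is_max = {}
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                            and raster[nr, nc] > raster[r, c]:
                        ok = False
            if ok:
                is_max[(r, c)] = raster[r, c]
    # collapse 8-connected equal-valued plateaus to their smallest pixel
    remaining = set(is_max)
    candidates = []
    for px in sorted(remaining):
        if px not in remaining:
            continue
        comp = {px}
        queue = [px]
        while queue:
            r, c = queue.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in remaining and nb not in comp \
                            and is_max[nb] == is_max[px]:
                        comp.add(nb)
                        queue.append(nb)
        remaining -= comp
        candidates.append((min(comp), is_max[px]))
    candidates.sort(key=lambda t: (-t[1], t[0]))
    # plateaus at the mask minimum only stand in when nothing else exists
    mask_min = raster[mask].min()
    contrasted = [c for c in candidates if c[1] > mask_min]
    if contrasted:
        candidates = contrasted
    accepted = []
    for (r, c), _val in candidates:
        if len(accepted) >= max_peaks:
            break
        if all(math.dist((r, c), a) >= min_distance for a in accepted):
            accepted.append((r, c))
    return accepted


def union_find_oracle(points, merge_distance):
    """Transitive closure of the strict pairwise-distance graph."""
    parent = list(range(len(points)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if math.dist(points[i], points[j]) < merge_distance:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(points)):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def _gauss(shape, center, amp, sigma):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return amp * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                        / (2 * sigma ** 2))


def _region(cell_id, cid, peaks_rc, pixels):
    peaks = [Peak(r, c, b) for r, c, b in peaks_rc]
    return CentrosomeRegion(cell_id=cell_id, centrosome_id=cid, peaks=peaks,
                            pixels=_sorted_pixels(np.array(pixels)))


# ------------------------------------------------------------------ blur

def test_blur_sigma_zero_is_identity():
    rng = np.random.default_rng(0)
    raster = rng.uniform(0, 100, (20, 20))
    np.testing.assert_array_equal(cq.blur_channel(raster, 0.0), raster)


def test_blur_preserves_constant():
    raster = np.full((30, 30), 7.5)
    np.testing.assert_allclose(cq.blur_channel(raster, 3.0), 7.5, rtol=1e-12)


def test_blur_impulse_matches_explicit_kernel():
    """A delta impulse maps to the sampled, normalized, truncated Gaussian
    kernel (separable product), computed here directly."""
    sigma = 2.0
    raster = np.zeros((21, 21))
    raster[10, 10] = 1.0
    blurred = cq.blur_channel(raster, sigma)
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-x ** 2 / (2 * sigma ** 2))
    k /= k.sum()
    expected = np.zeros_like(raster)
    expected[10 - radius:10 + radius + 1, 10 - radius:10 + radius + 1] = \
        np.outer(k, k)
    np.testing.assert_allclose(blurred, expected, atol=1e-12)


def test_blur_negative_sigma_rejected():
    with pytest.raises(ParameterError):
        cq.blur_channel(np.zeros((5, 5)), -1.0)


# ----------------------------------------------------------- find_peaks

def test_two_spots_12px_apart_both_found():
    raster = _gauss((40, 40), (20, 14), 100, 2) + _gauss((40, 40), (20, 26), 90, 2)
    mask = np.ones((40, 40), bool)
    peaks = cq.find_peaks_in_cell(raster, mask, cq.DetectionConfig())
    got = sorted(p.coord for p in peaks)
    assert len(got) == 2
    assert math.dist(got[0], (20, 14)) <= 1
    assert math.dist(got[1], (20, 26)) <= 1


def test_close_maxima_keep_only_brighter():
    """Two maxima 4 px apart violate the 6-px minimum distance; only the
    brighter survives."""
    raster = _gauss((20, 20), (10, 8), 100, 1.2) + _gauss((20, 20), (10, 12),
                                                          90, 1.2)
    peaks = cq.find_peaks_in_cell(raster, np.ones((20, 20), bool),
                                  cq.DetectionConfig())
    assert [p.coord for p in peaks] == [(10, 8)]


def test_constant_mask_single_low_contrast_peak():
    raster = np.full((15, 15), 3.0)
    mask = np.zeros((15, 15), bool)
    mask[4:11, 4:11] = True
    peaks = cq.find_peaks_in_cell(raster, mask, cq.DetectionConfig())
    assert len(peaks) == 1
    assert peaks[0].coord == (4, 4)          # lexicographic tie-break
    assert peaks[0].low_contrast


def test_empty_mask_rejected():
    with pytest.raises(ContractError):
        cq.find_peaks_in_cell(np.zeros((5, 5)), np.zeros((5, 5), bool),
                              cq.DetectionConfig())


def test_find_peaks_matches_exhaustive_scan_oracle():
    rng = np.random.default_rng(42)
    config = cq.DetectionConfig()
    for _ in range(100):
        h = int(rng.integers(8, 33))
        w = int(rng.integers(8, 33))
        raster = rng.uniform(0, 100, (h, w))
        mask = rng.uniform(size=(h, w)) < 0.8
        if not mask.any():
            continue
        got = [p.coord for p in cq.find_peaks_in_cell(raster, mask, config)]
        want = peak_scan_oracle(raster, mask, config.min_peak_distance,
                                config.max_peaks_per_cell)
        assert got == want


# --------------------------------------------------------- expand_region

def test_expansion_threshold_boundary_inclusive():
    """At a peak of 100, a neighbor at exactly 70.0 is included
    (>= 0.70 x peak) and one at 69.9 is excluded."""
    raster = np.zeros((9, 9))
    raster[4, 4] = 100.0
    raster[4, 5] = 70.0
    raster[4, 3] = 69.9
    pixels = cq.expand_region(raster, (4, 4), np.ones((9, 9), bool), 0.70)
    coords = {tuple(p) for p in pixels}
    assert (4, 5) in coords
    assert (4, 3) not in coords
    assert coords == {(4, 4), (4, 5)}


def test_isolated_peak_region_is_single_pixel():
    raster = np.zeros((9, 9))
    raster[4, 4] = 50.0
    pixels = cq.expand_region(raster, (4, 4), np.ones((9, 9), bool), 0.70)
    assert pixels.tolist() == [[4, 4]]


def test_peak_outside_mask_rejected():
    raster = np.ones((6, 6))
    mask = np.zeros((6, 6), bool)
    mask[0:3, 0:3] = True
    with pytest.raises(ContractError):
        cq.expand_region(raster, (5, 5), mask, 0.7)


def test_expand_matches_flood_fill_oracle():
    rng = np.random.default_rng(7)
    for _ in range(100):
        raster = rng.uniform(0, 100, (15, 15))
        mask = rng.uniform(size=(15, 15)) < 0.85
        in_mask = np.argwhere(mask)
        if len(in_mask) == 0:
            continue
        peak = tuple(in_mask[rng.integers(len(in_mask))])
        got = [tuple(p) for p in cq.expand_region(raster, peak, mask, 0.7)]
        assert got == flood_fill_oracle(raster, peak, mask, 0.7)


def test_raising_fraction_never_grows_region():
    rng = np.random.default_rng(9)
    raster = rng.uniform(0, 100, (20, 20))
    mask = np.ones((20, 20), bool)
    peak = (10, 10)
    prev = None
    for fraction in (0.3, 0.5, 0.7, 0.9):
        region = {tuple(p) for p in cq.expand_region(raster, peak, mask,
                                                     fraction)}
        if prev is not None:
            assert region <= prev
        prev = region


# ----------------------------------------------------- merge and filter

def test_peaks_8px_apart_merge_to_one_region():
    a = _region(1, 1, [(0, 0, 10.0)], [(0, 0), (0, 1)])
    b = _region(1, 2, [(0, 8, 12.0)], [(0, 8), (0, 9)])
    merged = cq.merge_close_peaks([a, b], 10.0)
    assert len(merged) == 1
    assert merged[0].peak_brightness == 12.0
    assert {tuple(p) for p in merged[0].pixels} == {(0, 0), (0, 1), (0, 8), (0, 9)}


def test_peaks_exactly_10px_apart_not_merged():
    a = _region(1, 1, [(0, 0, 10.0)], [(0, 0)])
    b = _region(1, 2, [(0, 10, 12.0)], [(0, 10)])
    assert len(cq.merge_close_peaks([a, b], 10.0)) == 2


def test_merge_chain_transitive_closure():
    regions = [_region(1, k + 1, [(0, 8 * k, 10.0 + k)], [(0, 8 * k)])
               for k in range(3)]
    merged = cq.merge_close_peaks(regions, 10.0)
    assert len(merged) == 1
    assert len(merged[0].peaks) == 3


def test_merge_matches_union_find_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(1, 8))
        pts = [(int(r), int(c)) for r, c in rng.integers(0, 30, (n, 2))]
        pts = list(dict.fromkeys(pts))       # distinct peak positions
        regions = [_region(1, i + 1, [(r, c, 1.0 + i)], [(r, c)])
                   for i, (r, c) in enumerate(pts)]
        merged = cq.merge_close_peaks(regions, 10.0)
        got = {frozenset((p.row, p.col) for p in m.peaks) for m in merged}
        want = {frozenset(pts[i] for i in grp)
                for grp in union_find_oracle(pts, 10.0)}
        assert got == want


def test_merge_empty_and_multi_cell_contract():
    assert cq.merge_close_peaks([], 10.0) == []
    a = _region(1, 1, [(0, 0, 1.0)], [(0, 0)])
    b = _region(2, 1, [(0, 1, 1.0)], [(0, 1)])
    with pytest.raises(ContractError):
        cq.merge_close_peaks([a, b], 10.0)


def test_size_filter_boundary_29_removed_30_kept():
    small = _region(1, 1, [(0, 0, 1.0)], [(0, c) for c in range(29)])
    exact = _region(1, 2, [(1, 0, 1.0)], [(1, c) for c in range(30)])
    kept = cq.filter_small_regions([small, exact], 30)
    assert [r.centrosome_id for r in kept] == [2]
    assert cq.filter_small_regions([], 30) == []


def test_size_filter_survivor_count_matches_direct_count():
    rng = np.random.default_rng(3)
    areas = rng.integers(1, 60, 20)
    regions = [_region(1, i + 1, [(i, 0, 1.0)],
                       [(i, c) for c in range(a)])
               for i, a in enumerate(areas)]
    kept = cq.filter_small_regions(regions, 30)
    assert len(kept) == int((areas >= 30).sum())
    # raising the cutoff never increases the survivor count
    assert len(cq.filter_small_regions(regions, 40)) <= len(kept)


# ------------------------------------------------------- full detection

def test_detection_recovers_well_separated_truth_spots(noise_free_field):
    """On a clean field, every cell's spot pair (separations >= 12 px)
    yields two distinct regions whose peaks sit within 2 px of the truth."""
    params, stack, labels, truth = noise_free_field
    regions = cq.detect_centrosomes(stack, labels)
    by_cell = {}
    for r in regions:
        by_cell.setdefault(r.cell_id, []).append(r)
    for cell in truth.cells.itertuples():
        cell_regions = by_cell.get(cell.cell_id, [])
        spots = truth.spots[truth.spots.cell_id == cell.cell_id]
        assert len(cell_regions) == 2
        detected = [r.peaks[0].coord for r in cell_regions]
        for spot in spots.itertuples():
            assert min(math.dist((spot.row, spot.col), d)
                       for d in detected) <= 2.0


def test_close_pair_yields_single_merged_region():
    for sep, expect_two_peaks in ((8.0, False), (10.0, True)):
        params = cq.SimulationParams(
            seed=4, n_cells=4, field_shape=(300, 300), fraction_mitotic=0.0,
            centriole_separation_range=(sep, sep), noise_model="none",
            golgi_clutter=False, gamma_debris_rate=0.0)
        stack, labels, _ = cq.generate_field(params)
        regions = cq.detect_centrosomes(stack, labels)
        per_cell = {}
        for r in regions:
            per_cell.setdefault(r.cell_id, []).append(r)
        assert all(len(v) == 1 for v in per_cell.values())
        if expect_two_peaks:
            assert any(len(v[0].peaks) == 2 for v in per_cell.values())


def test_cell_without_spots_yields_no_regions():
    """A cell with nothing above its own flat background has nothing to
    detect: its only peak candidate is the low-contrast background plateau,
    which the detector skips."""
    h = w = 80
    raster = np.full((h, w), 8.0)
    labels = np.zeros((h, w), dtype=np.int32)
    rrr = np.arange(h)[:, None]
    ccc = np.arange(w)[None, :]
    labels[(rrr - 40) ** 2 + (ccc - 40) ** 2 <= 30 ** 2] = 1
    stack = cq.ImageStack(channels={"gamma": raster})
    regions = cq.detect_centrosomes(stack, cq.CellLabelMap(labels=labels))
    assert regions == []


def test_detection_deterministic_and_sound(default_field):
    params, stack, labels, truth = default_field
    r1 = cq.detect_centrosomes(stack, labels)
    r2 = cq.detect_centrosomes(stack, labels)
    assert len(r1) == len(r2)
    for a, b in zip(r1, r2):
        assert a.peaks == b.peaks
        np.testing.assert_array_equal(a.pixels, b.pixels)
    gamma = stack.channels["gamma"]
    for region in r1:
        # region confined to its cell mask
        assert (labels.labels[region.pixels[:, 0], region.pixels[:, 1]]
                == region.cell_id).all()
        # every pixel satisfies the threshold against some member peak
        vals = gamma[region.pixels[:, 0], region.pixels[:, 1]]
        lowest_peak = min(p.brightness for p in region.peaks)
        assert (vals >= 0.70 * lowest_peak - 1e-6).all()
        assert region.area >= 30


def test_missing_gamma_channel_is_input_error(default_field):
    _, stack, labels, _ = default_field
    bad = cq.ImageStack(channels={"dna": stack.channels["dna"]})
    with pytest.raises(FormatError, match="gamma"):
        cq.detect_centrosomes(bad, labels)
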
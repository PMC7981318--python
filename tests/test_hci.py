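import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk, line_aa

from ciliascreen import hci, synthgen
from ciliascreen.hci import HCIConfig, LabeledObjects
from ciliascreen.synthgen import FieldSpec


def _noisy(img, sd=5.0, seed=0):
    return np.clip(img + np.random.default_rng(seed).normal(0, sd, img.shape), 0, None)


def _match_centroids(measured, truth_points, tol=3.0):
    """Fraction of truth points with a measured centroid within tol px."""
    pts = measured[["centroid_r", "centroid_c"]].to_numpy()
    hits = 0
    for tr, tc in truth_points:
        if len(pts) and np.min(np.hypot(pts[:, 0] - tr, pts[:, 1] - tc)) <= tol:
            hits += 1
    return hits / len(truth_points)


# ---------------------------------------------------------------------------
# nuclei


def test_blank_field_yields_no_nuclei():
    spec = FieldSpec(n_cells=0, seed=1)
    fld = synthgen.render_field(spec)
    assert hci.segment_nuclei(fld.nuclear_channel).n_objects == 0


def test_constant_image_yields_zero_objects_not_error():
    assert hci.segment_nuclei(np.full((64, 64), 7.0)).n_objects == 0


def test_non_2d_image_rejected():
    with pytest.raises(ValueError):
        hci.segment_nuclei(np.zeros((4, 4, 3)))


def test_well_separated_nuclei_counted_exactly():
    spec = FieldSpec(n_cells=50, ciliation_prob=0.0, micronucleus_rate=0.0, seed=21)
    fld = synthgen.render_field(spec)
    nuclei = hci.segment_nuclei(fld.nuclear_channel)
    assert nuclei.n_objects == 50
    truth_pts = [c.centroid for c in fld.truth]
    assert _match_centroids(nuclei.measurements, truth_pts, tol=3.0) == 1.0


def test_declumping_splits_overlapping_pairs():
    img = np.full((200, 200), 100.0)
    for c in [(50, 50), (50, 62), (120, 120), (132, 120)]:
        rr, cc = disk(c, 9, shape=img.shape)
        img[rr, cc] = 1000.0
    nuclei = hci.segment_nuclei(_noisy(img))
    assert nuclei.n_objects == 4


def test_compactness_near_one_for_discs():
    img = np.full((128, 128), 100.0)
    rr, cc = disk((64, 64), 10, shape=img.shape)
    img[rr, cc] = 1000.0
    nuclei = hci.segment_nuclei(_noisy(img))
    assert nuclei.n_objects == 1
    # compactness = perimeter^2/(4 pi area): 1 for a perfect disc, with
    # discretization tolerance
    assert nuclei.measurements["compactness"].iloc[0] == pytest.approx(1.0, abs=0.15)


# ---------------------------------------------------------------------------
# micronuclei


def test_zero_rate_gives_zero_micronuclei():
    spec = FieldSpec(n_cells=30, micronucleus_rate=0.0, ciliation_prob=0.2, seed=5)
    fld = synthgen.render_field(spec)
    nuclei = hci.segment_nuclei(fld.nuclear_channel)
    counts = hci.detect_micronuclei(fld.nuclear_channel, nuclei)
    assert counts.sum() == 0


def test_planted_micronuclei_counted_for_their_nucleus():
    img = np.full((128, 128), 100.0)
    rr, cc = disk((64, 64), 9, shape=img.shape)
    img[rr, cc] = 1000.0
    for c in [(50, 64), (64, 80)]:  # two micronuclei within search radius
        rr, cc = disk(c, 2, shape=img.shape)
        img[rr, cc] = 900.0
    nuclei = hci.segment_nuclei(_noisy(img))
    counts = hci.detect_micronuclei(_noisy(img), nuclei)
    assert nuclei.n_objects == 1
    assert counts.tolist() == [2]


def test_distant_small_object_discarded():
    img = np.full((256, 256), 100.0)
    rr, cc = disk((40, 40), 9, shape=img.shape)
    img[rr, cc] = 1000.0
    rr, cc = disk((200, 200), 2, shape=img.shape)  # far beyond search radius
    img[rr, cc] = 900.0
    nuclei = hci.segment_nuclei(_noisy(img))
    counts = hci.detect_micronuclei(_noisy(img), nuclei)
    assert counts.tolist() == [0]


def test_micronucleus_rate_recovered_on_simulation():
    """Mean recovered micronuclei per cell over 100 fields at rate 0.3 is
    within 0.1 of the generating Poisson rate."""
    vals = []
    for seed in range(100):
        spec = FieldSpec(
            n_cells=30,
            micronucleus_rate=0.3,
            ciliation_prob=0.3,
            image_shape=(256, 256),
            seed=seed,
        )
        fld = synthgen.render_field(spec)
        nuclei = hci.segment_nuclei(fld.nuclear_channel)
        micro = hci.detect_micronuclei(fld.nuclear_channel, nuclei)
        vals.append(micro.mean())
    assert abs(np.mean(vals) - 0.3) < 0.1


# ---------------------------------------------------------------------------
# cells


def test_single_centered_nucleus_one_whole_cell():
    img = np.full((256, 256), 100.0)
    rr, cc = disk((128, 128), 9, shape=img.shape)
    img[rr, cc] = 1000.0
    nuclei = hci.segment_nuclei(_noisy(img))
    cells = hci.delineate_cells(nuclei, img.shape)
    assert cells.n_objects == 1
    assert not cells.measurements["touches_border"].iloc[0]


def test_nucleus_near_edge_flagged_border():
    img = np.full((256, 256), 100.0)
    rr, cc = disk((15, 128), 9, shape=img.shape)  # expansion reaches the edge
    img[rr, cc] = 1000.0
    nuclei = hci.segment_nuclei(_noisy(img))
    cells = hci.delineate_cells(nuclei, img.shape)
    assert cells.measurements["touches_border"].iloc[0]


def test_cell_regions_tile_by_nearest_nucleus():
    """Two nuclei 20 px apart: the cell map equals a brute-force
    nearest-nucleus-pixel assignment limited to the expansion distance."""
    img = np.full((90, 90), 100.0)
    for c in [(45, 30), (45, 50)]:
        rr, cc = disk(c, 7, shape=img.shape)
        img[rr, cc] = 1000.0
    nuclei = hci.segment_nuclei(_noisy(img))
    assert nuclei.n_objects == 2
    config = HCIConfig()
    cells = hci.delineate_cells(nuclei, img.shape, config)

    # brute force: per pixel, nearest labeled nucleus pixel within distance
    lbl = nuclei.label_map
    coords = {k: np.argwhere(lbl == k) for k in (1, 2)}
    expected = np.zeros_like(lbl)
    for r in range(90):
        for c in range(90):
            best, bestd = 0, np.inf
            for k, pts in coords.items():
                d = np.min(np.hypot(pts[:, 0] - r, pts[:, 1] - c))
                if d < bestd:
                    best, bestd = k, d
            if bestd <= config.cell_expansion:
                expected[r, c] = best
    assert np.array_equal(cells.label_map, expected)


# ---------------------------------------------------------------------------
# cilia


def test_no_cilia_detected_at_zero_probability():
    spec = FieldSpec(n_cells=30, ciliation_prob=0.0, multi_cilium_prob=0.0, seed=9)
    fld = synthgen.render_field(spec)
    assert hci.detect_cilia(fld.cilium_channel).n_objects == 0


def test_planted_rods_all_detected_near_truth():
    img = np.full((256, 256), 100.0)
    centers = [(30 + 40 * i, 30 + 40 * j) for i in range(5) for j in range(6)]
    mids = []
    for k, (r, c) in enumerate(centers):
        ang = k * 0.7
        dr, dc = 5 * np.sin(ang), 5 * np.cos(ang)
        rr, cc, val = line_aa(
            int(r - dr), int(c - dc), int(r + dr), int(c + dc)
        )
        img[rr, cc] = np.maximum(img[rr, cc], 100 + val * 1500)
        mids.append((r, c))
    cilia = hci.detect_cilia(_noisy(img))
    assert cilia.n_objects == 30
    assert _match_centroids(cilia.measurements, mids, tol=3.0) == 1.0


def test_round_blobs_rejected_by_shape_filter():
    img = np.full((256, 256), 100.0)
    for c in [(64, 64), (128, 128), (192, 100)]:
        rr, cc = disk(c, 4, shape=img.shape)
        img[rr, cc] = 1500.0
    assert hci.detect_cilia(_noisy(img)).n_objects == 0


# ---------------------------------------------------------------------------
# assignment + field measurement


def _label_objects(label_map):
    return LabeledObjects(label_map=label_map, measurements=hci._measure(label_map, None))


def test_cilium_inside_cell_assigned():
    cells_map = np.zeros((64, 64), dtype=np.int32)
    cells_map[10:30, 10:30] = 1
    cilia_map = np.zeros_like(cells_map)
    cilia_map[20, 18:24] = 1
    counts = hci.assign_cilia(_label_objects(cilia_map), _label_objects(cells_map))
    assert counts.tolist() == [1]


def test_distant_cilium_unassigned():
    cells_map = np.zeros((200, 200), dtype=np.int32)
    cells_map[10:30, 10:30] = 1
    cilia_map = np.zeros_like(cells_map)
    cilia_map[150, 150:156] = 1  # ~170 px away, max_gap 10
    counts = hci.assign_cilia(_label_objects(cilia_map), _label_objects(cells_map))
    assert counts.tolist() == [0]


def test_shape_mismatch_rejected():
    a = _label_objects(np.zeros((10, 10), dtype=np.int32))
    b = _label_objects(np.zeros((12, 10), dtype=np.int32))
    with pytest.raises(ValueError, match="shape mismatch"):
        hci.assign_cilia(a, b)


def test_per_cell_counts_match_truth(small_field):
    """>= 95% of cells in a 50-cell synthetic field get the true cilium count."""
    _, fld = small_field
    nuclei = hci.segment_nuclei(fld.nuclear_channel)
    cells = hci.delineate_cells(nuclei, fld.nuclear_channel.shape)
    cilia = hci.detect_cilia(fld.cilium_channel)
    counts = hci.assign_cilia(cilia, cells)
    sc = nuclei.measurements[["centroid_r", "centroid_c"]].to_numpy()
    agree = 0
    for cell in fld.truth:
        d = np.hypot(sc[:, 0] - cell.centroid[0], sc[:, 1] - cell.centroid[1])
        agree += counts[int(np.argmin(d))] == cell.n_cilia
    assert agree / len(fld.truth) >= 0.95


def test_pct_single_cilium_arithmetic():
    # 40 whole cells; 10 with one cilium, 2 with two -> 25%
    cells_map = np.zeros((300, 300), dtype=np.int32)
    k = 0
    for i in range(8):
        for j in range(5):
            k += 1
            cells_map[20 + 30 * i : 40 + 30 * i, 20 + 30 * j : 40 + 30 * j] = k
    cells = _label_objects(cells_map)
    nuclei = cells  # stand-in; only counts are used
    counts = np.zeros(40, dtype=int)
    counts[:10] = 1
    counts[10:12] = 2
    fm = hci.measure_field(nuclei, cells, counts)
    assert fm.n_whole_cells == 40
    assert fm.n_cells_single_cilium == 10
    assert fm.pct_single_cilium == pytest.approx(25.0)
    # all-single case
    fm2 = hci.measure_field(nuclei, cells, np.ones(40, dtype=int))
    assert fm2.pct_single_cilium == pytest.approx(100.0)


def test_field_without_whole_cells_flagged_unusable():
    empty = LabeledObjects.empty((64, 64))
    fm = hci.measure_field(empty, empty, np.zeros(0, dtype=int))
    assert not fm.usable
    assert np.isnan(fm.pct_single_cilium)


def test_counting_conservation(small_field):
    _, fld = small_field
    nuclei = hci.segment_nuclei(fld.nuclear_channel)
    cells = hci.delineate_cells(nuclei, fld.nuclear_channel.shape)
    cilia = hci.detect_cilia(fld.cilium_channel)
    counts = hci.assign_cilia(cilia, cells)
    whole = ~cells.measurements["touches_border"].to_numpy(dtype=bool)
    n0 = int(((counts == 0) & whole).sum())
    n1 = int(((counts == 1) & whole).sum())
    n2 = int(((counts >= 2) & whole).sum())
    fm = hci.measure_field(nuclei, cells, counts)
    assert n0 + n1 + n2 == fm.n_whole_cells
    assert fm.n_cells_single_cilium <= fm.n_whole_cells <= fm.n_nuclei


def test_intensity_shift_leaves_counts_unchanged(small_field):
    """Thresholds are data-derived: adding a constant to both channels
    changes no object count."""
    _, fld = small_field
    fm1 = hci.analyze_field(fld.nuclear_channel, fld.cilium_channel)
    fm2 = hci.analyze_field(fld.nuclear_channel + 500.0, fld.cilium_channel + 500.0)
    assert fm1.n_nuclei == fm2.n_nuclei
    assert fm1.n_cilia == fm2.n_cilia
    assert fm1.n_whole_cells == fm2.n_whole_cells
    assert fm1.pct_single_cilium == pytest.approx(fm2.pct_single_cilium)


def test_segmentation_matches_connected_components_on_disjoint_fixture():
    """With disjoint planted objects, counts equal a brute-force
    connected-components count above the same global threshold."""
    img = np.full((256, 256), 100.0)
    centers = [(40 + 50 * i, 40 + 50 * j) for i in range(4) for j in range(4)]
    for c in centers:
        rr, cc = disk(c, 8, shape=img.shape)
        img[rr, cc] = 1000.0
    img = _noisy(img)
    from skimage.filters import threshold_otsu

    brute, _ = ndi.label(img > threshold_otsu(img))
    # apply the same minimum-area filter the pipeline uses
    areas = np.bincount(brute.ravel())
    n_brute = int((areas[1:] >= hci.HCIConfig().nucleus_min_area).sum())
    nuclei = hci.segment_nuclei(img)
    assert nuclei.n_objects == n_brute == 16
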
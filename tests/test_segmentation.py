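"""Nucleus and cell segmentation against synthetic ground truth and
constructed fixtures."""

import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi

from mitomorph import (
    LabelImage,
    MultiChannelImage,
    OpticsNoiseParams,
    SceneParams,
    SegmentationParams,
    cell_label_image,
    filter_cells,
    interior_cell_ids,
    make_scene,
    nucleus_label_image,
    render_scene,
    segment,
    segment_cells,
    segment_nuclei,
)
from mitomorph._exceptions import MissingChannelError

SMALL_SCENE = dict(cell_radius_um=(10.0, 14.0), skeleton_length_budget_um=100.0)


def _img(nucleus=None, membrane=None, mito=None, shape=(64, 64)):
    planes = {}
    if nucleus is not None:
        planes["nucleus"] = np.asarray(nucleus, dtype=np.float64)
    if membrane is not None:
        planes["membrane"] = np.asarray(membrane, dtype=np.float64)
    if mito is not None:
        planes["mito"] = np.asarray(mito, dtype=np.float64)
    if not planes:
        planes["nucleus"] = np.zeros(shape)
    return MultiChannelImage(planes=planes)


def test_blank_plane_yields_no_nuclei():
    assert segment_nuclei(_img(nucleus=np.full((64, 64), 9.0))).n_labels == 0


def test_missing_nucleus_channel_rejected():
    img = MultiChannelImage(planes={"mito": np.zeros((16, 16))})
    with pytest.raises(MissingChannelError):
        segment_nuclei(img)


def test_synthetic_nuclei_count_and_centroids():
    """8 well-separated nuclei: all found, centroids within 3 px of truth."""
    scene = make_scene(SceneParams(n_cells=8, seed=4, **SMALL_SCENE))
    img = render_scene(scene, OpticsNoiseParams(seed=4))
    nuclei = segment_nuclei(img)
    assert nuclei.n_labels == 8
    truth = {c.cell_id: c.nucleus.center for c in scene.cells}
    for lab in nuclei.ids:
        rows, cols = np.nonzero(nuclei.labels == lab)
        centroid = np.array([rows.mean(), cols.mean()])
        nearest = min(np.linalg.norm(centroid - np.array(t)) for t in truth.values())
        assert nearest < 3.0


def test_two_overlapping_discs_are_split():
    """Two discs with centres 1.5 radii apart are separated by the
    distance-transform watershed."""
    shape = (128, 128)
    rr, cc = np.mgrid[:128, :128]
    r = 30
    d1 = (rr - 64) ** 2 + (cc - 42) ** 2 <= r * r
    d2 = (rr - 64) ** 2 + (cc - 87) ** 2 <= r * r  # centres 45 = 1.5r apart
    plane = np.where(d1 | d2, 200.0, 10.0)
    nuclei = segment_nuclei(_img(nucleus=plane, shape=shape))
    assert nuclei.n_labels == 2


def test_cells_match_ground_truth_polygons():
    """Interior cells recovered with >= 90% Jaccard overlap per cell."""
    scene = make_scene(SceneParams(image_size_px=(1536, 1536), n_cells=10, seed=2))
    assert len(interior_cell_ids(scene)) == 10  # roomy field: all interior
    img = render_scene(scene, OpticsNoiseParams(seed=2))
    cells = segment(img)
    assert cells.n_labels == 10
    truth = cell_label_image(scene)
    for lab in truth.ids:
        gt = truth.labels == lab
        overlaps = cells.labels[gt]
        got = np.bincount(overlaps[overlaps > 0]).argmax()
        pred = cells.labels == got
        jaccard = np.logical_and(gt, pred).sum() / np.logical_or(gt, pred).sum()
        assert jaccard >= 0.90


def test_uniform_membrane_single_cell_covers_foreground():
    shape = (96, 96)
    nucleus = np.full(shape, 10.0)
    nucleus[40:56, 40:56] = 220.0
    membrane = np.full(shape, 30.0)
    mito = np.full(shape, 30.0)
    img = _img(nucleus=nucleus, membrane=membrane, mito=mito, shape=shape)
    nuclei = segment_nuclei(img)
    assert nuclei.n_labels == 1
    cells = segment_cells(img, nuclei)
    assert cells.n_labels == 1
    assert (cells.labels > 0).all()  # constant composite: everything foreground


def test_zero_nuclei_gives_empty_cells_with_warning():
    img = _img(nucleus=np.full((64, 64), 5.0), membrane=np.zeros((64, 64)),
               mito=np.zeros((64, 64)))
    nuclei = segment_nuclei(img)
    with pytest.warns(UserWarning, match="no nuclei"):
        cells = segment_cells(img, nuclei)
    assert cells.n_labels == 0


def test_segmentation_is_deterministic():
    scene = make_scene(SceneParams(n_cells=2, seed=9, **SMALL_SCENE,
                                   image_size_px=(320, 320)))
    img = render_scene(scene, OpticsNoiseParams(seed=9))
    a = segment(img)
    b = segment(img)
    assert np.array_equal(a.labels, b.labels)


def test_filter_cells_border_policy():
    labels = np.zeros((40, 40), dtype=np.int32)
    labels[0:20, 5:35] = 1          # touches row 0
    labels[25:39, 5:35] = 2         # interior
    params_small = SegmentationParams(cell_min_area_px=10)
    cells = LabelImage(labels, kind="cells")
    kept = filter_cells(cells, params_small)
    assert list(kept.ids) == [2]
    kept_all = filter_cells(cells, SegmentationParams(cell_min_area_px=10,
                                                      border_policy="keep"))
    assert list(kept_all.ids) == [1, 2]


def test_filter_cells_minimum_area():
    labels = np.zeros((50, 50), dtype=np.int32)
    labels[10:12, 10:12] = 1   # 4 px
    labels[20:45, 20:45] = 2   # 625 px
    kept = filter_cells(LabelImage(labels, kind="cells"),
                        SegmentationParams(cell_min_area_px=100, border_policy="keep"))
    assert list(kept.ids) == [2]


def test_filter_keeps_exactly_ground_truth_interior_cells():
    """On a crowded field, filtering the true label map keeps exactly the
    cells that do not touch the border."""
    scene = make_scene(SceneParams(n_cells=7, seed=11))
    truth = cell_label_image(scene)
    interior = set(interior_cell_ids(scene))
    assert 0 < len(interior) < 7  # crowded: some cells clipped
    kept = filter_cells(truth)
    assert set(int(i) for i in kept.ids) == interior


def test_cell_count_recovery_rate_across_seeds():
    """Recovered cell count equals the ground-truth interior count in at
    least 95% of fields at default noise."""
    matches = 0
    n_fields = 20
    for seed in range(n_fields):
        scene = make_scene(SceneParams(
            image_size_px=(640, 640), n_cells=3, seed=seed,
            cell_radius_um=(12.0, 16.0), skeleton_length_budget_um=150.0))
        img = render_scene(scene, OpticsNoiseParams(seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cells = segment(img)
        if cells.n_labels == len(interior_cell_ids(scene)):
            matches += 1
    assert matches >= 0.95 * n_fields


def test_every_cell_contains_its_nucleus_seed():
    scene = make_scene(SceneParams(n_cells=4, seed=6, image_size_px=(512, 512),
                                   **SMALL_SCENE))
    img = render_scene(scene, OpticsNoiseParams(seed=6))
    nuclei = segment_nuclei(img)
    cells = segment_cells(img, nuclei)
    assert cells.n_labels == nuclei.n_labels
    for lab in nuclei.ids:
        seed_region = nuclei.labels == lab
        assert (cells.labels[seed_region] == lab).all()
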
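"""Shape-descriptor correctness against analytic values and a brute-force
moment oracle, plus particle-analysis semantics."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomorph import LabelImage
from mitomorph.morphology import (
    MorphologyParams,
    aspect_ratio,
    binarize_mito,
    circularity,
    crofton_perimeter,
    equivalent_ellipse_axes,
    extract_particles,
    particle_from_mask,
    summarize_cell,
    summarize_cells,
)
from mitomorph._exceptions import EmptyInputError


# -- independent oracle -----------------------------------------------------

def oracle_axes(coords):
    """Brute-force covariance + closed-form 2x2 eigenvalues (independent of
    the linear-algebra route used by the implementation)."""
    n = len(coords)
    mr = sum(r for r, _ in coords) / n
    mc = sum(c for _, c in coords) / n
    srr = sum((r - mr) ** 2 for r, _ in coords) / n + 1.0 / 12.0
    scc = sum((c - mc) ** 2 for _, c in coords) / n + 1.0 / 12.0
    src = sum((r - mr) * (c - mc) for r, c in coords) / n
    tr, det_disc = srr + scc, math.sqrt((srr - scc) ** 2 + 4 * src**2)
    lam1 = (tr + det_disc) / 2.0
    lam2 = (tr - det_disc) / 2.0
    return 4.0 * math.sqrt(lam1), 4.0 * math.sqrt(max(lam2, 0.0))


def polyominoes(max_n):
    """All fixed polyominoes (4-connected masks) of 1..max_n pixels."""
    shapes = {1: {frozenset({(0, 0)})}}
    for n in range(2, max_n + 1):
        grown = set()
        for s in shapes[n - 1]:
            for r, c in s:
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    cell = (r + dr, c + dc)
                    if cell in s:
                        continue
                    t = s | {cell}
                    minr = min(r2 for r2, _ in t)
                    minc = min(c2 for _, c2 in t)
                    grown.add(frozenset((r2 - minr, c2 - minc) for r2, c2 in t))
        shapes[n] = grown
    return [sorted(s) for n in shapes for s in shapes[n]]


def disc_mask(radius, pad=2):
    size = 2 * (radius + pad) + 1
    rr, cc = np.mgrid[:size, :size]
    return (rr - radius - pad) ** 2 + (cc - radius - pad) ** 2 <= radius**2


# -- analytic descriptor values --------------------------------------------

def test_circularity_analytic_circle_and_square():
    r, s = 7.3, 4.2
    assert circularity(math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0)
    assert circularity(s * s, 4 * s) == pytest.approx(math.pi / 4)


def test_circularity_clamped_at_one():
    # tiny rasterized blobs can overshoot 1 with any discrete estimator
    assert circularity(100.0, 1.0) == 1.0


@pytest.mark.parametrize("bad", [(0.0, 5.0), (5.0, 0.0), (-1.0, 5.0)])
def test_circularity_rejects_degenerate(bad):
    with pytest.raises(ValueError):
        circularity(*bad)


@pytest.mark.parametrize("w,h", [(1, 1), (5, 3), (12, 2), (7, 7), (1, 9)])
def test_rectangle_aspect_ratio_is_side_ratio(w, h):
    coords = np.array([(r, c) for r in range(h) for c in range(w)])
    assert aspect_ratio(coords) == pytest.approx(max(w, h) / min(w, h), rel=1e-12)


def test_single_pixel_is_isotropic():
    assert aspect_ratio(np.array([[3, 5]])) == pytest.approx(1.0)
    major, minor = equivalent_ellipse_axes(np.array([[0, 0]]))
    # a unit square has variance 1/12 per axis
    assert major == pytest.approx(4 / math.sqrt(12))
    assert minor == pytest.approx(major)


def test_rasterized_disc_descriptors():
    mask = disc_mask(20)
    p = particle_from_mask(mask)
    assert 1.0 <= p.aspect_ratio <= 1.05
    assert 0.9 <= p.circularity <= 1.0


def test_empty_pixel_set_rejected():
    with pytest.raises(EmptyInputError):
        equivalent_ellipse_axes(np.empty((0, 2)))


def test_axes_match_bruteforce_oracle_exhaustively(rng):
    """Moment-equivalent-ellipse axes agree with an independent covariance
    computation on every small 4-connected mask, and on random larger ones."""
    shapes = polyominoes(8)
    assert len(shapes) == 1 + 2 + 6 + 19 + 63 + 216 + 760 + 2725
    for coords in shapes:
        got = equivalent_ellipse_axes(np.array(coords))
        want = oracle_axes(coords)
        assert got == pytest.approx(want, abs=1e-9)
    # random connected masks of 9..12 pixels
    for _ in range(300):
        n = int(rng.integers(9, 13))
        pts = {(0, 0)}
        while len(pts) < n:
            r, c = list(pts)[int(rng.integers(len(pts)))]
            dr, dc = [(1, 0), (-1, 0), (0, 1), (0, -1)][int(rng.integers(4))]
            pts.add((r + dr, c + dc))
        coords = sorted(pts)
        got = equivalent_ellipse_axes(np.array(coords))
        assert got == pytest.approx(oracle_axes(coords), abs=1e-9)


# -- geometric invariances --------------------------------------------------

@settings(max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_descriptors_invariant_under_symmetries(seed):
    r = np.random.default_rng(seed)
    mask = r.random((9, 9)) < 0.45
    mask[4, 4] = True
    from scipy import ndimage as ndi
    lab, _ = ndi.label(mask, structure=np.ones((3, 3)))
    mask = lab == lab[4, 4]
    base = particle_from_mask(mask)
    assert base.aspect_ratio >= 1.0
    assert 0.0 < base.circularity <= 1.0
    for variant in (np.rot90(mask), mask[::-1], mask[:, ::-1],
                    np.pad(mask, ((3, 1), (2, 5)))):
        p = particle_from_mask(variant)
        assert p.aspect_ratio == pytest.approx(base.aspect_ratio, rel=1e-9)
        assert p.circularity == pytest.approx(base.circularity, rel=1e-9)
        assert p.area_px == base.area_px


# -- particle extraction ----------------------------------------------------

def _cells_everywhere(shape):
    return LabelImage(np.ones(shape, dtype=np.int32), kind="cells")


def test_two_squares_are_two_particles():
    mask = np.zeros((20, 20), dtype=bool)
    mask[2:7, 2:7] = True
    mask[10:15, 10:15] = True
    particles = extract_particles(mask, _cells_everywhere(mask.shape))
    assert len(particles) == 2
    assert sorted(p.area_px for p in particles) == [25, 25]


def test_connectivity_semantics_on_diagonal_chain():
    n = 6
    mask = np.eye(n, dtype=bool)
    cells = _cells_everywhere(mask.shape)
    p8 = extract_particles(mask, cells, MorphologyParams(min_particle_area_px=1))
    p4 = extract_particles(mask, cells,
                           MorphologyParams(min_particle_area_px=1, connectivity=4))
    assert len(p8) == 1
    assert len(p4) == n


def test_min_area_filter_drops_specks():
    mask = np.zeros((12, 12), dtype=bool)
    mask[1, 1] = True            # 1-px speck
    mask[5:8, 5:8] = True        # 9-px particle
    particles = extract_particles(mask, _cells_everywhere(mask.shape))
    assert [p.area_px for p in particles] == [9]


def test_straddling_particle_assigned_by_majority_vote():
    labels = np.zeros((10, 12), dtype=np.int32)
    labels[:, :5] = 1
    labels[:, 5:] = 2
    cells = LabelImage(labels, kind="cells")
    mask = np.zeros((10, 12), dtype=bool)
    mask[4, 2:10] = True  # 3 px in cell 1, 5 px in cell 2
    mask[5, 2:10] = True
    (p,) = extract_particles(mask, cells)
    assert p.cell_id == 2


# -- per-cell binarization --------------------------------------------------

def test_constant_plane_gives_empty_mask():
    labels = np.zeros((32, 32), dtype=np.int32)
    labels[4:28, 4:28] = 1
    with pytest.warns(UserWarning, match="constant intensity"):
        mask = binarize_mito(np.full((32, 32), 7.0), LabelImage(labels, kind="cells"))
    assert not mask.any()


def test_per_cell_threshold_recovers_dim_and_bright_cells():
    """Identical structures in a dim and a bright cell are both recovered
    because each cell is thresholded on its own intensity distribution."""
    shape = (60, 120)
    labels = np.zeros(shape, dtype=np.int32)
    labels[5:55, 5:55] = 1
    labels[5:55, 65:115] = 2
    plane = np.zeros(shape)
    structure = np.zeros((50, 50), dtype=bool)
    structure[10:14, 5:45] = True
    structure[30:34, 5:45] = True
    plane[5:55, 5:55][structure] = 200.0      # bright cell
    plane[5:55, 65:115][structure] = 20.0     # 10x dimmer cell
    mask = binarize_mito(plane, LabelImage(labels, kind="cells"))
    particles = extract_particles(mask, LabelImage(labels, kind="cells"))
    per_cell = {}
    for p in particles:
        per_cell.setdefault(p.cell_id, 0)
        per_cell[p.cell_id] += p.area_px
    assert set(per_cell) == {1, 2}
    assert per_cell[1] == pytest.approx(per_cell[2], rel=0.05)


def test_intensity_rescaling_does_not_change_mask():
    r = np.random.default_rng(0)
    labels = np.zeros((64, 64), dtype=np.int32)
    labels[4:60, 4:60] = 1
    plane = r.gamma(2.0, 10.0, size=(64, 64))
    plane[20:24, 10:50] += 300.0
    a = binarize_mito(plane, LabelImage(labels, kind="cells"))
    b = binarize_mito(plane * 37.5, LabelImage(labels, kind="cells"))
    assert np.array_equal(a, b)


# -- per-cell summaries -----------------------------------------------------

def test_summarize_cell_means():
    mask = disc_mask(5)
    p1 = particle_from_mask(mask, cell_id=3)
    p2 = particle_from_mask(mask[:, : mask.shape[1] // 2], cell_id=3)
    s = summarize_cell([p1, p2])
    assert s.cell_id == 3
    assert s.n_particles == 2
    assert s.mean_circularity == pytest.approx((p1.circularity + p2.circularity) / 2)
    assert s.mean_aspect_ratio == pytest.approx((p1.aspect_ratio + p2.aspect_ratio) / 2)
    assert s.total_mito_area_px == p1.area_px + p2.area_px


def test_summarize_random_particles_matches_bruteforce(rng):
    mask = disc_mask(4)
    particles = []
    for _ in range(50):
        cid = int(rng.integers(1, 5))
        particles.append(particle_from_mask(mask, cell_id=cid))
    summaries = summarize_cells(particles)
    for s in summaries:
        mine = [p for p in particles if p.cell_id == s.cell_id]
        assert s.n_particles == len(mine)
        assert s.mean_circularity == pytest.approx(
            sum(p.circularity for p in mine) / len(mine))


def test_summarize_empty_cell_rejected():
    with pytest.raises(EmptyInputError):
        summarize_cell([])


def test_crofton_perimeter_of_large_disc_near_analytic():
    mask = disc_mask(40)
    assert crofton_perimeter(mask) == pytest.approx(2 * math.pi * 40, rel=0.03)
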
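"""Synthetic three-channel fluorescence fields with ground truth.

The generator emulates a monolayer of keratinocyte-like cells imaged in
three channels (nucleus / plasma membrane / mitochondria) so that every
pipeline stage can be validated against known geometry. A scene is:

* **cells** — disjoint star-convex polygons with radii drawn from a stated
  range, placed by rejection sampling (interior positions preferred, border
  positions allowed when the field is crowded);
* **nuclei** — one ellipse per cell near the cell centre;
* **mitochondria** — per cell, a fixed skeleton length budget split over
  ``n_frag = round(2 + 38·f)`` fragments, where the fragmentation state
  ``f ∈ [0, 1]`` spans hyperfused networks (f≈0: few, long, elongated
  structures) to a fully punctate phenotype (f=1: many small round blobs).

Each fragment is a serpentine-coiled tubule of the nominal tubule width
filling an elliptical territory whose aspect interpolates from strongly
elongated at f=0 down to circular at f=1. Coiling at a pitch equal to the
tubule width makes the rendered fragment a compact filled region whose
moment aspect ratio tracks the territory aspect and whose circularity rises
monotonically with f, while keeping the stored skeleton length exactly on
budget. Fragments are pairwise separated by a guard gap larger than the
optical blur so that ground truth and pipeline see the same particle count.

Rendering convolves each channel with a Gaussian PSF, scales to photon
counts, applies Poisson shot noise, Gaussian read noise and a constant
camera offset. Geometry and optics use separate seeds so one scene can be
re-imaged.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian
from skimage.morphology import disk

from ._exceptions import PlacementError
from .image_io import LabelImage, MultiChannelImage
from .morphology import CellMorphology, particle_from_mask, summarize_cell

#: territory aspect ratio at f=0 (hyperfused); interpolates linearly to 1 at f=1
TERRITORY_ASPECT_MAX = 6.0
#: cap on the territory semi-minor axis (px). Keeps every rendered structure
#: narrower than the top-hat background-subtraction scale of the measurement
#: pipeline (disk radius 8), so binarization preserves fragment interiors.
TERRITORY_SEMI_MINOR_MAX = 7.0
#: guard gap (px) kept between fragment masks so blur cannot merge them
FRAGMENT_GAP_PX = 4
#: cytoplasm brightness relative to the membrane ridge
CYTOPLASM_LEVEL = 0.25
#: thickness (px) of the bright plasma-membrane band
MEMBRANE_BAND_PX = 2


@dataclass(frozen=True)
class SceneParams:
    """Geometry parameters of a synthetic field.

    ``fragmentation`` is the single dial of the phenotype axis; everything
    else stays fixed across conditions. ``cell_radius_um`` is a sampling
    range; when a field is too crowded, radii are re-drawn toward the lower
    bound before placement fails.
    """

    image_size_px: tuple[int, int] = (512, 512)
    n_cells: int = 10
    cell_radius_um: tuple[float, float] = (15.0, 25.0)
    fragmentation: float = 0.5
    skeleton_length_budget_um: float = 250.0
    branch_prob: float = 0.15
    tubule_width_um: float = 0.4
    pixel_size_um: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragmentation <= 1.0:
            raise ValueError("fragmentation must lie in [0, 1]")
        if self.skeleton_length_budget_um <= 0:
            raise ValueError("skeleton length budget must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        lo, hi = self.cell_radius_um
        if not 0 < lo <= hi:
            raise ValueError("cell_radius_um must be an increasing positive range")
        if self.tubule_width_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("tubule width and pixel size must be > 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")


@dataclass(frozen=True)
class OpticsNoiseParams:
    """Imaging model: Gaussian PSF, Poisson shot noise, Gaussian read noise,
    constant camera offset. ``apply_shot_noise=False`` gives a noiseless
    rendering (used for identity-optics checks)."""

    psf_sigma_px: float = 1.2
    photon_scale: float = 200.0
    gaussian_read_sd: float = 3.0
    background_offset: float = 10.0
    apply_shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("psf_sigma_px", "photon_scale", "gaussian_read_sd", "background_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class NucleusGeometry:
    center: tuple[float, float]      # (row, col) px
    semi_axes: tuple[float, float]   # (a, b) px, a >= b
    theta: float                     # orientation, radians


@dataclass
class Fragment:
    """One mitochondrial fragment: skeleton polylines (px coords) + width."""

    polylines: list[np.ndarray]
    width_px: float

    @property
    def length_px(self) -> float:
        return float(sum(np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
                         for p in self.polylines))


@dataclass
class SyntheticCell:
    cell_id: int
    center: tuple[float, float]
    radius_px: float
    polygon: np.ndarray              # (M, 2) (row, col) vertices
    nucleus: NucleusGeometry
    fragments: list[Fragment]


@dataclass
class SyntheticScene:
    """Ground-truth geometry of one field plus the generating parameters."""

    params: SceneParams
    cells: list[SyntheticCell]

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.params.image_size_px)


# --------------------------------------------------------------------------
# geometry helpers


def _star_polygon(rng: np.random.Generator, center: tuple[float, float],
                  radius: float, n_vertices: int = 48) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    pert = np.zeros_like(theta)
    for k in range(2, 7):
        pert += rng.normal(0, 0.04 / math.sqrt(k)) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    pert = np.clip(pert, -0.12, 0.12)
    r = radius * (1.0 + pert)
    return np.column_stack([center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)])


def _polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(polygon[:, 0], polygon[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _ellipse_mask(nuc: NucleusGeometry, shape: tuple[int, int]) -> np.ndarray:
    a, b = nuc.semi_axes
    r0, c0 = nuc.center
    pad = int(math.ceil(a)) + 2
    rlo, rhi = max(0, int(r0) - pad), min(shape[0], int(r0) + pad + 1)
    clo, chi = max(0, int(c0) - pad), min(shape[1], int(c0) + pad + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    ct, st = math.cos(nuc.theta), math.sin(nuc.theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    mask = np.zeros(shape, dtype=bool)
    mask[rlo:rhi, clo:chi] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _densify(points: np.ndarray, step: float = 0.5) -> np.ndarray:
    out = [points[:1]]
    for i in range(len(points) - 1):
        seg = points[i + 1] - points[i]
        n = max(1, int(math.ceil(np.linalg.norm(seg) / step)))
        t = np.linspace(0, 1, n + 1)[1:, None]
        out.append(points[i] + t * seg)
    return np.vstack(out)


def rasterize_fragment(frag: Fragment, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of a fragment: pixels within width/2 of its skeleton."""
    pts = np.vstack([_densify(p) for p in frag.polylines])
    ij = np.round(pts).astype(int)
    half = frag.width_px / 2.0
    pad = int(math.ceil(half)) + 2
    rlo = max(0, ij[:, 0].min() - pad)
    rhi = min(shape[0], ij[:, 0].max() + pad + 1)
    clo = max(0, ij[:, 1].min() - pad)
    chi = min(shape[1], ij[:, 1].max() + pad + 1)
    if rlo >= rhi or clo >= chi:
        return np.zeros(shape, dtype=bool)
    box = np.zeros((rhi - rlo, chi - clo), dtype=bool)
    keep = (ij[:, 0] >= rlo) & (ij[:, 0] < rhi) & (ij[:, 1] >= clo) & (ij[:, 1] < chi)
    box[ij[keep, 0] - rlo, ij[keep, 1] - clo] = True
    dist = ndi.distance_transform_edt(~box)
    mask = np.zeros(shape, dtype=bool)
    mask[rlo:rhi, clo:chi] = dist <= half
    return mask


def _serpentine_path(a: float, b: float, width: float
                     ) -> tuple[list[tuple[float, float]], float]:
    """Full boustrophedon path over the ellipse (a, b); returns (points, length).

    Strands run parallel to the major (col) axis at one tubule width pitch,
    connected by short joins; every move, including the inward clamps at the
    tapering ends of the ellipse, is counted toward the length.
    """
    ys = np.arange(b - width / 2.0, -b, -width)
    pts: list[tuple[float, float]] = []
    total = 0.0
    pos: tuple[float, float] | None = None
    for y in ys:
        half = a * math.sqrt(max(0.0, 1.0 - (y / b) ** 2))
        if half < width / 2.0:
            continue
        if pos is None:
            pos = (y, -half)
            pts.append(pos)
        else:
            new = (y, pos[1])
            total += abs(y - pos[0])
            pts.append(new)
            pos = new
            x = min(max(pos[1], -half), half)
            if x != pos[1]:
                new = (y, x)
                total += abs(x - pos[1])
                pts.append(new)
                pos = new
        target = half if pos[1] <= 0 else -half
        new = (y, target)
        total += abs(target - pos[1])
        pts.append(new)
        pos = new
    return pts, total


def _truncate_path(pts: list[tuple[float, float]], length: float) -> np.ndarray:
    out = [np.asarray(pts[0], dtype=np.float64)]
    total = 0.0
    for nxt in pts[1:]:
        nxt = np.asarray(nxt, dtype=np.float64)
        seg = float(np.linalg.norm(nxt - out[-1]))
        if seg == 0.0:
            continue
        if total + seg >= length:
            out.append(out[-1] + (length - total) / seg * (nxt - out[-1]))
            total = length
            break
        out.append(nxt)
        total += seg
    return np.vstack(out)


def _serpentine(length: float, aspect: float, width: float,
                rng: np.random.Generator) -> np.ndarray:
    """Serpentine-coiled tubule of exactly ``length`` filling an ellipse.

    The territory semi-minor axis is calibrated so the available path just
    covers the requested length (the residual truncation is a few percent of
    the last strand), giving compact fragments at aspect 1 and elongated
    coils at high aspect. Returns an (N, 2) polyline in local (row, col)
    coordinates centred on the territory.
    """
    aspect = max(aspect, 1.0)
    b = math.sqrt(width * length / (math.pi * aspect))
    total = 0.0
    pts: list[tuple[float, float]] = []
    for _ in range(4):
        pts, total = _serpentine_path(aspect * b, b, width)
        if total <= 0:
            b *= 1.4
            continue
        factor = math.sqrt(length / total)
        if 0.99 <= factor <= 1.02:
            break
        b *= min(1.4, max(0.75, factor))
    if total < length:
        b *= 1.03 * math.sqrt(length / max(total, 1e-9))
        pts, total = _serpentine_path(aspect * b, b, width)
    if total < length or len(pts) < 2:
        # degenerate (length shorter than one strand): render as a straight bar
        return np.array([[0.0, -length / 2.0], [0.0, length / 2.0]])
    poly = _truncate_path(pts, length)
    # small smooth jitter for an organic look (kept well below the width)
    if len(poly) >= 3:
        jitter = rng.normal(0.0, 0.25, size=poly.shape)
        jitter = ndi.uniform_filter1d(jitter, size=3, axis=0)
        jitter[0] = jitter[-1] = 0.0
        poly = poly + jitter
    return poly


def _bend_angle(a: float, amax: float) -> float | None:
    """Half-angle of the arc a territory of semi-length ``a`` must be bent
    through so its chord fits within ``amax``; None when it fits straight.
    Solves sin(α)/α = amax/a on (0, π/2]."""
    if a <= amax:
        return None
    ratio = amax / a
    if ratio <= 2.0 / math.pi:
        return math.pi / 2
    lo, hi = 1e-6, math.pi / 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if math.sin(mid) / mid > ratio:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _wrap(poly: np.ndarray, rho: float) -> np.ndarray:
    """Bend a straight serpentine (strands along the col axis) around a circle
    of radius ``rho`` centred at local (rho, 0); arc length is preserved to
    first order in (strand offset / rho)."""
    r = rho - poly[:, 0]
    phi = poly[:, 1] / rho
    return np.column_stack([rho - r * np.cos(phi), r * np.sin(phi)])


def _rotate_translate(poly: np.ndarray, theta: float,
                      center: tuple[float, float]) -> np.ndarray:
    ct, st = math.cos(theta), math.sin(theta)
    rot = np.array([[ct, -st], [st, ct]])
    return poly @ rot.T + np.asarray(center)


def _split_budget(rng: np.random.Generator, budget: float, n: int,
                  min_length: float) -> np.ndarray:
    lengths = budget * rng.dirichlet(np.full(n, 8.0))
    for _ in range(3):
        lengths = np.maximum(lengths, min_length)
        lengths *= budget / lengths.sum()
    return lengths


# --------------------------------------------------------------------------
# scene construction


def _place_cells(rng: np.random.Generator, params: SceneParams
                 ) -> list[tuple[tuple[float, float], float, np.ndarray]]:
    """Place disjoint cell polygons; returns (center, radius, polygon) triples.

    Sequential rejection sampling with true polygon-gap tests (gap >= 3 px)
    is tried first; crowded fields fall back to a jittered hex layout at the
    lower end of the radius range, with border-clipped cells allowed.
    """
    from shapely.geometry import Polygon as ShPolygon

    h, w = params.image_size_px
    px = params.pixel_size_um
    r_lo, r_hi = (r / px for r in params.cell_radius_um)

    def try_random() -> list | None:
        placed: list[tuple[tuple[float, float], float, np.ndarray]] = []
        shapes: list[ShPolygon] = []
        for _ in range(params.n_cells):
            radius = rng.uniform(r_lo, r_hi)
            for attempt in range(300):
                if attempt and attempt % 100 == 0:
                    radius = max(r_lo, 0.9 * radius)  # crowded field: shrink
                # prefer interior placements; relax toward the border when crowded
                level = min(attempt // 60, 2)
                margin = (1.15 * radius + 4, 0.6 * radius, 0.3 * radius)[level]
                if 2 * margin >= min(h, w):
                    margin = 0.3 * radius
                center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
                poly = _star_polygon(rng, center, radius)
                shape = ShPolygon(poly)
                if all(shape.distance(s) >= 3.0 for s in shapes):
                    placed.append((center, radius, poly))
                    shapes.append(shape)
                    break
            else:
                return None
        return placed

    def try_hex_grid() -> list | None:
        radius = r_lo
        dx = 2.26 * radius + 4
        dy = 0.87 * dx
        inset = 0.3 * radius
        nodes = []
        for i, row in enumerate(np.arange(inset, h - inset + 1e-9, dy)):
            offset = (dx / 2) if i % 2 else 0.0
            for col in np.arange(inset + offset, w - inset + 1e-9, dx):
                nodes.append((float(row), float(col)))
        if len(nodes) < params.n_cells:
            return None
        order = rng.permutation(len(nodes))
        placed: list = []
        shapes: list[ShPolygon] = []
        for k in order:
            if len(placed) == params.n_cells:
                break
            row, col = nodes[k]
            center = (row + rng.uniform(-3, 3), col + rng.uniform(-3, 3))
            poly = _star_polygon(rng, center, radius)
            shape = ShPolygon(poly)
            if all(shape.distance(s) >= 3.0 for s in shapes):
                placed.append((center, radius, poly))
                shapes.append(shape)
        return placed if len(placed) == params.n_cells else None

    placed = try_random()
    if placed is None:
        placed = try_hex_grid()
    if placed is None:
        raise PlacementError(
            f"could not place {params.n_cells} disjoint cells of radius "
            f"{params.cell_radius_um} um in a {h}x{w} field"
        )
    return placed


def _build_fragments(rng: np.random.Generator, params: SceneParams,
                     cell_mask: np.ndarray, nucleus_mask: np.ndarray,
                     center: tuple[float, float], radius: float) -> list[Fragment]:
    px = params.pixel_size_um
    width = params.tubule_width_um / px
    budget = params.skeleton_length_budget_um / px
    f = params.fragmentation
    n_frag = int(math.floor(2 + 38 * f + 0.5))
    lengths = np.sort(_split_budget(rng, budget, n_frag, 3 * width))[::-1]

    # work inside the cell's bounding box; placement cost scales with the
    # cell, not the field
    rows, cols = np.nonzero(cell_mask)
    origin = np.array([max(0, rows.min() - 4), max(0, cols.min() - 4)])
    sl = (slice(origin[0], min(cell_mask.shape[0], rows.max() + 5)),
          slice(origin[1], min(cell_mask.shape[1], cols.max() + 5)))
    cell_mask = cell_mask[sl]
    nucleus_mask = nucleus_mask[sl]
    center = (center[0] - origin[0], center[1] - origin[1])
    shape = cell_mask.shape

    allowed = ndi.binary_erosion(cell_mask, structure=disk(2))
    allowed &= ~ndi.binary_dilation(nucleus_mask, structure=disk(2))
    allowed_idx = np.argwhere(allowed)
    if allowed_idx.size == 0:
        raise PlacementError("cell has no cytoplasmic room for mitochondria")
    blocked = np.zeros(shape, dtype=bool)
    gap_struct = disk(FRAGMENT_GAP_PX)

    aspect0 = 1.0 + (TERRITORY_ASPECT_MAX - 1.0) * (1.0 - f)
    dists = np.linalg.norm(allowed_idx - np.asarray(center), axis=1)
    fragments: list[Fragment] = []
    for length in lengths:
        # territory semi-axes: b from the aspect schedule, capped so structures
        # stay narrower than the measurement top-hat; a follows from the length
        b = min(TERRITORY_SEMI_MINOR_MAX, math.sqrt(width * length / (math.pi * aspect0)))
        a = width * length / (math.pi * b)
        aspect = max(1.0, a / b)
        amax = max(8.0, 0.76 * radius - 3.0)
        placed = None
        for attempt in range(240):
            if attempt and attempt % 30 == 0:
                amax *= 0.85  # could not fit: bend the territory more strongly
            alpha = _bend_angle(a, amax)
            # long territories sit mid-cytoplasm and wrap around the nucleus
            if a > 0.5 * radius:
                band = (dists > 0.40 * radius) & (dists < 0.75 * radius)
                pool = allowed_idx[band] if band.any() else allowed_idx
            else:
                pool = allowed_idx
            anchor = pool[rng.integers(len(pool))]
            radial = math.atan2(anchor[0] - center[0], anchor[1] - center[1])
            spread = math.pi * min(1.0, 1.5 / aspect)
            theta = -(math.pi / 2 + radial) + rng.uniform(-spread, spread)

            if f < 0.999 and rng.random() < params.branch_prob * (1.0 - f):
                # part of the fragment's length budget becomes a side branch
                spur_len = min(0.2 * length, 25.0)
                main = _serpentine(length - spur_len, aspect, width, rng)
                k = int(rng.integers(0, len(main)))
                phi = rng.uniform(0, 2 * np.pi)
                spur = np.array([main[k],
                                 main[k] + spur_len * np.array([math.sin(phi), math.cos(phi)])])
                polylines = [main, spur]
            else:
                polylines = [_serpentine(length, aspect, width, rng)]
            if alpha is not None:
                rho = a / alpha
                polylines = [_wrap(p, rho) for p in polylines]
            cand = Fragment(
                polylines=[_rotate_translate(p, theta, tuple(anchor.astype(float)))
                           for p in polylines],
                width_px=width,
            )
            mask = rasterize_fragment(cand, shape)
            if not mask.any():
                continue
            if np.any(mask & ~allowed) or np.any(mask & blocked):
                continue
            placed = (cand, mask)
            break
        if placed is None:
            raise PlacementError("could not place a mitochondrial fragment inside the cell")
        frag, mask = placed
        fragments.append(frag)
        blocked |= ndi.binary_dilation(mask, structure=gap_struct)
    for frag in fragments:
        frag.polylines = [p + origin for p in frag.polylines]
    return fragments


def make_scene(params: SceneParams) -> SyntheticScene:
    """Generate the ground-truth geometry of one field (deterministic in seed)."""
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_size_px)
    placements = _place_cells(rng, params)

    # geometry is built on a padded canvas so border-clipped cells still carry
    # a full mitochondrial network; rasterizations later crop to the frame,
    # reproducing the truncated networks that border exclusion guards against
    pad = int(math.ceil(params.cell_radius_um[1] / params.pixel_size_um)) + 8
    wshape = (shape[0] + 2 * pad, shape[1] + 2 * pad)

    cells: list[SyntheticCell] = []
    for cid, (center, radius, polygon) in enumerate(placements, start=1):
        a = 0.29 * radius * rng.uniform(0.9, 1.1)
        b = 0.21 * radius * rng.uniform(0.9, 1.1)
        off_r = rng.uniform(-0.1, 0.1) * radius
        off_c = rng.uniform(-0.1, 0.1) * radius
        nucleus = NucleusGeometry(
            center=(center[0] + off_r, center[1] + off_c),
            semi_axes=(max(a, b), min(a, b)),
            theta=rng.uniform(0, math.pi),
        )
        offset = np.array([pad, pad], dtype=np.float64)
        cmask = _polygon_mask(polygon + offset, wshape)
        nucleus_p = NucleusGeometry(
            center=(nucleus.center[0] + pad, nucleus.center[1] + pad),
            semi_axes=nucleus.semi_axes, theta=nucleus.theta)
        nmask = _ellipse_mask(nucleus_p, wshape)
        center_p = (center[0] + pad, center[1] + pad)
        fragments = None
        for retry in range(5):
            try:
                fragments = _build_fragments(rng, params, cmask, nmask, center_p, radius)
                break
            except PlacementError:
                if retry == 4:
                    raise
        for frag in fragments:
            frag.polylines = [p - offset for p in frag.polylines]
        cells.append(SyntheticCell(cell_id=cid, center=center, radius_px=radius,
                                   polygon=polygon, nucleus=nucleus, fragments=fragments))
    return SyntheticScene(params=params, cells=cells)


# --------------------------------------------------------------------------
# ground-truth rasterizations


def cell_label_image(scene: SyntheticScene) -> LabelImage:
    labels = np.zeros(scene.shape, dtype=np.int32)
    for cell in scene.cells:
        labels[_polygon_mask(cell.polygon, scene.shape)] = cell.cell_id
    return LabelImage(labels, kind="cells")


def nucleus_label_image(scene: SyntheticScene) -> LabelImage:
    labels = np.zeros(scene.shape, dtype=np.int32)
    for cell in scene.cells:
        labels[_ellipse_mask(cell.nucleus, scene.shape)] = cell.cell_id
    return LabelImage(labels, kind="nuclei")


def mito_mask(scene: SyntheticScene) -> np.ndarray:
    mask = np.zeros(scene.shape, dtype=bool)
    for cell in scene.cells:
        for frag in cell.fragments:
            mask |= rasterize_fragment(frag, scene.shape)
    return mask


def interior_cell_ids(scene: SyntheticScene) -> list[int]:
    """Cells whose rasterized polygon touches no image border."""
    ids = []
    for cell in scene.cells:
        m = _polygon_mask(cell.polygon, scene.shape)
        if not (m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any()):
            ids.append(cell.cell_id)
    return ids


def ground_truth_morphology(scene: SyntheticScene) -> list[CellMorphology]:
    """Descriptors on the noiseless rasterized fragment masks.

    Uses the same particle operators as the measurement path, so this is
    the recovery target for the full pipeline. Particle count per cell
    equals fragment count by construction (fragments are disjoint).
    """
    out: list[CellMorphology] = []
    for cell in scene.cells:
        particles = []
        for frag in cell.fragments:
            mask = rasterize_fragment(frag, scene.shape)
            if not mask.any():  # fragment lies outside the frame (border cell)
                continue
            rows, cols = np.nonzero(mask)
            sl = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
            particles.append(particle_from_mask(mask[sl], cell_id=cell.cell_id,
                                                offset=(sl[0].start, sl[1].start)))
        if particles:
            out.append(summarize_cell(particles))
    return out


# --------------------------------------------------------------------------
# rendering


def render_scene(scene: SyntheticScene,
                 optics: OpticsNoiseParams = OpticsNoiseParams()) -> MultiChannelImage:
    """Render the three channels through the optics/noise model."""
    shape = scene.shape
    rng = np.random.default_rng(optics.seed)

    nucleus = np.zeros(shape, dtype=np.float64)
    membrane = np.zeros(shape, dtype=np.float64)
    mito = np.zeros(shape, dtype=np.float64)
    band_struct = disk(MEMBRANE_BAND_PX)
    for cell in scene.cells:
        cmask = _polygon_mask(cell.polygon, shape)
        nucleus[_ellipse_mask(cell.nucleus, shape)] = 1.0
        band = cmask & ~ndi.binary_erosion(cmask, structure=band_struct)
        membrane[cmask] = np.maximum(membrane[cmask], CYTOPLASM_LEVEL)
        membrane[band] = 1.0
        brightness = rng.uniform(0.6, 1.0)  # per-cell staining efficiency
        for frag in cell.fragments:
            mito[rasterize_fragment(frag, shape)] = brightness

    planes = {}
    for role, plane in (("nucleus", nucleus), ("membrane", membrane), ("mito", mito)):
        img = gaussian(plane, sigma=optics.psf_sigma_px, preserve_range=True) \
            if optics.psf_sigma_px > 0 else plane
        counts = img * optics.photon_scale
        if optics.apply_shot_noise and optics.photon_scale > 0:
            counts = rng.poisson(counts).astype(np.float64)
        if optics.gaussian_read_sd > 0:
            counts = counts + rng.normal(0.0, optics.gaussian_read_sd, size=shape)
        counts = counts + optics.background_offset
        planes[role] = np.clip(counts, 0.0, None)
    return MultiChannelImage(planes=planes, pixel_size_um=scene.params.pixel_size_um,
                             source_path=f"synthetic(seed={scene.params.seed})")


# --------------------------------------------------------------------------
# serialization


def scene_to_dict(scene: SyntheticScene) -> dict:
    return {
        "params": asdict(scene.params),
        "cells": [
            {
                "cell_id": c.cell_id,
                "center": list(c.center),
                "radius_px": c.radius_px,
                "polygon": c.polygon.tolist(),
                "nucleus": {
                    "center": list(c.nucleus.center),
                    "semi_axes": list(c.nucleus.semi_axes),
                    "theta": c.nucleus.theta,
                },
                "fragments": [
                    {"width_px": f.width_px,
                     "polylines": [p.tolist() for p in f.polylines]}
                    for f in c.fragments
                ],
            }
            for c in scene.cells
        ],
    }


def scene_from_dict(data: dict) -> SyntheticScene:
    p = dict(data["params"])
    p["image_size_px"] = tuple(p["image_size_px"])
    p["cell_radius_um"] = tuple(p["cell_radius_um"])
    params = SceneParams(**p)
    cells = []
    for c in data["cells"]:
        nucleus = NucleusGeometry(
            center=tuple(c["nucleus"]["center"]),
            semi_axes=tuple(c["nucleus"]["semi_axes"]),
            theta=c["nucleus"]["theta"],
        )
        fragments = [
            Fragment(polylines=[np.asarray(p_, dtype=np.float64) for p_ in f["polylines"]],
                     width_px=f["width_px"])
            for f in c["fragments"]
        ]
        cells.append(SyntheticCell(
            cell_id=c["cell_id"], center=tuple(c["center"]), radius_px=c["radius_px"],
            polygon=np.asarray(c["polygon"], dtype=np.float64),
            nucleus=nucleus, fragments=fragments,
        ))
    return SyntheticScene(params=params, cells=cells)


def save_scene(scene: SyntheticScene, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(scene_to_dict(scene)))
    return path


def load_scene(path: str | Path) -> SyntheticScene:
    return scene_from_dict(json.loads(Path(path).read_text()))
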
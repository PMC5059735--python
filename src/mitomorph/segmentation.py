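"""Per-cell segmentation from the nucleus and membrane channels.

Nuclei: Gaussian smoothing → Otsu threshold → hole filling → area filter →
distance-transform watershed seeded at h-maxima (splits touching nuclei).

Cells: seeded watershed on the smoothed membrane channel used as an
elevation map — membrane-bright ridges become basin boundaries — with the
nuclei as seeds, restricted to a foreground support obtained by Otsu
thresholding the smoothed membrane+mito composite (so mitochondria-bearing
cytoplasm always lies inside some cell). One cell region per retained
nucleus; regions are disjoint and contain their seed.

All thresholds are global per image; the model assumes fairly uniform
illumination, so no flat-field correction stage exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from ._exceptions import MissingChannelError
from .image_io import LabelImage, MultiChannelImage


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the two-stage (nuclei → cells) segmentation.

    nucleus_smooth_sigma_px : Gaussian sigma applied to the nucleus plane
        (and to the membrane/composite planes) before thresholding.
    nucleus_min_area_px : nuclei smaller than this are discarded as debris.
    split_h_maxima_depth : depth h of the h-maxima transform on the distance
        map; controls how aggressively touching nuclei are split.
    cell_min_area_px : cells smaller than this are removed by filter_cells.
    border_policy : 'exclude' removes cells touching the image border
        (truncated mitochondrial networks would bias the descriptors);
        'keep' retains them.
    """

    nucleus_smooth_sigma_px: float = 2.0
    nucleus_min_area_px: int = 200
    split_h_maxima_depth: float = 2.0
    cell_min_area_px: int = 2000
    border_policy: str = "exclude"

    def __post_init__(self) -> None:
        if self.nucleus_smooth_sigma_px < 0:
            raise ValueError("nucleus_smooth_sigma_px must be >= 0")
        if self.nucleus_min_area_px <= 0 or self.cell_min_area_px <= 0:
            raise ValueError("area thresholds must be > 0")
        if self.split_h_maxima_depth <= 0:
            raise ValueError("split_h_maxima_depth must be > 0")
        if self.border_policy not in ("exclude", "keep"):
            raise ValueError("border_policy must be 'exclude' or 'keep'")


def _smooth(plane: np.ndarray, sigma: float) -> np.ndarray:
    plane = np.asarray(plane, dtype=np.float64)
    return gaussian(plane, sigma=sigma, preserve_range=True) if sigma > 0 else plane


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Zero out labeled regions smaller than ``min_area`` (labels preserved)."""
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    small = small[small > 0]
    if small.size:
        labels = labels.copy()
        labels[np.isin(labels, small)] = 0
    return labels


def segment_nuclei(img: MultiChannelImage,
                   params: SegmentationParams = SegmentationParams()) -> LabelImage:
    """Label nuclei in the nucleus channel.

    Returns an empty label image for a blank (constant) plane. Touching
    nuclei are split by a watershed on the distance transform seeded at
    h-maxima of depth ``split_h_maxima_depth``.
    """
    if "nucleus" not in img.planes:
        raise MissingChannelError("automatic segmentation needs a nucleus channel")
    plane = _smooth(img.plane("nucleus"), params.nucleus_smooth_sigma_px)
    if np.ptp(plane) == 0:
        return LabelImage(np.zeros(plane.shape, dtype=np.int32), kind="nuclei")
    binary = plane > threshold_otsu(plane)
    binary = ndi.binary_fill_holes(binary)
    binary = _drop_small(binary.astype(np.int32), params.nucleus_min_area_px) > 0
    if not binary.any():
        return LabelImage(np.zeros(plane.shape, dtype=np.int32), kind="nuclei")

    distance = ndi.distance_transform_edt(binary)
    # smooth the distance map so boundary wobble cannot spawn spurious maxima
    distance = ndi.gaussian_filter(distance, sigma=2.0)
    peaks = h_maxima(distance, params.split_h_maxima_depth)
    markers, n_markers = ndi.label(peaks)
    if n_markers == 0:  # degenerate: fall back to plain components
        labels, _ = ndi.label(binary)
    else:
        labels = watershed(-distance, markers=markers, mask=binary)
    labels = _drop_small(labels, params.nucleus_min_area_px)
    return LabelImage(labels.astype(np.int32), kind="nuclei")


def segment_cells(img: MultiChannelImage, nuclei: LabelImage,
                  params: SegmentationParams = SegmentationParams()) -> LabelImage:
    """Partition the foreground into one region per nucleus.

    Elevation = smoothed membrane plane (bright cell-boundary ridges are the
    watershed lines). Support = Otsu threshold on the smoothed membrane+mito
    composite, union the nuclei (a constant composite means everything is
    foreground). With zero nuclei an empty label map is returned with a
    warning.
    """
    if nuclei.n_labels == 0:
        warnings.warn("no nuclei to seed cell segmentation; returning empty cell map",
                      stacklevel=2)
        return LabelImage(np.zeros(img.shape, dtype=np.int32), kind="cells")

    membrane = img.plane("membrane")
    mito = img.plane("mito")
    sigma = params.nucleus_smooth_sigma_px
    elevation = _smooth(membrane, sigma)
    composite = _smooth(membrane + mito, sigma)
    if np.ptp(composite) == 0:
        support = np.ones(img.shape, dtype=bool)
    else:
        support = composite > threshold_otsu(composite)
        support = ndi.binary_fill_holes(support)
    support |= nuclei.labels > 0

    labels = watershed(elevation, markers=nuclei.labels, mask=support)
    return LabelImage(labels.astype(np.int32), kind="cells")


def filter_cells(cells: LabelImage,
                 params: SegmentationParams = SegmentationParams(),
                 image_shape: tuple[int, int] | None = None) -> LabelImage:
    """Drop cells below ``cell_min_area_px`` and, under the 'exclude' border
    policy, cells with any pixel on the image border. Surviving labels keep
    their values (no renumbering), so ids stay traceable across stages.
    """
    labels = cells.labels.copy()
    shape = image_shape or labels.shape
    if shape != labels.shape:
        raise ValueError("image_shape does not match the label map")

    drop: set[int] = set()
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    drop.update(int(i) for i, c in zip(ids, counts) if c < params.cell_min_area_px)
    if params.border_policy == "exclude":
        border = np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        drop.update(int(i) for i in np.unique(border) if i > 0)
    if drop:
        labels[np.isin(labels, list(drop))] = 0
    return LabelImage(labels, kind="cells")


def segment(img: MultiChannelImage,
            params: SegmentationParams = SegmentationParams()) -> LabelImage:
    """Full automatic protocol: nuclei → cells → size/border filtering."""
    nuclei = segment_nuclei(img, params)
    cells = segment_cells(img, nuclei, params)
    return filter_cells(cells, params)
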
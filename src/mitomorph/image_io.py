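"""Raster and tabular I/O.

Images travel as plain multi-plane TIFF; the binding of planes to the three
semantic channel roles (``nucleus``, ``membrane``, ``mito``) is supplied
explicitly by a channel map — never inferred from metadata — so that a run is
fully determined by its config. Label masks (nuclei / cells / particles) are
single-plane integer TIFFs with 0 meaning background. All tabular output is
CSV with a fixed, documented column order and floats printed at six
significant digits.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from ._exceptions import (
    ConsistencyError,
    DuplicateRoleError,
    MissingChannelError,
    MissingFileError,
    NonIntegerMaskError,
    PlaneIndexError,
    SchemaError,
)

CHANNEL_ROLES = ("nucleus", "membrane", "mito")

#: fixed column orders for the three output tables
PARTICLE_COLUMNS = [
    "image", "condition", "cell_id", "particle_id", "area_px", "perimeter_px",
    "major_axis_px", "minor_axis_px", "circularity", "aspect_ratio",
    "centroid_row", "centroid_col",
]
CELL_COLUMNS = [
    "image", "condition", "cell_id", "n_particles",
    "mean_circularity", "mean_aspect_ratio", "total_mito_area_px",
]
CONDITION_COLUMNS = [
    "condition", "n_cells",
    "circularity_mean", "circularity_sd",
    "aspect_ratio_mean", "aspect_ratio_sd",
]

FLOAT_FORMAT = "%.6g"


@dataclass
class MultiChannelImage:
    """Registered 2-D intensity planes keyed by channel role.

    Parameters
    ----------
    planes
        Mapping from role (``nucleus`` / ``membrane`` / ``mito``) to a 2-D
        non-negative float array. All planes must share one shape.
    pixel_size_um
        Physical pixel edge length in micrometers. Affects only
        µm-denominated outputs; the shape descriptors are dimensionless.
    source_path
        Provenance string (file the planes were read from, or a synthetic tag).
    """

    planes: dict[str, np.ndarray]
    pixel_size_um: float = 0.2
    source_path: str = ""

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) > 1:
            raise ValueError(f"planes differ in shape: {sorted(shapes)}")
        for role, plane in self.planes.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if plane.ndim != 2:
                raise ValueError(f"plane {role!r} is not 2-D")
            if not np.all(np.isfinite(plane)) or np.any(plane < 0):
                raise ValueError(f"plane {role!r} has non-finite or negative intensities")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def plane(self, role: str) -> np.ndarray:
        try:
            return self.planes[role]
        except KeyError:
            raise MissingChannelError(f"image has no {role!r} channel") from None


@dataclass
class LabelImage:
    """Integer-labeled segmentation map; label 0 is background.

    Labels are not required to be contiguous (filtering preserves surviving
    label values).
    """

    labels: np.ndarray
    kind: str = "cells"  # one of {nuclei, cells, particles}

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label image must have an integer dtype")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.kind not in ("nuclei", "cells", "particles"):
            raise ValueError(f"unknown label kind {self.kind!r}")

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero label values present in the map."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    @property
    def n_labels(self) -> int:
        return int(self.ids.size)


def load_stack(
    path: str | os.PathLike,
    channel_map: Mapping[str, int],
    pixel_size_um: float = 0.2,
) -> MultiChannelImage:
    """Read a multi-plane TIFF and bind planes to channel roles.

    ``channel_map`` maps role names to 0-based plane indices; indices must be
    distinct and within the plane count. Pixel size comes from the caller
    (config); TIFF metadata is deliberately ignored.
    """
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(f"no such image file: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {data.shape}")

    indices = list(channel_map.values())
    if len(set(indices)) != len(indices):
        raise DuplicateRoleError(f"channel map assigns one plane to several roles: {dict(channel_map)}")
    planes: dict[str, np.ndarray] = {}
    for role, idx in channel_map.items():
        if role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {role!r} in channel map")
        if not 0 <= int(idx) < data.shape[0]:
            raise PlaneIndexError(
                f"channel map requests plane {idx} for role {role!r} "
                f"but file has {data.shape[0]} plane(s)"
            )
        planes[role] = np.asarray(data[int(idx)], dtype=np.float64)
    return MultiChannelImage(planes=planes, pixel_size_um=pixel_size_um, source_path=str(path))


def write_stack(image: MultiChannelImage, path: str | os.PathLike,
                order: Sequence[str] = CHANNEL_ROLES) -> Path:
    """Write the image's planes as a multi-plane uint16 TIFF in ``order``."""
    path = Path(path)
    stack = []
    for role in order:
        plane = image.plane(role)
        stack.append(np.clip(np.rint(plane), 0, 65535).astype(np.uint16))
    tifffile.imwrite(path, np.stack(stack, axis=0), photometric="minisblack")
    return path


def load_label_mask(path: str | os.PathLike, kind: str = "cells") -> LabelImage:
    """Read a single-plane integer TIFF as a label image.

    Float-valued files are rejected unless every value is integral. An
    all-zero mask is legal (a field with no usable cells) but warned about.
    """
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(f"no such mask file: {path}")
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"label mask must be a single 2-D plane, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.isfinite(data)) or np.any(data != np.rint(data)):
            raise NonIntegerMaskError(f"mask {path} contains non-integer pixel values")
        data = np.rint(data)
    labels = data.astype(np.int32)
    if labels.min() < 0:
        raise NonIntegerMaskError(f"mask {path} contains negative labels")
    if labels.max() == 0:
        warnings.warn(f"label mask {path} is all background (0 cells)", stacklevel=2)
    return LabelImage(labels=labels, kind=kind)


def write_label_mask(label: LabelImage, path: str | os.PathLike) -> Path:
    """Write a label image as uint16 TIFF (lossless for < 65536 labels)."""
    path = Path(path)
    if label.labels.max() > 65535:
        raise ValueError("too many labels for uint16 TIFF")
    tifffile.imwrite(path, label.labels.astype(np.uint16))
    return path


def _as_dataframe(records: Iterable, columns: list[str]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in columns if c not in records.columns]
        if missing:
            raise SchemaError(f"table is missing columns {missing}; expected {columns}")
        return records.loc[:, columns]
    return pd.DataFrame(list(records), columns=columns)


def write_tables(
    particles: pd.DataFrame | Iterable[Mapping],
    cells: pd.DataFrame | Iterable[Mapping],
    summaries: pd.DataFrame | Iterable[Mapping],
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write the per-particle, per-cell and per-condition CSVs.

    Referential integrity is checked: every particle's (image, cell_id) must
    exist among the cell records. Empty inputs yield header-only files.
    Returns the three output paths keyed by table name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pdf = _as_dataframe(particles, PARTICLE_COLUMNS)
    cdf = _as_dataframe(cells, CELL_COLUMNS)
    sdf = _as_dataframe(summaries, CONDITION_COLUMNS)

    if len(pdf):
        cell_keys = set(zip(cdf["image"], cdf["cell_id"]))
        particle_keys = set(zip(pdf["image"], pdf["cell_id"]))
        orphans = particle_keys - cell_keys
        if orphans:
            raise ConsistencyError(f"particles reference unknown cells: {sorted(orphans)[:5]}")

    paths = {
        "particles": out_dir / "particles.csv",
        "cells": out_dir / "cells.csv",
        "conditions": out_dir / "conditions.csv",
    }
    pdf.to_csv(paths["particles"], index=False, float_format=FLOAT_FORMAT)
    cdf.to_csv(paths["cells"], index=False, float_format=FLOAT_FORMAT)
    sdf.to_csv(paths["conditions"], index=False, float_format=FLOAT_FORMAT)
    return paths
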
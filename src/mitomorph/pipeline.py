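"""Orchestration: image → cells → particles → per-cell and per-condition tables.

Two protocols are supported, mirroring how such measurements are made in
practice:

* **automatic** — cells are segmented from the nucleus and membrane channels
  (seeded watershed), then the mitochondrial channel is binarized per cell
  and particle-analyzed;
* **semimanual** — a user-supplied cell-label mask replaces the segmentation
  stage; binarization and particle analysis are identical.

Both paths produce the same tables, so their condition-level agreement on
the same images is a direct consistency check of the automatic masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .image_io import (
    CELL_COLUMNS,
    CONDITION_COLUMNS,
    PARTICLE_COLUMNS,
    LabelImage,
    MultiChannelImage,
)
from .morphology import CellMorphology, MitoParticle, binarize_mito, extract_particles, summarize_cells
from .segmentation import filter_cells, segment_cells, segment_nuclei
from .stats import ComparisonResult, dose_response_table, summarize_condition

MODES = ("automatic", "semimanual")


@dataclass
class FieldResult:
    """Everything measured on one field (image)."""

    image: str
    condition: str
    cells: LabelImage
    mito_mask: np.ndarray
    particles: list[MitoParticle]
    cell_morphologies: list[CellMorphology]


def analyze_field(
    img: MultiChannelImage,
    config: AnalysisConfig = AnalysisConfig(),
    mode: str = "automatic",
    cell_mask: LabelImage | None = None,
    condition: str = "",
) -> FieldResult:
    """Run one field through segmentation (or mask loading) and morphology."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "automatic":
        nuclei = segment_nuclei(img, config.segmentation)
        cells = segment_cells(img, nuclei, config.segmentation)
        cells = filter_cells(cells, config.segmentation)
    else:
        if cell_mask is None:
            raise ValueError("semimanual mode needs a cell-label mask")
        cells = filter_cells(cell_mask, config.segmentation)

    mask = binarize_mito(img.plane("mito"), cells, config.morphology)
    particles = extract_particles(mask, cells, config.morphology)
    morphologies = summarize_cells(particles)
    measured = {m.cell_id for m in morphologies}
    empty = [int(i) for i in cells.ids if int(i) not in measured]
    if empty:
        warnings.warn(
            f"{img.source_path or 'image'}: cells {empty} have no particles and are omitted",
            stacklevel=2,
        )
    return FieldResult(
        image=img.source_path,
        condition=condition,
        cells=cells,
        mito_mask=mask,
        particles=particles,
        cell_morphologies=morphologies,
    )


@dataclass
class BatchResult:
    """Accumulated tables over a set of fields grouped by condition."""

    fields: list[FieldResult] = field(default_factory=list)

    def add(self, result: FieldResult) -> None:
        self.fields.append(result)

    # -- tables ------------------------------------------------------------

    def particle_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.fields:
            for i, p in enumerate(fr.particles, start=1):
                rows.append({
                    "image": fr.image, "condition": fr.condition,
                    "cell_id": p.cell_id, "particle_id": i,
                    "area_px": p.area_px, "perimeter_px": p.perimeter_px,
                    "major_axis_px": p.major_axis_px, "minor_axis_px": p.minor_axis_px,
                    "circularity": p.circularity, "aspect_ratio": p.aspect_ratio,
                    "centroid_row": p.centroid[0], "centroid_col": p.centroid[1],
                })
        return pd.DataFrame(rows, columns=PARTICLE_COLUMNS)

    def cell_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.fields:
            for m in fr.cell_morphologies:
                rows.append({
                    "image": fr.image, "condition": fr.condition, "cell_id": m.cell_id,
                    "n_particles": m.n_particles,
                    "mean_circularity": m.mean_circularity,
                    "mean_aspect_ratio": m.mean_aspect_ratio,
                    "total_mito_area_px": m.total_mito_area_px,
                })
        return pd.DataFrame(rows, columns=CELL_COLUMNS)

    def cells_by_condition(self) -> dict[str, list[CellMorphology]]:
        out: dict[str, list[CellMorphology]] = {}
        for fr in self.fields:
            out.setdefault(fr.condition, []).extend(fr.cell_morphologies)
        return out

    def condition_table(self) -> pd.DataFrame:
        rows = []
        for label, cells in self.cells_by_condition().items():
            if not cells:
                continue
            s = summarize_condition(cells, label)
            rows.append({
                "condition": s.condition, "n_cells": s.n_cells,
                "circularity_mean": s.circularity_mean, "circularity_sd": s.circularity_sd,
                "aspect_ratio_mean": s.aspect_ratio_mean, "aspect_ratio_sd": s.aspect_ratio_sd,
            })
        return pd.DataFrame(rows, columns=CONDITION_COLUMNS)

    def comparisons(self, config: AnalysisConfig = AnalysisConfig()
                    ) -> list[ComparisonResult]:
        """Every condition after the first (in batch order) vs the first."""
        grouped = [(label, cells) for label, cells in self.cells_by_condition().items()]
        if len(grouped) < 2:
            return []
        return dose_response_table(grouped, test=config.stats.test,
                                   thresholds=config.stats.star_thresholds)


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "descriptor": r.descriptor, "group_a": r.group_a, "group_b": r.group_b,
            "n_a": r.n_a, "n_b": r.n_b, "t_stat": r.t_stat,
            "p_value": r.p_value, "stars": r.stars,
        } for r in results],
        columns=["descriptor", "group_a", "group_b", "n_a", "n_b",
                 "t_stat", "p_value", "stars"],
    )
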
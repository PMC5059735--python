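"""Reusable in-silico experiment drivers.

These compose the synthetic generator with the measurement pipeline into
the standard validation experiments: measuring a fragmentation condition
over a set of independently seeded fields, sweeping the fragmentation axis,
and the two-condition control-vs-fragmented comparison with Welch t-tests
on per-cell descriptor means.

One field per seed carries a single cell, so a condition with ``n`` seeds
contributes up to ``n`` cells (a cell can drop out if segmentation or
binarization fails on that field — the counts are reported, not hidden).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .morphology import CellMorphology
from .pipeline import analyze_field
from .stats import ComparisonResult, compare
from .synthetic import (
    OpticsNoiseParams,
    SceneParams,
    cell_label_image,
    ground_truth_morphology,
    make_scene,
    render_scene,
)


@dataclass
class ConditionMeasurement:
    """Per-cell morphologies of one condition via up to three routes."""

    fragmentation: float
    ground_truth: list[CellMorphology] = field(default_factory=list)
    automatic: list[CellMorphology] = field(default_factory=list)
    semimanual: list[CellMorphology] = field(default_factory=list)

    def mean(self, route: str, descriptor: str) -> float:
        cells = getattr(self, route)
        return float(np.mean([getattr(c, descriptor) for c in cells]))


def measure_condition(
    fragmentation: float,
    seeds: list[int],
    config: AnalysisConfig | None = None,
    include_semimanual: bool = False,
    scene_kwargs: dict | None = None,
    on_placement_error: str = "raise",
) -> ConditionMeasurement:
    """Generate, render and measure one single-cell field per seed.

    Scene and optics parameters are the generator defaults (single cell per
    field) unless overridden via ``scene_kwargs``; the geometry and optics
    of field *i* both derive from ``seeds[i]``. With
    ``on_placement_error="skip"`` a field whose geometry cannot be packed is
    dropped (shrinking the reported n) instead of aborting the experiment.
    """
    from ._exceptions import PlacementError

    cfg = config or AnalysisConfig()
    out = ConditionMeasurement(fragmentation=fragmentation)
    kwargs = {"n_cells": 1, **(scene_kwargs or {})}
    for seed in seeds:
        try:
            scene = make_scene(SceneParams(fragmentation=fragmentation, seed=seed, **kwargs))
        except PlacementError:
            if on_placement_error == "skip":
                continue
            raise
        out.ground_truth.extend(ground_truth_morphology(scene))
        img = render_scene(scene, OpticsNoiseParams(seed=seed))
        auto = analyze_field(img, cfg, mode="automatic", condition=f"f={fragmentation}")
        out.automatic.extend(auto.cell_morphologies)
        if include_semimanual:
            semi = analyze_field(img, cfg, mode="semimanual",
                                 cell_mask=cell_label_image(scene),
                                 condition=f"f={fragmentation}")
            out.semimanual.extend(semi.cell_morphologies)
    return out


def fragmentation_sweep(
    fragmentations: list[float],
    cells_per_condition: int = 30,
    base_seed: int = 0,
    config: AnalysisConfig | None = None,
) -> dict[float, ConditionMeasurement]:
    """Measure several fragmentation conditions with disjoint seed blocks."""
    out: dict[float, ConditionMeasurement] = {}
    for i, f in enumerate(fragmentations):
        seeds = [base_seed + 100 * (i + 1) + k for k in range(cells_per_condition)]
        out[f] = measure_condition(f, seeds, config=config)
    return out


def two_condition_experiment(
    control_f: float = 0.15,
    fragmented_f: float = 0.75,
    cells_per_condition: int = 30,
    base_seed: int = 0,
    config: AnalysisConfig | None = None,
    include_semimanual: bool = False,
    on_placement_error: str = "raise",
) -> tuple[ConditionMeasurement, ConditionMeasurement]:
    """Control-vs-fragmented experiment, 30 cells per condition by default.

    Geometry/optics seeds are ``base_seed + 1 .. +n`` for the control and
    ``base_seed + n+1 .. +2n`` for the fragmented condition.
    """
    n = cells_per_condition
    control = measure_condition(control_f, [base_seed + k for k in range(1, n + 1)],
                                config=config, include_semimanual=include_semimanual,
                                on_placement_error=on_placement_error)
    fragmented = measure_condition(fragmented_f,
                                   [base_seed + k for k in range(n + 1, 2 * n + 1)],
                                   config=config, include_semimanual=include_semimanual,
                                   on_placement_error=on_placement_error)
    return control, fragmented


def descriptor_significance(
    control: ConditionMeasurement,
    fragmented: ConditionMeasurement,
    route: str = "automatic",
) -> dict[str, ComparisonResult]:
    """Welch two-sided t-tests on both per-cell descriptors between conditions."""
    a = getattr(control, route)
    b = getattr(fragmented, route)
    return {
        d: compare(a, b, d, label_a="control", label_b="fragmented")
        for d in ("mean_circularity", "mean_aspect_ratio")
    }
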
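"""Condition-level statistics on per-cell morphology.

The unit of analysis is the cell: per-cell descriptor means are aggregated
into condition means ± sample SD, and conditions are compared with a
two-sided Welch (unequal-variance) t-test by default — Student's pooled
test can be selected in the config. Significance stars follow the usual
thresholds 0.05 / 0.01 / 0.001. No multiple-testing correction is applied:
each comparison against the control is reported on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from ._exceptions import EmptyInputError, GroupTooSmallError
from .morphology import CellMorphology

DESCRIPTORS = ("mean_circularity", "mean_aspect_ratio")
STAR_THRESHOLDS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class ConditionSummary:
    """Mean ± SD of each descriptor over a condition's cells."""

    condition: str
    n_cells: int
    circularity_mean: float
    circularity_sd: float  # NaN when n_cells < 2
    aspect_ratio_mean: float
    aspect_ratio_sd: float


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group test on one descriptor."""

    descriptor: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t_stat: float
    p_value: float
    stars: str


def stars_for(p: float, thresholds: Sequence[float] = STAR_THRESHOLDS) -> str:
    """Map a p-value to {'ns', '*', '**', '***'} under the given thresholds."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    lo, mid, hi = thresholds
    if p < hi:
        return "***"
    if p < mid:
        return "**"
    if p < lo:
        return "*"
    return "ns"


def _values(cells: Sequence[CellMorphology], descriptor: str) -> np.ndarray:
    if descriptor not in DESCRIPTORS:
        raise ValueError(f"unknown descriptor {descriptor!r}; expected one of {DESCRIPTORS}")
    return np.array([getattr(c, descriptor) for c in cells], dtype=np.float64)


def summarize_condition(cells: Sequence[CellMorphology], label: str) -> ConditionSummary:
    """Unweighted mean and sample SD (n−1 denominator) over cells.

    With a single cell the SD is undefined and reported as NaN.
    """
    if len(cells) == 0:
        raise EmptyInputError(f"condition {label!r} has no cells")
    circ = _values(cells, "mean_circularity")
    ar = _values(cells, "mean_aspect_ratio")
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) >= 2 else math.nan
    return ConditionSummary(
        condition=label,
        n_cells=len(cells),
        circularity_mean=float(circ.mean()),
        circularity_sd=sd(circ),
        aspect_ratio_mean=float(ar.mean()),
        aspect_ratio_sd=sd(ar),
    )


def compare(
    group_a: Sequence[CellMorphology],
    group_b: Sequence[CellMorphology],
    descriptor: str,
    label_a: str = "A",
    label_b: str = "B",
    test: str = "welch",
    thresholds: Sequence[float] = STAR_THRESHOLDS,
) -> ComparisonResult:
    """Two-sided t-test on per-cell descriptor values.

    ``test`` is 'welch' (default, unequal variances) or 'student'. Each
    group needs at least two cells. Identical groups give t = 0, p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise GroupTooSmallError("each group needs at least 2 cells for a t-test")
    a = _values(group_a, descriptor)
    b = _values(group_b, descriptor)
    if np.array_equal(a, b) and np.ptp(a) == 0:
        # both groups constant and equal: define t=0, p=1 rather than NaN
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=(test == "student"))
        if math.isnan(p):
            t_stat, p = 0.0, 1.0
    return ComparisonResult(
        descriptor=descriptor,
        group_a=label_a,
        group_b=label_b,
        n_a=len(a),
        n_b=len(b),
        t_stat=float(t_stat),
        p_value=float(p),
        stars=stars_for(float(p), thresholds),
    )


def dose_response_table(
    conditions: Sequence[tuple[str, Sequence[CellMorphology]]],
    test: str = "welch",
    thresholds: Sequence[float] = STAR_THRESHOLDS,
) -> list[ComparisonResult]:
    """Compare every non-control condition against the first (control).

    ``conditions`` is an ordered list of (label, cells); the first entry is
    the control. Returns one ComparisonResult per non-control condition per
    descriptor, in dose order.
    """
    if len(conditions) < 2:
        raise EmptyInputError("need a control plus at least one other condition")
    control_label, control_cells = conditions[0]
    results: list[ComparisonResult] = []
    for label, cells in conditions[1:]:
        for descriptor in DESCRIPTORS:
            results.append(compare(control_cells, cells, descriptor,
                                   label_a=control_label, label_b=label,
                                   test=test, thresholds=thresholds))
    return results
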
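"""Map library retention times onto current column conditions.

A recent single-injection DIA run provides (library RT, observed RT) anchor
pairs; a robust affine fit (median of pairwise slopes, i.e. Theil-Sen)
absorbs gradient drift while shrugging off gross outliers from misassigned
peaks. With too few anchors the map falls back to identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .ranking import Candidate

__all__ = ["RTAnchor", "RTMap", "fit_rt_map", "apply_rt_map", "anchors_from_observed"]


@dataclass(frozen=True)
class RTAnchor:
    """One peptide seen in both the library and the recent DIA run."""

    bare_sequence: str
    charge: int
    library_rt: float
    observed_rt: float

    def __post_init__(self) -> None:
        if self.library_rt < 0 or self.observed_rt < 0:
            raise ValidationError("anchor retention times must be >= 0")


@dataclass(frozen=True)
class RTMap:
    """Affine (or identity fallback) map from library RT to observed RT."""

    kind: str  # "identity" | "affine"
    slope: float = 1.0
    intercept: float = 0.0
    n_anchors: int = 0
    residual_mad: float = 0.0


IDENTITY_MAP = RTMap(kind="identity", slope=1.0, intercept=0.0)


def fit_rt_map(anchors: list[RTAnchor], min_anchors: int = 10) -> RTMap:
    """Robust affine fit of observed RT on library RT.

    Uses the median-of-pairwise-slopes estimator with intercept
    ``median(observed - slope * library)``. Falls back to the identity map
    (with a warning) when there are fewer than ``min_anchors`` anchors or
    the fitted slope is non-positive.
    """
    n = len(anchors)
    if n < min_anchors:
        warnings.warn(
            f"only {n} RT anchors (< {min_anchors}); using identity RT map"
        )
        return RTMap(kind="identity", n_anchors=n)

    x = np.array([a.library_rt for a in anchors], dtype=float)
    y = np.array([a.observed_rt for a in anchors], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("RT anchors contain non-finite values")

    slope, _, _, _ = stats.theilslopes(y, x)
    # theilslopes' intercept is median(y) - slope*median(x); the median
    # residual is the more outlier-resistant companion estimator.
    intercept = float(np.median(y - slope * x))
    if not (math.isfinite(slope) and slope > 0):
        warnings.warn(
            f"degenerate RT fit (slope {slope}); using identity RT map"
        )
        return RTMap(kind="identity", n_anchors=n)

    residuals = y - (slope * x + intercept)
    mad = float(np.median(np.abs(residuals)))
    return RTMap(
        kind="affine",
        slope=float(slope),
        intercept=float(intercept),
        n_anchors=n,
        residual_mad=mad,
    )


def apply_rt_map(rt_map: RTMap, library_rt: float) -> float:
    """Map a library RT into current-run minutes, floored at 0."""
    if library_rt < 0:
        raise ValidationError(f"library_rt must be >= 0, got {library_rt}")
    return max(0.0, rt_map.slope * library_rt + rt_map.intercept)


def anchors_from_observed(
    candidates: list[Candidate],
    observed: pd.DataFrame,
    top_n: int = 200,
) -> list[RTAnchor]:
    """Build anchors by matching the top-N candidates by score against an
    observed-RT table (de-duplicated on sequence and charge)."""
    lookup: dict[tuple[str, int], float] = {}
    for row in observed.itertuples(index=False):
        lookup[(str(row.ModifiedSequence), int(row.PrecursorCharge))] = float(
            row.ObservedRT
        )
    ranked = sorted(candidates, key=lambda c: -c.score)
    anchors = []
    seen = set()
    for cand in ranked:
        key = (cand.entry.modified_sequence, cand.entry.precursor_charge)
        if key in seen:
            continue
        seen.add(key)
        if key in lookup:
            anchors.append(
                RTAnchor(
                    bare_sequence=cand.entry.bare_sequence,
                    charge=cand.entry.precursor_charge,
                    library_rt=cand.entry.retention_time,
                    observed_rt=lookup[key],
                )
            )
        if len(anchors) >= top_n:
            break
    return anchors
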
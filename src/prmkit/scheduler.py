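"""Greedy density-constrained retention-time scheduling.

Candidates are visited in rank order (most abundant first, forced peptides
ahead of everything). A candidate is scheduled iff (i) at least one of its
credited target proteins is still below the per-protein cap (forced
candidates bypass the cap) and (ii) adding its retention-time window keeps
the number of concurrent targets at or below the maximum assay density at
every instant. Windows are half-open ``[start, stop)`` so abutting windows
never share an instant; density is checked exactly at interval endpoints,
never on a sampled grid.

Also provides the cycle-time arithmetic: per-scan maximum injection time
budgets and points-across-peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .ranking import Candidate
from .rt_alignment import RTMap, apply_rt_map

__all__ = [
    "ScheduleConfig",
    "ScheduledTarget",
    "Schedule",
    "make_window",
    "build_schedule",
    "density_profile",
    "max_injection_time",
    "points_per_peak",
    "tier_assay",
]

REJECT_DENSITY = "density"
REJECT_PROTEIN_CAP = "protein_cap"
REJECT_EXCLUDED = "excluded"
REJECT_INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class ScheduleConfig:
    """Instrument and curation settings for one assay tier."""

    gradient_end: float
    window_width: float = 5.0
    max_density: int = 10
    per_protein_cap: int = 3
    gradient_start: float = 0.0
    cycle_time: float = 2.0
    routing_overhead: float = 5.0
    isolation_width: float = 2.0
    allow_any_cap: bool = False

    def __post_init__(self) -> None:
        if not self.window_width > 0:
            raise ValidationError("window_width must be > 0")
        if self.max_density < 1:
            raise ValidationError("max_density must be >= 1")
        if not self.gradient_start < self.gradient_end:
            raise ValidationError("gradient_start must be < gradient_end")
        if self.per_protein_cap < 1:
            raise ValidationError("per_protein_cap must be >= 1")
        if not self.allow_any_cap and not 3 <= self.per_protein_cap <= 5:
            raise ValidationError(
                f"per_protein_cap {self.per_protein_cap} outside the usual "
                "3-5 range; pass allow_any_cap=True to override"
            )


@dataclass(frozen=True)
class ScheduledTarget:
    candidate: Candidate
    window_start: float
    window_stop: float
    isolation_center: float
    aligned_rt: float

    def __post_init__(self) -> None:
        if not self.window_start < self.window_stop:
            raise ValidationError("window_start must be < window_stop")


@dataclass
class Schedule:
    """The scheduled assay plus a rejection reason for every candidate that
    did not make it in."""

    targets: list[ScheduledTarget]
    config: ScheduleConfig
    rejections: dict[Candidate, str] = field(default_factory=dict)
    n_excluded: int = 0


def make_window(
    aligned_rt: float, config: ScheduleConfig
) -> tuple[float, float] | None:
    """Center a scheduling window on the aligned RT, clamped to the gradient
    without re-extension. Returns None when the RT falls off the gradient."""
    if not config.gradient_start <= aligned_rt <= config.gradient_end:
        return None
    half = config.window_width / 2.0
    start = max(config.gradient_start, aligned_rt - half)
    stop = min(config.gradient_end, aligned_rt + half)
    return (start, stop)


def _fits_density(
    starts: np.ndarray, stops: np.ndarray, start: float, stop: float, max_density: int
) -> bool:
    """Exact check that adding [start, stop) keeps concurrency <= max_density.

    Concurrency within the new window is piecewise constant and can only
    change at the starts of overlapping existing windows, so it suffices to
    evaluate at the candidate's start and at each overlapping window start.
    """
    if starts.size == 0:
        return max_density >= 1
    mask = (starts < stop) & (stops > start)
    n_overlap = int(mask.sum())
    if n_overlap + 1 <= max_density:
        return True
    ov_starts = np.sort(starts[mask])
    ov_stops = np.sort(stops[mask])
    probe = np.unique(np.concatenate(([start], np.clip(ov_starts, start, stop))))
    probe = probe[probe < stop]
    active = np.searchsorted(ov_starts, probe, side="right") - np.searchsorted(
        ov_stops, probe, side="right"
    )
    return int(active.max()) + 1 <= max_density


def build_schedule(
    candidates: list[Candidate],
    rt_map: RTMap,
    config: ScheduleConfig,
    n_excluded: int = 0,
) -> Schedule:
    """Run the greedy scheduler over pre-ranked candidates.

    Every candidate is either scheduled or recorded in ``rejections`` with
    one of the reasons {density, protein_cap, ineligible}.
    """
    targets: list[ScheduledTarget] = []
    rejections: dict[Candidate, str] = {}
    protein_counts: dict[str, int] = {}
    starts: list[float] = []
    stops: list[float] = []

    for cand in candidates:
        if not cand.eligible:
            rejections[cand] = REJECT_INELIGIBLE
            continue
        aligned = apply_rt_map(rt_map, cand.entry.retention_time)
        window = make_window(aligned, config)
        if window is None:
            rejections[cand] = REJECT_INELIGIBLE
            continue
        if not cand.forced:
            has_capacity = any(
                protein_counts.get(p, 0) < config.per_protein_cap
                for p in cand.target_proteins
            )
            if not has_capacity:
                rejections[cand] = REJECT_PROTEIN_CAP
                continue
        start, stop = window
        if not _fits_density(
            np.asarray(starts), np.asarray(stops), start, stop, config.max_density
        ):
            rejections[cand] = REJECT_DENSITY
            continue
        targets.append(
            ScheduledTarget(
                candidate=cand,
                window_start=start,
                window_stop=stop,
                isolation_center=cand.entry.precursor_mz,
                aligned_rt=aligned,
            )
        )
        starts.append(start)
        stops.append(stop)
        if not cand.forced:
            for protein in cand.target_proteins:
                protein_counts[protein] = protein_counts.get(protein, 0) + 1

    return Schedule(
        targets=targets,
        config=config,
        rejections=rejections,
        n_excluded=n_excluded,
    )


def density_profile(schedule: Schedule) -> list[tuple[float, int]]:
    """Piecewise-constant concurrency from sorted endpoint events.

    Returns (time, concurrency-from-that-time) pairs; empty for an empty
    schedule.
    """
    deltas: dict[float, int] = {}
    for t in schedule.targets:
        deltas[t.window_start] = deltas.get(t.window_start, 0) + 1
        deltas[t.window_stop] = deltas.get(t.window_stop, 0) - 1
    profile = []
    active = 0
    for time in sorted(deltas):
        active += deltas[time]
        profile.append((time, active))
    return profile


def max_injection_time(
    cycle_time: float,
    density: int,
    routing_overhead: float = 0.0,
    requested: float | None = None,
    override: bool = False,
) -> float:
    """Per-scan maximum ion injection time (ms) that fits the cycle budget.

    ``floor(1000 * cycle_time / density) - routing_overhead``, floored at
    1 ms. When ``requested`` exceeds the budget a ValidationError is raised
    unless ``override`` is set, in which case the requested value is
    returned (scans rarely fill the budget at high density, so operators may
    deliberately exceed it).
    """
    if density < 1:
        raise ValidationError(f"density must be >= 1, got {density}")
    if not cycle_time > 0:
        raise ValidationError(f"cycle_time must be > 0, got {cycle_time}")
    budget = max(1.0, math.floor(1000.0 * cycle_time / density) - routing_overhead)
    if requested is None:
        return budget
    if requested > budget and not override:
        raise ValidationError(
            f"requested maxIIT {requested} ms exceeds budget {budget} ms "
            "(pass override=True to exceed it)"
        )
    return float(requested)


def points_per_peak(peak_width: float, cycle_time: float) -> float:
    """Chromatographic points sampled across a peak of the given width."""
    if not peak_width > 0 or not cycle_time > 0:
        raise ValidationError("peak_width and cycle_time must be > 0")
    return peak_width / cycle_time


def tier_assay(
    candidates: list[Candidate],
    rt_map: RTMap,
    tiers: list[ScheduleConfig],
) -> list[Schedule]:
    """Build one independent schedule per tier from the same candidate bank.

    Tiers must be ordered by descending max_density (highest-input assay
    first).
    """
    densities = [t.max_density for t in tiers]
    if densities != sorted(densities, reverse=True):
        raise ValidationError(
            f"tiers must be ordered by descending max_density, got {densities}"
        )
    return [build_schedule(candidates, rt_map, config) for config in tiers]
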
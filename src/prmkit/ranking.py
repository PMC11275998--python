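"""Peptide scoring and transition selection.

DDA peptides are scored by precursor intensity (falling back to summed
fragment intensity). DIA peptides are scored by the intensity of the third
largest fragment ion surviving the transition filters, so a peptide's score
reflects signal that at least three usable transitions can carry.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .errors import ValidationError
from .library_io import FragmentIon, LibraryEntry, TargetList

__all__ = [
    "TransitionPolicy",
    "Candidate",
    "parse_ion_label",
    "passing_fragments",
    "select_transitions",
    "score_dda",
    "score_dia",
    "build_candidates",
]

_ION_LABEL = re.compile(r"^([abcxyz])(\d+)(?:\^(\d+))?$")


def parse_ion_label(label: str) -> tuple[str, int, int] | None:
    """Parse ``y5^1``-style labels into (series, index, charge).

    Charge defaults to 1 when omitted. Returns None for labels that do not
    follow the series+index[+charge] convention.
    """
    m = _ION_LABEL.match(label)
    if m is None:
        return None
    series, index, charge = m.group(1), int(m.group(2)), m.group(3)
    return series, index, 1 if charge is None else int(charge)


@dataclass(frozen=True)
class TransitionPolicy:
    """Filters and limits for selecting diagnostic transitions."""

    min_count: int = 3
    quant_max: int = 5
    report_max: int = 9
    product_mz_min: float = 200.0
    product_mz_max: float = 1500.0
    precursor_exclusion_halfwidth: float = 1.0
    allowed_series: frozenset[str] = frozenset({"b", "y"})
    allowed_fragment_charges: frozenset[int] = frozenset({1, 2})
    terminal_trim: bool = True

    def __post_init__(self) -> None:
        if not (self.min_count <= self.quant_max <= self.report_max):
            raise ValidationError(
                "require min_count <= quant_max <= report_max, got "
                f"{self.min_count}/{self.quant_max}/{self.report_max}"
            )
        if not self.product_mz_min < self.product_mz_max:
            raise ValidationError("product_mz_min must be < product_mz_max")


@dataclass(frozen=True)
class Candidate:
    """A ranked, schedulable peptide with its selected transitions."""

    entry: LibraryEntry
    score: float
    transitions: tuple[FragmentIon, ...]
    target_proteins: tuple[str, ...]
    forced: bool = False
    eligible: bool = True

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"score must be >= 0, got {self.score}")
        if not self.target_proteins:
            raise ValidationError("candidate must map to >= 1 target protein")


def passing_fragments(
    entry: LibraryEntry,
    policy: TransitionPolicy,
    isolation_center: float,
) -> list[FragmentIon]:
    """Fragments surviving series/charge/m/z-range/precursor-exclusion and
    terminal-trim filters (unsorted, input order preserved)."""
    peptide_length = len(entry.bare_sequence)
    survivors = []
    for frag in entry.fragments:
        parsed = parse_ion_label(frag.ion_label)
        if parsed is None:
            continue
        series, index, charge = parsed
        if series not in policy.allowed_series:
            continue
        if charge not in policy.allowed_fragment_charges:
            continue
        if not policy.product_mz_min <= frag.mz <= policy.product_mz_max:
            continue
        if abs(frag.mz - isolation_center) <= policy.precursor_exclusion_halfwidth:
            continue
        if policy.terminal_trim and not (3 <= index <= peptide_length - 2):
            continue
        survivors.append(frag)
    return survivors


def select_transitions(
    entry: LibraryEntry,
    policy: TransitionPolicy,
    isolation_center: float,
) -> list[FragmentIon]:
    """Top ``report_max`` passing fragments, ordered by descending intensity
    with ties broken by ascending m/z."""
    survivors = passing_fragments(entry, policy, isolation_center)
    survivors.sort(key=lambda f: (-f.intensity, f.mz))
    return survivors[: policy.report_max]


def score_dda(entry: LibraryEntry) -> float:
    """Precursor intensity; falls back to summed fragment intensity, then 0."""
    if entry.source != "DDA":
        raise ValidationError("score_dda requires a DDA entry")
    if entry.precursor_intensity is not None:
        return float(entry.precursor_intensity)
    if entry.fragments:
        return float(sum(f.intensity for f in entry.fragments))
    warnings.warn(
        f"DDA entry {entry.modified_sequence}.{entry.precursor_charge} has "
        "neither precursor intensity nor fragments; scored 0"
    )
    return 0.0


def score_dia(
    entry: LibraryEntry, policy: TransitionPolicy | None = None
) -> float:
    """Intensity of the third largest passing fragment; 0 (ineligible) when
    fewer than ``min_count`` fragments pass the filters."""
    if entry.source != "DIA":
        raise ValidationError("score_dia requires a DIA entry")
    if policy is None:
        policy = TransitionPolicy()
    survivors = passing_fragments(entry, policy, entry.precursor_mz)
    if len(survivors) < policy.min_count:
        return 0.0
    intensities = sorted((f.intensity for f in survivors), reverse=True)
    return float(intensities[2])


def build_candidates(
    entries: list[LibraryEntry],
    resolved_targets: set[str],
    target_list: TargetList | None = None,
    policy: TransitionPolicy | None = None,
) -> list[Candidate]:
    """Filter library entries to target proteins and rank them.

    Entries mapping to no resolved target accession are dropped, as are
    peptides on the exclusion list. Forced (inclusion-list) peptides are
    flagged and sorted ahead of the rest. Within each group the order is
    descending score with (bare_sequence, charge) tie-breaks. DIA entries
    with fewer than ``min_count`` usable transitions are kept but marked
    ineligible so the scheduler can report them.
    """
    if target_list is None:
        target_list = TargetList()
    if policy is None:
        policy = TransitionPolicy()

    candidates = []
    present = set()
    for entry in entries:
        mapped = tuple(
            a for a in entry.protein_accessions if a in resolved_targets
        )
        if not mapped:
            continue
        bare = entry.bare_sequence
        if bare in target_list.excluded_peptides:
            continue
        present.add(bare)
        forced = bare in target_list.forced_peptides
        eligible = True
        if entry.source == "DIA":
            score = score_dia(entry, policy)
            if score == 0.0 and len(
                passing_fragments(entry, policy, entry.precursor_mz)
            ) < policy.min_count:
                eligible = False
        else:
            score = score_dda(entry)
        transitions = tuple(
            select_transitions(entry, policy, entry.precursor_mz)
        )
        candidates.append(
            Candidate(
                entry=entry,
                score=score,
                transitions=transitions,
                target_proteins=mapped,
                forced=forced,
                eligible=eligible,
            )
        )

    missing_forced = target_list.forced_peptides - present
    for peptide in sorted(missing_forced):
        warnings.warn(f"forced peptide {peptide!r} not found in library")

    candidates.sort(
        key=lambda c: (
            not c.forced,
            -c.score,
            c.entry.bare_sequence,
            c.entry.precursor_charge,
        )
    )
    return candidates
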
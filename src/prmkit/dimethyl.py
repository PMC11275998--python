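"""Mass arithmetic for the dimethyl matched-matrix design.

Reductive dimethylation adds two methyl groups to every free amine (the
peptide N-terminus plus each lysine side chain), shifting background
precursors out of every foreground isolation window. The validator checks
the worst case: a single methyl group on a single site.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .scheduler import Schedule

__all__ = [
    "METHYL_MONOISOTOPIC",
    "METHYL_NOMINAL",
    "ExclusionCheck",
    "label_sites",
    "mass_shift",
    "min_precursor_mz_shift",
    "validate_background_exclusion",
    "write_exclusion_report",
]

# CH2 replacing an amine H: C (12 exactly) + 2 H (1.00782503) - H
METHYL_MONOISOTOPIC = 14.01565
METHYL_NOMINAL = 14.0

_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _methyl_delta(mode: str) -> float:
    if mode == "monoisotopic":
        return METHYL_MONOISOTOPIC
    if mode == "nominal":
        return METHYL_NOMINAL
    raise ValidationError(f"mode must be 'monoisotopic' or 'nominal', got {mode!r}")


def label_sites(bare_sequence: str) -> int:
    """Number of dimethyl-labelable free amines: N-terminus plus lysines.

    Proline N-termini and modified lysines are still counted; overcounting
    sites never weakens the worst-case exclusion check.
    """
    if not bare_sequence:
        raise ValidationError("empty peptide sequence")
    bad = set(bare_sequence) - _AMINO_ACIDS
    if bad:
        raise ValidationError(
            f"sequence contains non-amino-acid characters: {sorted(bad)}"
        )
    return 1 + bare_sequence.count("K")


def mass_shift(
    n_sites: int, methyls_per_site: int, mode: str = "monoisotopic"
) -> float:
    """Total label mass shift in Da: sites x methyls x per-methyl delta."""
    if n_sites < 0:
        raise ValidationError(f"n_sites must be >= 0, got {n_sites}")
    if methyls_per_site not in (1, 2):
        raise ValidationError(
            f"methyls_per_site must be 1 or 2, got {methyls_per_site}"
        )
    return n_sites * methyls_per_site * _methyl_delta(mode)


def min_precursor_mz_shift(
    bare_sequence: str, charge: int, mode: str = "monoisotopic"
) -> float:
    """Worst-case (smallest) precursor m/z shift of a labeled background
    peptide: one single methyl group on one site, divided by charge."""
    if charge < 1:
        raise ValidationError(f"charge must be >= 1, got {charge}")
    label_sites(bare_sequence)  # validates the sequence
    return _methyl_delta(mode) / charge


@dataclass(frozen=True)
class ExclusionCheck:
    """Per-target, per-charge outcome of the background-exclusion check."""

    compound: str
    charge: int
    min_shift_mz: float
    half_width_mz: float
    margin_mz: float
    passed: bool


def validate_background_exclusion(
    schedule: Schedule, max_charge: int = 3, mode: str = "monoisotopic"
) -> list[ExclusionCheck]:
    """Check that every labeled background precursor falls outside every
    scheduled isolation window, for all charges up to ``max_charge``."""
    if max_charge < 1:
        raise ValidationError(f"max_charge must be >= 1, got {max_charge}")
    half_width = schedule.config.isolation_width / 2.0
    checks = []
    for target in schedule.targets:
        entry = target.candidate.entry
        compound = f"{entry.modified_sequence}.{entry.precursor_charge}"
        for charge in range(1, max_charge + 1):
            shift = min_precursor_mz_shift(entry.bare_sequence, charge, mode)
            checks.append(
                ExclusionCheck(
                    compound=compound,
                    charge=charge,
                    min_shift_mz=shift,
                    half_width_mz=half_width,
                    margin_mz=shift - half_width,
                    passed=shift > half_width,
                )
            )
    return checks


def write_exclusion_report(checks: list[ExclusionCheck], path: str) -> None:
    """Write the per-target exclusion report as TSV."""
    header = "Compound\tCharge\tMinShiftMz\tHalfWidthMz\tMarginMz\tPass"
    lines = [header]
    for c in checks:
        lines.append(
            f"{c.compound}\t{c.charge}\t{c.min_shift_mz:.4f}\t"
            f"{c.half_width_mz:.4f}\t{c.margin_mz:.4f}\t{c.passed}"
        )
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
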
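"""Readers and writers for peptide libraries, FASTA databases, target lists,
observed retention-time tables, inclusion lists, and scheduling reports.

Library exchange format is a flat, diff-able TSV with two dialects:

* ``DIA`` (chromatogram library): one row per fragment ion, columns
  ``ModifiedSequence, PrecursorCharge, PrecursorMz, RetentionTime,
  ProteinAccessions, FragmentLabel, FragmentMz, FragmentIntensity``.
* ``DDA`` (spectrum library): one row per precursor, columns
  ``ModifiedSequence, PrecursorCharge, PrecursorMz, RetentionTime,
  ProteinAccessions, PrecursorIntensity``; optional fragment columns as in
  the DIA dialect.

Retention times are minutes, m/z in Thomson, masses monoisotopic Da.
Modifications use bracketed delta masses, e.g. ``C[+57.0215]``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO

from .errors import DuplicateKeyError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .scheduler import Schedule

__all__ = [
    "FragmentIon",
    "LibraryEntry",
    "TargetList",
    "strip_modifications",
    "read_library",
    "write_library",
    "read_fasta",
    "resolve_targets",
    "read_peptide_list",
    "read_observed_rt",
    "write_inclusion_list",
    "read_inclusion_list",
    "write_schedule_report",
]

_MOD_PATTERN = re.compile(r"\[[^\[\]]*\]")

DIA_COLUMNS = [
    "ModifiedSequence",
    "PrecursorCharge",
    "PrecursorMz",
    "RetentionTime",
    "ProteinAccessions",
    "FragmentLabel",
    "FragmentMz",
    "FragmentIntensity",
]

DDA_COLUMNS = [
    "ModifiedSequence",
    "PrecursorCharge",
    "PrecursorMz",
    "RetentionTime",
    "ProteinAccessions",
    "PrecursorIntensity",
]

FRAGMENT_COLUMNS = ["FragmentLabel", "FragmentMz", "FragmentIntensity"]

INCLUSION_COLUMNS = ["Compound", "m/z", "z", "t start (min)", "t stop (min)"]


def strip_modifications(modified_sequence: str) -> str:
    """Remove bracketed modification groups, returning the bare sequence."""
    return _MOD_PATTERN.sub("", modified_sequence)


@dataclass(frozen=True)
class FragmentIon:
    """A single product ion from a library spectrum or chromatogram."""

    ion_label: str
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.ion_label:
            raise ValidationError("fragment ion_label must be non-empty")
        if not self.mz > 0:
            raise ValidationError(f"fragment mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(
                f"fragment intensity must be >= 0, got {self.intensity}"
            )


@dataclass(frozen=True)
class LibraryEntry:
    """One peptide precursor in a library.

    ``source`` is ``"DDA"`` or ``"DIA"``. DDA entries may lack fragments only
    when a precursor intensity is present.
    """

    modified_sequence: str
    precursor_charge: int
    precursor_mz: float
    retention_time: float
    protein_accessions: tuple[str, ...]
    source: str
    precursor_intensity: float | None = None
    fragments: tuple[FragmentIon, ...] = ()

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValidationError(
                f"precursor_charge must be >= 1, got {self.precursor_charge}"
            )
        if self.retention_time < 0:
            raise ValidationError(
                f"retention_time must be >= 0, got {self.retention_time}"
            )
        if self.source not in ("DDA", "DIA"):
            raise ValidationError(f"source must be DDA or DIA, got {self.source!r}")
        if not self.protein_accessions or any(
            not a for a in self.protein_accessions
        ):
            raise ValidationError("every protein accession must be non-empty")
        if (
            self.source == "DDA"
            and not self.fragments
            and self.precursor_intensity is None
        ):
            raise ValidationError(
                "DDA entry without fragments requires a precursor intensity"
            )

    @property
    def bare_sequence(self) -> str:
        return strip_modifications(self.modified_sequence)

    @property
    def key(self) -> tuple[str, int]:
        return (self.modified_sequence, self.precursor_charge)


@dataclass
class TargetList:
    """Accessions/keywords to target plus peptide inclusion/exclusion lists."""

    accessions: frozenset[str] = frozenset()
    keywords: frozenset[str] = frozenset()
    forced_peptides: frozenset[str] = frozenset()
    excluded_peptides: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.accessions = frozenset(self.accessions)
        self.keywords = frozenset(self.keywords)
        self.forced_peptides = frozenset(self.forced_peptides)
        self.excluded_peptides = frozenset(self.excluded_peptides)
        overlap = self.forced_peptides & self.excluded_peptides
        if overlap:
            raise ValidationError(
                f"peptides both forced and excluded: {sorted(overlap)}"
            )


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_library(path: str, dialect: str) -> list[LibraryEntry]:
    """Read a library TSV, aggregating fragment rows per precursor.

    Returns one :class:`LibraryEntry` per ``(ModifiedSequence,
    PrecursorCharge)`` key, in first-appearance order.
    """
    dialect = dialect.upper()
    if dialect not in ("DDA", "DIA"):
        raise ValueError(f"dialect must be 'DDA' or 'DIA', got {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"ModifiedSequence": str})
    required = DIA_COLUMNS if dialect == "DIA" else DDA_COLUMNS
    _require_columns(df, required, str(path))
    has_fragments = dialect == "DIA" or all(
        c in df.columns for c in FRAGMENT_COLUMNS
    )

    entries: dict[tuple[str, int], dict] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # 1-based, after the header line
        rec = row._asdict()
        # pandas mangles 'ProteinAccessions' etc. only if unnamed; itertuples
        # keeps valid identifiers, which all our columns are.
        rt = float(rec["RetentionTime"])
        if rt < 0:
            raise ValidationError(f"row {rownum}: negative RetentionTime {rt}")
        key = (str(rec["ModifiedSequence"]), int(rec["PrecursorCharge"]))
        accessions = tuple(
            a for a in str(rec["ProteinAccessions"]).split(";") if a
        )
        if key not in entries:
            entries[key] = {
                "modified_sequence": key[0],
                "precursor_charge": key[1],
                "precursor_mz": float(rec["PrecursorMz"]),
                "retention_time": rt,
                "protein_accessions": accessions,
                "precursor_intensity": None,
                "fragments": [],
            }
            if dialect == "DDA":
                pint = rec.get("PrecursorIntensity")
                if pint is not None and pd.notna(pint):
                    pint = float(pint)
                    if pint < 0:
                        raise ValidationError(
                            f"row {rownum}: negative PrecursorIntensity {pint}"
                        )
                    entries[key]["precursor_intensity"] = pint
        elif dialect == "DDA" and not has_fragments:
            raise DuplicateKeyError(
                f"row {rownum}: duplicate precursor "
                f"({key[0]!r}, charge {key[1]}) in DDA dialect"
            )
        if has_fragments:
            label = rec.get("FragmentLabel")
            if label is not None and pd.notna(label):
                fmz = float(rec["FragmentMz"])
                fint = float(rec["FragmentIntensity"])
                if fint < 0:
                    raise ValidationError(
                        f"row {rownum}: negative FragmentIntensity {fint}"
                    )
                entries[key]["fragments"].append(
                    FragmentIon(str(label), fmz, fint)
                )

    return [
        LibraryEntry(
            modified_sequence=e["modified_sequence"],
            precursor_charge=e["precursor_charge"],
            precursor_mz=e["precursor_mz"],
            retention_time=e["retention_time"],
            protein_accessions=e["protein_accessions"],
            source=dialect,
            precursor_intensity=e["precursor_intensity"],
            fragments=tuple(e["fragments"]),
        )
        for e in entries.values()
    ]


def write_library(entries: Iterable[LibraryEntry], path: str, dialect: str) -> None:
    """Write entries to a library TSV in the given dialect."""
    dialect = dialect.upper()
    rows = []
    for entry in entries:
        base = {
            "ModifiedSequence": entry.modified_sequence,
            "PrecursorCharge": entry.precursor_charge,
            "PrecursorMz": entry.precursor_mz,
            "RetentionTime": entry.retention_time,
            "ProteinAccessions": ";".join(entry.protein_accessions),
        }
        if dialect == "DDA":
            base["PrecursorIntensity"] = entry.precursor_intensity
            rows.append(dict(base))
        else:
            for frag in entry.fragments:
                rows.append(
                    dict(
                        base,
                        FragmentLabel=frag.ion_label,
                        FragmentMz=frag.mz,
                        FragmentIntensity=frag.intensity,
                    )
                )
    columns = DDA_COLUMNS if dialect == "DDA" else DIA_COLUMNS
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


_UNIPROT_HEADER = re.compile(r"^[^|\s]+\|([^|\s]+)\|\S*")


def read_fasta(path: str) -> dict[str, tuple[str, str]]:
    """Index a FASTA file as ``accession -> (description, sequence)``.

    Accepts UniProt ``db|ACC|NAME Description`` headers and plain
    ``>ACC Description`` headers.
    """
    index: dict[str, tuple[str, str]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description
        m = _UNIPROT_HEADER.match(record.id)
        accession = m.group(1) if m else record.id
        parts = header.split(None, 1)
        description = parts[1] if len(parts) > 1 else ""
        sequence = str(record.seq).upper()
        if not sequence:
            raise ValidationError(f"FASTA record {accession!r} has empty sequence")
        if accession in index:
            raise DuplicateKeyError(f"duplicate FASTA accession {accession!r}")
        index[accession] = (description, sequence)
    return index


def resolve_targets(
    index: dict[str, tuple[str, str]], targets: TargetList
) -> set[str]:
    """Resolve a target list against a FASTA index.

    Returns accessions listed explicitly or whose description contains any
    keyword (case-insensitive substring). Unknown listed accessions produce
    warnings, not errors.
    """
    resolved: set[str] = set()
    for acc in targets.accessions:
        if acc in index:
            resolved.add(acc)
        else:
            warnings.warn(f"target accession {acc!r} not in FASTA index")
    if targets.keywords:
        lowered = [k.lower() for k in targets.keywords]
        for acc, (description, _seq) in index.items():
            desc = description.lower()
            if any(k in desc for k in lowered):
                resolved.add(acc)
    return resolved


def read_peptide_list(path: str) -> frozenset[str]:
    """Read a one-peptide-per-line list; '#' starts a comment."""
    peptides = set()
    with open(path) as handle:
        for line in handle:
            seq = line.split("#", 1)[0].strip()
            if seq:
                peptides.add(seq)
    return frozenset(peptides)


OBSERVED_RT_COLUMNS = ["ModifiedSequence", "PrecursorCharge", "ObservedRT"]


def read_observed_rt(path: str) -> pd.DataFrame:
    """Read the observed-RT TSV from a recent single-injection DIA run."""
    df = pd.read_csv(path, sep="\t", dtype={"ModifiedSequence": str})
    _require_columns(df, OBSERVED_RT_COLUMNS, str(path))
    if (df["ObservedRT"] < 0).any():
        bad = int(df.index[df["ObservedRT"] < 0][0]) + 2
        raise ValidationError(f"row {bad}: negative ObservedRT")
    return df[OBSERVED_RT_COLUMNS].copy()


def write_inclusion_list(schedule: "Schedule", path: str) -> None:
    """Write the method-editor inclusion list CSV.

    m/z is written to 4 decimals and times to 2; rows are sorted by window
    start, ties broken by ascending m/z.
    """
    rows = sorted(
        schedule.targets,
        key=lambda t: (t.window_start, t.isolation_center),
    )
    df = pd.DataFrame(
        {
            "Compound": [
                f"{t.candidate.entry.modified_sequence}.{t.candidate.entry.precursor_charge}"
                for t in rows
            ],
            "m/z": [f"{t.isolation_center:.4f}" for t in rows],
            "z": [t.candidate.entry.precursor_charge for t in rows],
            "t start (min)": [f"{t.window_start:.2f}" for t in rows],
            "t stop (min)": [f"{t.window_stop:.2f}" for t in rows],
        },
        columns=INCLUSION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_inclusion_list(path: str) -> pd.DataFrame:
    """Read back an inclusion-list CSV (round-trip support)."""
    df = pd.read_csv(path)
    _require_columns(df, INCLUSION_COLUMNS, str(path))
    return df


REPORT_COLUMNS = [
    "Peptide",
    "Charge",
    "Proteins",
    "Score",
    "LibraryRT",
    "AlignedRT",
    "WindowStart",
    "WindowStop",
    "Transitions",
]


def write_schedule_report(schedule: "Schedule", path: str) -> None:
    """Write the scheduling report TSV: one row per scheduled target plus a
    footer block of '#'-prefixed summary lines."""
    from .scheduler import density_profile  # local import avoids cycle

    lines = ["\t".join(REPORT_COLUMNS)]
    for t in schedule.targets:
        entry = t.candidate.entry
        lines.append(
            "\t".join(
                [
                    entry.modified_sequence,
                    str(entry.precursor_charge),
                    ";".join(t.candidate.target_proteins),
                    f"{t.candidate.score:.6g}",
                    f"{entry.retention_time:.4f}",
                    f"{t.aligned_rt:.4f}",
                    f"{t.window_start:.2f}",
                    f"{t.window_stop:.2f}",
                    ";".join(f.ion_label for f in t.candidate.transitions),
                ]
            )
        )
    reasons = list(schedule.rejections.values())
    profile = density_profile(schedule)
    peak = max((c for _, c in profile), default=0)
    lines.append(f"# targets_scheduled\t{len(schedule.targets)}")
    lines.append(f"# rejected_density\t{reasons.count('density')}")
    lines.append(f"# rejected_protein_cap\t{reasons.count('protein_cap')}")
    lines.append(f"# rejected_excluded\t{schedule.n_excluded}")
    lines.append(f"# rejected_ineligible\t{reasons.count('ineligible')}")
    lines.append(f"# peak_density\t{peak}")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
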
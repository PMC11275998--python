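"""Shared fixtures and instance generators for the prmkit test suite."""

from __future__ import annotations

import numpy as np
import pytest

from prmkit.library_io import FragmentIon, LibraryEntry
from prmkit.ranking import Candidate


def make_entry(
    sequence: str = "PEPTIDEK",
    charge: int = 2,
    mz: float = 450.0,
    rt: float = 20.0,
    proteins: tuple[str, ...] = ("P1",),
    source: str = "DDA",
    precursor_intensity: float | None = 1000.0,
    fragments: tuple[FragmentIon, ...] = (),
) -> LibraryEntry:
    return LibraryEntry(
        modified_sequence=sequence,
        precursor_charge=charge,
        precursor_mz=mz,
        retention_time=rt,
        protein_accessions=proteins,
        source=source,
        precursor_intensity=precursor_intensity,
        fragments=fragments,
    )


def make_candidate(
    sequence: str = "PEPTIDEK",
    charge: int = 2,
    score: float = 100.0,
    rt: float = 20.0,
    mz: float = 450.0,
    proteins: tuple[str, ...] = ("P1",),
    forced: bool = False,
    eligible: bool = True,
) -> Candidate:
    entry = make_entry(
        sequence=sequence, charge=charge, mz=mz, rt=rt, proteins=proteins
    )
    return Candidate(
        entry=entry,
        score=score,
        transitions=(),
        target_proteins=proteins,
        forced=forced,
        eligible=eligible,
    )


def random_instance(
    seed: int,
    max_candidates: int = 500,
    n_proteins: int | None = None,
    gradient_end: float = 50.0,
):
    """A seeded random scheduling instance: sorted candidates + parameters.

    Returns (candidates, max_density, per_protein_cap, gradient_end).
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, max_candidates + 1))
    if n_proteins is None:
        n_proteins = max(1, n // int(rng.integers(1, 8)))
    max_density = int(rng.integers(1, 25))
    cap = int(rng.integers(3, 6))
    candidates = []
    for i in range(n):
        protein = f"P{int(rng.integers(0, n_proteins))}"
        candidates.append(
            make_candidate(
                sequence=f"SEQ{i}K",
                charge=int(rng.choice([2, 3])),
                score=float(rng.uniform(1, 1e6)),
                rt=float(rng.uniform(0, gradient_end)),
                mz=float(rng.uniform(400, 1000)),
                proteins=(protein,),
            )
        )
    candidates.sort(
        key=lambda c: (-c.score, c.entry.bare_sequence, c.entry.precursor_charge)
    )
    return candidates, max_density, cap, gradient_end


@pytest.fixture
def dia_fragments() -> tuple[FragmentIon, ...]:
    """Six passing y-ions for a length-10 peptide (indices 3..8)."""
    return tuple(
        FragmentIon(f"y{i}^1", 300.0 + 50 * i, 1000.0 - 100 * i)
        for i in range(3, 9)
    )
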
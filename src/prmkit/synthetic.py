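"""Seeded synthetic libraries, observed-RT tables, and calibration curves.

Everything is deterministic under its seed and ships with a ground-truth
table so downstream estimators can be tested for parameter recovery without
any external data. Generated sequences are tryptic-like (ending in K/R,
optionally without internal K/R) and fragment m/z values follow real y/b-ion
arithmetic so transition filters behave as they would on real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CurvePoint
from .errors import ValidationError
from .library_io import FragmentIon, LibraryEntry

__all__ = [
    "SimConfig",
    "CurveSimConfig",
    "generate_library",
    "generate_observed_rt",
    "generate_curve",
    "bilinear_mean",
]

PROTON = 1.007276466
WATER = 18.010565

# Monoisotopic residue masses, standard 20 amino acids.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

_INTERNAL_AA = "ACDEFGHILMNPQSTVWY"  # no K/R: zero missed cleavages
_INTERNAL_AA_MC = _INTERNAL_AA + "KR"  # allow internal K/R (missed cleavage)
_TERMINAL_AA = "KR"


@dataclass(frozen=True)
class SimConfig:
    """Parameters for a synthetic DIA chromatogram library."""

    n_proteins: int = 10
    peptides_per_protein: int = 5
    gradient: tuple[float, float] = (0.0, 50.0)
    abundance_mu: float = 11.0
    abundance_sigma: float = 1.5
    fragment_count: tuple[int, int] = (6, 12)
    peptide_length: tuple[int, int] = (7, 15)
    allow_missed_cleavage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.peptides_per_protein < 1:
            raise ValidationError("counts must be >= 1")
        if not self.gradient[0] < self.gradient[1]:
            raise ValidationError("gradient start must be < end")


@dataclass(frozen=True)
class CurveSimConfig:
    """Parameters for one synthetic matrix-matched calibration curve."""

    true_breakpoint: float = 0.05
    slope: float = 1e5
    noise_floor: float = 100.0
    replicate_cv: float = 0.05
    dilution_levels: tuple[float, ...] = (
        1.0, 0.3, 0.1, 0.03, 0.01, 0.003, 0.001, 0.0,
    )
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        levels = list(self.dilution_levels)
        if levels != sorted(levels, reverse=True):
            raise ValidationError("dilution_levels must be sorted descending")


def _peptide_mz(sequence: str, charge: int) -> float:
    mass = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER
    return (mass + charge * PROTON) / charge


def _y_ion_mz(sequence: str, index: int, charge: int = 1) -> float:
    mass = sum(RESIDUE_MASS[aa] for aa in sequence[-index:]) + WATER
    return (mass + charge * PROTON) / charge


def _b_ion_mz(sequence: str, index: int, charge: int = 1) -> float:
    mass = sum(RESIDUE_MASS[aa] for aa in sequence[:index])
    return (mass + charge * PROTON) / charge


def _random_sequence(rng: np.random.Generator, config: SimConfig) -> str:
    lo, hi = config.peptide_length
    length = int(rng.integers(lo, hi + 1))
    pool = _INTERNAL_AA_MC if config.allow_missed_cleavage else _INTERNAL_AA
    body = "".join(rng.choice(list(pool), size=length - 1))
    tail = str(rng.choice(list(_TERMINAL_AA)))
    return body + tail


def generate_library(
    config: SimConfig,
) -> tuple[list[LibraryEntry], pd.DataFrame]:
    """Generate a DIA-dialect library and its ground truth.

    Each protein gets ``peptides_per_protein`` tryptic-like peptides with
    uniform RTs inside the gradient interior and fragment intensities drawn
    so the third largest equals a log-normal abundance (the intended score).
    The truth table records sequence, charge, protein, RT, and abundance.
    """
    rng = np.random.default_rng(config.seed)
    g0, g1 = config.gradient
    span = g1 - g0
    entries = []
    truth_rows = []
    seen: set[str] = set()
    for p in range(config.n_proteins):
        accession = f"SIMP{p:04d}"
        for _ in range(config.peptides_per_protein):
            sequence = _random_sequence(rng, config)
            while sequence in seen:
                sequence = _random_sequence(rng, config)
            seen.add(sequence)
            charge = int(rng.choice([2, 3]))
            rt = float(g0 + span * (0.05 + 0.9 * rng.random()))
            abundance = float(
                np.exp(rng.normal(config.abundance_mu, config.abundance_sigma))
            )

            lo, hi = config.fragment_count
            n_frag = int(rng.integers(lo, hi + 1))
            # y-ions from y3 up to y(len-2) obey the terminal-trim filter;
            # indices outside the 200-1500 product range or inside the
            # precursor exclusion window are dropped so every generated
            # fragment survives the default transition filters; ratios are
            # scaled so the third largest equals `abundance`.
            precursor_mz = _peptide_mz(sequence, charge)
            max_index = len(sequence) - 2
            indices = [
                i
                for i in range(3, max_index + 1)
                if 200.0 <= _y_ion_mz(sequence, i) <= 1500.0
                and abs(_y_ion_mz(sequence, i) - precursor_mz) > 1.0
            ]
            rng.shuffle(indices)
            indices = sorted(indices[:n_frag])
            ratios = rng.lognormal(0.0, 0.8, size=len(indices))
            if len(ratios) >= 3:
                third = np.sort(ratios)[::-1][2]
                ratios = ratios / third * abundance
            else:
                ratios = ratios * abundance
            fragments = tuple(
                FragmentIon(f"y{idx}^1", _y_ion_mz(sequence, idx), float(r))
                for idx, r in zip(indices, ratios)
            )
            entries.append(
                LibraryEntry(
                    modified_sequence=sequence,
                    precursor_charge=charge,
                    precursor_mz=precursor_mz,
                    retention_time=rt,
                    protein_accessions=(accession,),
                    source="DIA",
                    fragments=fragments,
                )
            )
            truth_rows.append(
                {
                    "ModifiedSequence": sequence,
                    "PrecursorCharge": charge,
                    "Protein": accession,
                    "RetentionTime": rt,
                    "Abundance": abundance,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return entries, truth


def generate_observed_rt(
    entries: list[LibraryEntry],
    slope: float = 1.0,
    intercept: float = 0.0,
    jitter_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed-RT table under a known affine drift plus optional Gaussian
    jitter and a seeded fraction of uniform gross outliers."""
    if not entries:
        raise ValidationError("need a non-empty library")
    if not 0.0 <= outlier_fraction <= 1.0:
        raise ValidationError("outlier_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    library_rt = np.array([e.retention_time for e in entries])
    observed = slope * library_rt + intercept
    if jitter_sd > 0:
        observed = observed + rng.normal(0.0, jitter_sd, size=observed.size)
    if outlier_fraction > 0:
        n_out = int(round(outlier_fraction * observed.size))
        if n_out > 0:
            idx = rng.choice(observed.size, size=n_out, replace=False)
            lo, hi = float(observed.min()), float(observed.max())
            span = max(hi - lo, 1.0)
            observed[idx] = rng.uniform(lo - span, hi + span, size=n_out)
    observed = np.clip(observed, 0.0, None)
    return pd.DataFrame(
        {
            "ModifiedSequence": [e.modified_sequence for e in entries],
            "PrecursorCharge": [e.precursor_charge for e in entries],
            "ObservedRT": observed,
        }
    )


def bilinear_mean(
    dilution: float, breakpoint: float, slope: float, noise_floor: float
) -> float:
    """Hockey-stick mean response at one dilution."""
    return noise_floor + slope * max(0.0, dilution - breakpoint)


def generate_curve(
    config: CurveSimConfig,
) -> tuple[list[CurvePoint], dict]:
    """Generate one calibration curve plus its generating truth.

    Replicates are Gaussian around the bilinear mean with the configured CV
    (clipped at zero area); cv=0 reproduces the mean exactly.
    """
    rng = np.random.default_rng(config.seed)
    points = []
    for dilution in config.dilution_levels:
        mean = bilinear_mean(
            dilution, config.true_breakpoint, config.slope, config.noise_floor
        )
        if config.replicate_cv > 0:
            areas = rng.normal(
                mean, config.replicate_cv * mean, size=config.n_replicates
            )
            areas = np.clip(areas, 0.0, None)
        else:
            areas = np.full(config.n_replicates, mean)
        points.append(
            CurvePoint(
                dilution=float(dilution),
                replicate_areas=tuple(float(a) for a in areas),
            )
        )
    truth = {
        "breakpoint": config.true_breakpoint,
        "slope": config.slope,
        "noise_floor": config.noise_floor,
        "replicate_cv": config.replicate_cv,
    }
    return points, truth
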
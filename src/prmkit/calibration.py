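"""Matrix-matched calibration curves: bilinear fits, LoD and LoQ.

The response model is a hockey stick: constant noise floor ``c`` up to a
breakpoint ``x0``, then linear ``c + m (x - x0)``. The breakpoint is found
by a log-spaced grid search (65 knots) over the dilution range with the
floor and slope solved analytically at each knot, followed by a bounded 1-D
refinement between the best knot's neighbors.

LoD is where the linear segment clears the noise floor by twice the blank
standard deviation. LoQ is the smallest measured dilution at or above the
LoD whose bootstrap CV of the replicate mean is within threshold (default
20%); it snaps to measured levels rather than interpolating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import InsufficientDataError, SchemaError, ValidationError

__all__ = [
    "CurvePoint",
    "BilinearFit",
    "FiguresOfMerit",
    "fit_bilinear",
    "estimate_lod",
    "estimate_loq",
    "bootstrap_cv",
    "replicate_cv",
    "figures_of_merit",
    "summarize_assay",
    "read_quant_table",
    "write_fom_table",
]

N_GRID_KNOTS = 65
QUANT_COLUMNS = ["Peptide", "Charge", "Dilution", "Replicate", "Area"]
FOM_COLUMNS = [
    "Peptide",
    "Charge",
    "LoD",
    "LoQ",
    "Slope",
    "NoiseFloor",
    "CVatLoQ",
    "Status",
]


@dataclass(frozen=True)
class CurvePoint:
    """One dilution level of a calibration curve with replicate peak areas.

    ``dilution`` is the foreground:background ratio normalized to a fraction
    of neat (0.043 for a 0.043:1 mix; 0 for the blank).
    """

    dilution: float
    replicate_areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.dilution < 0:
            raise ValidationError(f"dilution must be >= 0, got {self.dilution}")
        if not self.replicate_areas:
            raise ValidationError("each curve point needs >= 1 replicate area")
        if any(a < 0 for a in self.replicate_areas):
            raise ValidationError("replicate areas must be >= 0")

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.replicate_areas))


@dataclass(frozen=True)
class BilinearFit:
    noise_floor: float
    breakpoint: float
    slope: float
    sse: float
    degenerate: bool


def _solve_at_knot(
    x: np.ndarray, y: np.ndarray, x0: float
) -> tuple[float, float, float]:
    """Least squares (c, m) for y = c + m * max(0, x - x0), m >= 0."""
    z = np.maximum(0.0, x - x0)
    zbar, ybar = z.mean(), y.mean()
    var = float(np.sum((z - zbar) ** 2))
    if var <= 0.0:
        c, m = ybar, 0.0
    else:
        m = float(np.sum((z - zbar) * (y - ybar)) / var)
        if m < 0:
            c, m = ybar, 0.0
        else:
            c = ybar - m * zbar
    sse = float(np.sum((y - (c + m * z)) ** 2))
    return c, m, sse


def fit_bilinear(points: list[CurvePoint]) -> BilinearFit:
    """Fit the hockey-stick model to per-level mean areas.

    Requires at least 4 distinct dilution levels. A flat fit (slope ~ 0, or
    all-zero areas) is returned with the ``degenerate`` flag set.
    """
    by_level: dict[float, CurvePoint] = {}
    for p in points:
        by_level[p.dilution] = p
    levels = sorted(by_level)
    if len(levels) < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct dilution levels, got {len(levels)}"
        )
    x = np.array(levels, dtype=float)
    y = np.array([by_level[lv].mean_area for lv in levels], dtype=float)

    positive = x[x > 0]
    lo = float(positive.min()) * 1e-6
    hi = float(positive.max())
    knots = np.geomspace(lo, hi, N_GRID_KNOTS)

    results = [_solve_at_knot(x, y, k) for k in knots]
    best = int(np.argmin([r[2] for r in results]))
    c, m, sse = results[best]
    x0 = float(knots[best])

    # Bounded refinement between the best knot's neighbors sharpens the
    # breakpoint beyond the ~11%/step grid resolution.
    lo_b = knots[max(0, best - 1)]
    hi_b = knots[min(len(knots) - 1, best + 1)]
    if hi_b > lo_b:
        res = minimize_scalar(
            lambda k: _solve_at_knot(x, y, k)[2],
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": lo_b * 1e-9},
        )
        c_r, m_r, sse_r = _solve_at_knot(x, y, float(res.x))
        if sse_r <= sse:
            c, m, sse, x0 = c_r, m_r, sse_r, float(res.x)

    scale = max(1.0, float(np.max(np.abs(y))))
    rise = m * max(0.0, float(x.max()) - x0)
    degenerate = (m <= 0.0) or (rise < 1e-9 * scale)
    return BilinearFit(
        noise_floor=c, breakpoint=x0, slope=m, sse=sse, degenerate=degenerate
    )


def _blank_sd(points: list[CurvePoint]) -> float:
    """Standard deviation of blank replicates; falls back to the lowest
    dilution level (with a warning) when no blank is present."""
    blanks = [p for p in points if p.dilution == 0]
    if blanks:
        areas = np.concatenate([np.asarray(p.replicate_areas) for p in blanks])
    else:
        lowest = min(points, key=lambda p: p.dilution)
        warnings.warn(
            "no blank replicates; using the lowest dilution level "
            f"({lowest.dilution}) for the noise estimate"
        )
        areas = np.asarray(lowest.replicate_areas, dtype=float)
    if areas.size < 2:
        return 0.0
    return float(np.std(areas, ddof=1))


def estimate_lod(points: list[CurvePoint], fit: BilinearFit) -> float | None:
    """Dilution where the fitted linear segment crosses
    ``noise_floor + 2 * sd(blank)``; None when that never happens inside the
    measured range or the fit is degenerate."""
    if fit.degenerate:
        return None
    sd = _blank_sd(points)
    lod = fit.breakpoint + 2.0 * sd / fit.slope
    max_level = max(p.dilution for p in points)
    if lod > max_level:
        return None
    return float(lod)


def bootstrap_cv(
    areas: tuple[float, ...] | list[float],
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> float | None:
    """CV of bootstrap-resampled replicate means; None when undefined
    (single replicate or zero mean)."""
    areas = np.asarray(areas, dtype=float)
    if areas.size < 2:
        return None
    if rng is None:
        rng = np.random.default_rng()
    samples = rng.choice(areas, size=(n_boot, areas.size), replace=True)
    means = samples.mean(axis=1)
    center = float(means.mean())
    if center == 0.0:
        return None
    return float(means.std(ddof=1) / center)


def estimate_loq(
    points: list[CurvePoint],
    fit: BilinearFit,
    cv_threshold: float = 0.20,
    n_boot: int = 100,
    seed: int = 0,
    lod: float | None = None,
) -> float | None:
    """Smallest measured dilution >= LoD whose bootstrap CV is within the
    threshold; None when no level qualifies (reported as 'could not be
    assigned a LoQ')."""
    if lod is None:
        lod = estimate_lod(points, fit)
    if lod is None:
        return None
    rng = np.random.default_rng(seed)
    eligible = sorted(
        (p for p in points if p.dilution >= lod - 1e-12),
        key=lambda p: p.dilution,
    )
    any_multi = False
    for point in eligible:
        cv = bootstrap_cv(point.replicate_areas, n_boot=n_boot, rng=rng)
        if cv is None:
            continue
        any_multi = True
        if cv <= cv_threshold:
            return float(point.dilution)
    if not any_multi:
        warnings.warn("no level has >= 2 replicates; LoQ undefined")
    return None


def replicate_cv(areas: tuple[float, ...] | list[float]) -> float | None:
    """Sample coefficient of variation (sd with n-1 denominator over mean);
    None when the mean is 0."""
    areas = np.asarray(areas, dtype=float)
    if areas.size < 2:
        raise InsufficientDataError("replicate_cv needs >= 2 replicates")
    mean = float(areas.mean())
    if mean == 0.0:
        return None
    return float(areas.std(ddof=1) / mean)


@dataclass(frozen=True)
class FiguresOfMerit:
    lod: float | None
    loq: float | None
    slope: float
    noise_floor: float
    cv_at_loq: float | None
    status: str  # ok | no_loq | no_lod | degenerate

    def __post_init__(self) -> None:
        if self.lod is not None and self.loq is not None and self.loq < self.lod:
            raise ValidationError("LoQ must be >= LoD when both are defined")


def figures_of_merit(
    points: list[CurvePoint],
    cv_threshold: float = 0.20,
    n_boot: int = 100,
    seed: int = 0,
) -> FiguresOfMerit:
    """Fit one curve and derive its LoD/LoQ figures of merit."""
    fit = fit_bilinear(points)
    lod = estimate_lod(points, fit)
    loq = estimate_loq(
        points, fit, cv_threshold=cv_threshold, n_boot=n_boot, seed=seed, lod=lod
    )
    cv_at_loq = None
    if loq is not None:
        level = next(p for p in points if p.dilution == loq)
        cv_at_loq = bootstrap_cv(
            level.replicate_areas, n_boot=n_boot, rng=np.random.default_rng(seed + 1)
        )
    if fit.degenerate:
        status = "degenerate"
    elif lod is None:
        status = "no_lod"
    elif loq is None:
        status = "no_loq"
    else:
        status = "ok"
    return FiguresOfMerit(
        lod=lod,
        loq=loq,
        slope=fit.slope,
        noise_floor=fit.noise_floor,
        cv_at_loq=cv_at_loq,
        status=status,
    )


def summarize_assay(foms: list[FiguresOfMerit]) -> dict:
    """Assay-level summary: median LoD/LoQ over defined values, fraction of
    peptides without a LoQ, and a log10 LoQ histogram for reporting."""
    if not foms:
        raise InsufficientDataError("summarize_assay needs >= 1 peptide")
    lods = [f.lod for f in foms if f.lod is not None]
    loqs = [f.loq for f in foms if f.loq is not None]
    frac_no_loq = sum(1 for f in foms if f.loq is None) / len(foms)
    summary = {
        "n_peptides": len(foms),
        "median_lod": float(np.median(lods)) if lods else None,
        "median_loq": float(np.median(loqs)) if loqs else None,
        "fraction_loq_undefined": frac_no_loq,
    }
    if loqs:
        counts, edges = np.histogram(np.log10(loqs), bins=10)
        summary["loq_log10_hist_counts"] = counts.tolist()
        summary["loq_log10_hist_edges"] = edges.tolist()
    return summary


def read_quant_table(path: str) -> dict[tuple[str, int], list[CurvePoint]]:
    """Read a per-peptide quant table (Peptide, Charge, Dilution, Replicate,
    Area) into curve points grouped by (peptide, charge)."""
    df = pd.read_csv(path)
    for col in QUANT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    curves: dict[tuple[str, int], list[CurvePoint]] = {}
    grouped = df.groupby(["Peptide", "Charge", "Dilution"], sort=True)
    for (peptide, charge, dilution), group in grouped:
        key = (str(peptide), int(charge))
        areas = tuple(
            float(a)
            for a in group.sort_values("Replicate")["Area"].tolist()
        )
        curves.setdefault(key, []).append(
            CurvePoint(dilution=float(dilution), replicate_areas=areas)
        )
    return curves


def write_fom_table(
    results: dict[tuple[str, int], FiguresOfMerit], path: str
) -> None:
    """Write per-peptide figures of merit as CSV."""
    rows = []
    for (peptide, charge), fom in sorted(results.items()):
        rows.append(
            {
                "Peptide": peptide,
                "Charge": charge,
                "LoD": fom.lod,
                "LoQ": fom.loq,
                "Slope": fom.slope,
                "NoiseFloor": fom.noise_floor,
                "CVatLoQ": fom.cv_at_loq,
                "Status": fom.status,
            }
        )
    pd.DataFrame(rows, columns=FOM_COLUMNS).to_csv(path, index=False)
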
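"""End-to-end orchestration: library -> candidates -> aligned schedule ->
inclusion list + report, and quant tables -> figures of merit.

Each run writes a JSON manifest next to its outputs recording inputs, the
config snapshot, seeds, and stage counts, so an assay can be regenerated
under new LC conditions from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import calibration, dimethyl, library_io, ranking, rt_alignment, scheduler
from .errors import PrmkitError

__all__ = ["RunManifest", "StageError", "run_schedule_pipeline", "run_calibration_pipeline"]


class StageError(PrmkitError):
    """An error raised inside a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Provenance for one pipeline run."""

    tool: str
    version: str
    inputs: dict
    config: dict
    counts: dict
    outputs: dict
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _stage(name: str):
    """Decorator-free stage wrapper: call fn, re-raise tagged."""

    class _Ctx:
        def __init__(self):
            self.name = name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(self.name, exc) from exc
            return False

    return _Ctx()


def run_schedule_pipeline(
    library_path: str,
    dialect: str,
    fasta_path: str,
    target_accessions: set[str] = frozenset(),
    target_keywords: set[str] = frozenset(),
    include_path: str | None = None,
    exclude_path: str | None = None,
    observed_rt_path: str | None = None,
    out_path: str = "assay.csv",
    report_path: str | None = None,
    config: scheduler.ScheduleConfig | None = None,
    policy: ranking.TransitionPolicy | None = None,
    validate_dimethyl: bool = False,
    max_charge: int = 3,
    min_anchors: int = 10,
    anchor_top_n: int = 200,
) -> RunManifest:
    """Run the full scheduling workflow and write all artifacts."""
    if config is None:
        raise PrmkitError("a ScheduleConfig is required")
    if policy is None:
        policy = ranking.TransitionPolicy()

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _stage("library_io"):
            entries = library_io.read_library(library_path, dialect)
            index = library_io.read_fasta(fasta_path)
            forced = (
                library_io.read_peptide_list(include_path)
                if include_path
                else frozenset()
            )
            excluded = (
                library_io.read_peptide_list(exclude_path)
                if exclude_path
                else frozenset()
            )
            targets = library_io.TargetList(
                accessions=frozenset(target_accessions),
                keywords=frozenset(target_keywords),
                forced_peptides=forced,
                excluded_peptides=excluded,
            )
            resolved = library_io.resolve_targets(index, targets)

        with _stage("ranking"):
            candidates = ranking.build_candidates(
                entries, resolved, targets, policy
            )
            n_excluded = sum(
                1
                for e in entries
                if any(a in resolved for a in e.protein_accessions)
                and e.bare_sequence in targets.excluded_peptides
            )

        with _stage("rt_alignment"):
            if observed_rt_path:
                observed = library_io.read_observed_rt(observed_rt_path)
                anchors = rt_alignment.anchors_from_observed(
                    candidates, observed, top_n=anchor_top_n
                )
                rt_map = rt_alignment.fit_rt_map(anchors, min_anchors=min_anchors)
            else:
                rt_map = rt_alignment.IDENTITY_MAP

        with _stage("scheduler"):
            schedule = scheduler.build_schedule(
                candidates, rt_map, config, n_excluded=n_excluded
            )

        outputs = {"inclusion_list": str(out_path)}
        with _stage("dimethyl"):
            if validate_dimethyl:
                checks = dimethyl.validate_background_exclusion(
                    schedule, max_charge=max_charge
                )
                exclusion_path = str(Path(out_path).with_suffix(".dimethyl.tsv"))
                dimethyl.write_exclusion_report(checks, exclusion_path)
                outputs["dimethyl_report"] = exclusion_path

        with _stage("writers"):
            library_io.write_inclusion_list(schedule, out_path)
            if report_path:
                library_io.write_schedule_report(schedule, report_path)
                outputs["schedule_report"] = str(report_path)

        captured = [str(w.message) for w in caught]

    reasons = list(schedule.rejections.values())
    manifest = RunManifest(
        tool="prmkit.schedule",
        version=__version__,
        inputs={
            "library": str(library_path),
            "dialect": dialect,
            "fasta": str(fasta_path),
            "include": include_path,
            "exclude": exclude_path,
            "observed_rt": observed_rt_path,
        },
        config={
            **dataclasses.asdict(config),
            "policy": dataclasses.asdict(policy),
            "rt_map": dataclasses.asdict(rt_map),
        },
        counts={
            "entries_read": len(entries),
            "targets_resolved": len(resolved),
            "candidates": len(candidates),
            "excluded_peptides_dropped": n_excluded,
            "scheduled": len(schedule.targets),
            "rejected_density": reasons.count(scheduler.REJECT_DENSITY),
            "rejected_protein_cap": reasons.count(scheduler.REJECT_PROTEIN_CAP),
            "rejected_ineligible": reasons.count(scheduler.REJECT_INELIGIBLE),
        },
        outputs=outputs,
        warnings=captured,
    )
    manifest.write(Path(out_path).with_suffix(".manifest.json"))
    return manifest


def run_calibration_pipeline(
    quant_path: str,
    out_path: str,
    cv_threshold: float = 0.20,
    n_boot: int = 100,
    seed: int = 0,
) -> RunManifest:
    """Estimate per-peptide figures of merit and an assay summary."""
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        with _stage("calibration"):
            curves = calibration.read_quant_table(quant_path)
            if not curves:
                raise PrmkitError(f"no curves found in {quant_path}")
            results = {}
            for i, (key, points) in enumerate(sorted(curves.items())):
                results[key] = calibration.figures_of_merit(
                    points,
                    cv_threshold=cv_threshold,
                    n_boot=n_boot,
                    seed=seed + i,
                )
            summary = calibration.summarize_assay(list(results.values()))
        with _stage("writers"):
            calibration.write_fom_table(results, out_path)
        captured = [str(w.message) for w in caught]

    manifest = RunManifest(
        tool="prmkit.calibrate",
        version=__version__,
        inputs={"quant": str(quant_path)},
        config={"cv_threshold": cv_threshold, "n_boot": n_boot, "seed": seed},
        counts={
            "n_peptides": summary["n_peptides"],
            "n_loq_defined": summary["n_peptides"]
            - round(summary["fraction_loq_undefined"] * summary["n_peptides"]),
        },
        outputs={"figures_of_merit": str(out_path), "summary": summary},
        warnings=captured,
    )
    manifest.write(Path(out_path).with_suffix(".manifest.json"))
    return manifest
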
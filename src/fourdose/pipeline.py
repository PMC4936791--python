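"""End-to-end experiment: cohort -> four plans per case -> simulated 4D
delivery -> accumulation -> endpoints -> paired statistics.

Per case, four step-and-shoot plans are prepared on the peak-exhale phase —
conventional (ITV + margin) and tracked (MTV + margin) targets, each
optimized with and without the 1.5 T field — and normalized to 54 Gy in 3
fractions to 95% of their own PTV.  Conventional plans are delivered to all
breathing phases with unchanged apertures; tracked plans are adapted per
phase by the beams-eye-view target translation with MLC resnapping.  Each
phase dose is warped to the reference phase and accumulated with weight
1/n_phases, endpoints are extracted per arm, and the cohort is compared with
the paired statistical framework.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dose_engine import BeamModel, DoseEngine, FieldConfig
from .fourd import ARM_NAMES, accumulate, evaluate_case
from .machine import MachineModel, equidistant_beams
from .phantom import Phantom4D, PhantomConfig, make_cohort
from .planning import ConstraintReport, ObjectiveSet, check_constraints, make_plan
from .stats_compare import ComparisonReport, compare_arms, motion_regression
from .targets import build_target_set
from .tracking import build_tracked_plans, phase_shifts

__all__ = ["RunConfig", "CaseResult", "ExperimentResult", "run_case", "run_experiment"]

log = logging.getLogger("fourdose")

_ARMS = (
    # (arm name, strategy, field strength)
    ("conv_0T", "conv", 0.0),
    ("conv_1.5T", "conv", 1.5),
    ("track_0T", "track", 0.0),
    ("track_1.5T", "track", 1.5),
)


@dataclass(frozen=True)
class RunConfig:
    """One experiment run; every simulated quantity derives from this + seeds."""

    n_cases: int = 9
    seed: int = 0
    motion_range: tuple[float, float] = (1.5, 14.1)
    volume_range: tuple[float, float] = (3.3, 25.5)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    machine: MachineModel = field(default_factory=MachineModel)
    beam_model: BeamModel = field(default_factory=BeamModel)
    objectives: ObjectiveSet = field(default_factory=ObjectiveSet)
    n_beams: int = 9
    n_subsegments: int = 2
    margin_mm: float = 5.0
    field_strength: float = 1.5
    engine_mode: str = "deterministic"
    resnap: str = "interpolate"
    regression_contrast: str = "1.5T"  # '0T' or '1.5T' tracked-conventional benefit
    save_phase_doses: bool = False
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, val in doc.items():
            if key == "phantom":
                val = PhantomConfig(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in val.items()})
            elif key == "machine":
                val = MachineModel(**val)
            elif key == "beam_model":
                val = BeamModel(**val)
            elif key == "objectives":
                val = ObjectiveSet(**val)
            elif isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CaseResult:
    case_id: int
    phantom: Phantom4D
    plans: dict[str, object]
    accumulated: dict[str, np.ndarray]
    endpoints: pd.DataFrame
    constraint_reports: dict[str, ConstraintReport]
    phase_doses: dict[str, list[np.ndarray]] | None = None
    motion_amplitude: float = 0.0


@dataclass
class ExperimentResult:
    endpoint_table: pd.DataFrame
    report: ComparisonReport | None
    cases: list[CaseResult]
    failures: dict[int, str]
    config: RunConfig


def run_case(
    phantom: Phantom4D,
    config: RunConfig,
    case_id: int = 0,
    engine: DoseEngine | None = None,
) -> CaseResult:
    """Simulate all four delivery arms of one case."""
    t0 = time.time()
    eng = engine or DoseEngine(
        config.machine, config.beam_model, phantom.voxel_size,
        config.engine_mode, config.seed + case_id,
    )
    eng.clear_cache()
    targets = build_target_set(
        phantom.gtv_masks, phantom.reference_phase, config.margin_mm, phantom.voxel_size
    )
    beams = equidistant_beams(config.n_beams)
    ref_density = phantom.reference_density
    structures = {
        "gtv": targets.gtv_ref,
        "body": phantom.organ_masks["body"],
        "lungs": phantom.organ_masks["lungs"],
        "skin": phantom.organ_masks["skin"],
        "vessels": phantom.organ_masks.get(
            "vessels", np.zeros_like(targets.gtv_ref)
        ),
    }
    fields = {0.0: FieldConfig(b=0.0), config.field_strength: FieldConfig(b=config.field_strength)}
    ptv_for = {"conv": targets.ptv_itv, "track": targets.ptv_mtv}
    label_for = {"conv": f"ITV+{config.margin_mm:g}mm", "track": f"MTV+{config.margin_mm:g}mm"}
    shifts = phase_shifts(phantom, beams)

    plans, accumulated, reports = {}, {}, {}
    phase_doses: dict[str, list[np.ndarray]] = {}
    ptv_masks = {}
    for arm, strategy, b in _ARMS:
        fieldcfg = fields[b]
        plan, _ = make_plan(
            ptv_for[strategy], structures, ref_density, beams, eng, fieldcfg,
            config.objectives, label_for[strategy], config.n_subsegments,
            seed=config.seed + case_id,
            phase_key=("ref", case_id),
        )
        plans[arm] = plan
        ptv_masks[arm] = ptv_for[strategy]

        if strategy == "track":
            per_phase_plans = build_tracked_plans(plan, shifts, config.machine, config.resnap)
        else:
            per_phase_plans = [plan] * phantom.n_phases
        doses = [
            eng.plan_dose(per_phase_plans[p], phantom.phases[p], fieldcfg,
                          phase_key=(p, case_id), phase_index=p).values
            for p in range(phantom.n_phases)
        ]
        accumulated[arm] = accumulate(doses, phantom.dvfs, phantom.voxel_size)
        if config.save_phase_doses:
            phase_doses[arm] = doses
        reports[arm] = check_constraints(
            accumulated[arm],
            {**structures, "ptv": ptv_for[strategy]},
            config.objectives.constraint_table,
            plan.prescription.total_dose,
        )
        if not reports[arm].overall_pass:
            log.warning("case %d arm %s: constraint violations\n%s",
                        case_id, arm, reports[arm].to_text())

    endpoints = evaluate_case(
        accumulated, structures, ref_density, phantom.voxel_volume_cc, ptv_masks,
    )
    endpoints.insert(0, "case", case_id)
    endpoints.insert(1, "motion_mm", phantom.motion_amplitude())
    log.info("case %d finished in %.1f s", case_id, time.time() - t0)
    return CaseResult(
        case_id=case_id,
        phantom=phantom,
        plans=plans,
        accumulated=accumulated,
        endpoints=endpoints,
        constraint_reports=reports,
        phase_doses=phase_doses or None,
        motion_amplitude=phantom.motion_amplitude(),
    )


def run_experiment(
    config: RunConfig,
    cohort: list[Phantom4D] | None = None,
) -> ExperimentResult:
    """Run the whole cohort and the paired statistical comparison.

    A failing case is logged and skipped; statistics require at least two
    successful cases, otherwise they are skipped with an explicit notice.
    """
    if cohort is None:
        cohort = make_cohort(
            config.n_cases, config.motion_range, config.volume_range,
            config.seed, config.phantom,
        )
    engine = DoseEngine(config.machine, config.beam_model,
                        cohort[0].voxel_size, config.engine_mode, config.seed)
    cases: list[CaseResult] = []
    failures: dict[int, str] = {}
    for i, phantom in enumerate(cohort):
        try:
            cases.append(run_case(phantom, config, case_id=i, engine=engine))
        except Exception as exc:  # crash isolation: other cases continue
            log.exception("case %d failed", i)
            failures[i] = f"{type(exc).__name__}: {exc}"

    if not cases:
        raise RuntimeError("no case completed successfully")
    table = pd.concat([c.endpoints for c in cases]).reset_index()

    report = None
    if len(cases) >= 2:
        report = compare_arms(table.set_index(["case", "arm"]).reset_index(),
                              seed=config.seed)
        arm_t = f"track_{config.regression_contrast}"
        arm_c = f"conv_{config.regression_contrast}"
        wide = table.pivot(index="case", columns="arm")
        motion = wide[("motion_mm", arm_t)].to_numpy()
        if len(cases) >= 3 and motion.std() > 0:
            for ep in ("lung_mean", "integral_energy_j"):
                diff = (wide[(ep, arm_t)] - wide[(ep, arm_c)]).to_numpy()
                report.regressions.append(motion_regression(motion, diff, ep))
    else:
        log.warning("fewer than 2 successful cases: statistics skipped")

    result = ExperimentResult(table, report, cases, failures, config)
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: ExperimentResult, outdir: Path) -> None:
    from . import gridio

    outdir.mkdir(parents=True, exist_ok=True)
    result.endpoint_table.to_csv(outdir / "endpoints.csv", index=False)
    manifest = {
        "config": result.config.to_dict(),
        "n_cases_requested": result.config.n_cases,
        "n_cases_completed": len(result.cases),
        "failures": result.failures,
        "files": {},
        "successful": not result.failures,
    }
    for case in result.cases:
        cdir = outdir / f"case{case.case_id:02d}"
        cdir.mkdir(exist_ok=True)
        files = []
        for arm, plan in case.plans.items():
            path = cdir / f"plan_{arm}.json"
            gridio.save_plan(plan, path)
            files.append(path.name)
        for arm, dose in case.accumulated.items():
            from .dose_engine import DoseGrid
            path = cdir / f"accumulated_{arm}.nrrd"
            gridio.save_dose(
                DoseGrid(dose, result.cases[0].phantom.reference_phase,
                         1.5 if "1.5" in arm else 0.0, "total",
                         case.phantom.voxel_size),
                path,
            )
            files.append(path.name)
        if case.phase_doses:
            from .dose_engine import DoseGrid
            for arm, doses in case.phase_doses.items():
                for p, d in enumerate(doses):
                    path = cdir / f"dose_{arm}_p{p:02d}.nrrd"
                    gridio.save_dose(
                        DoseGrid(d, p, 1.5 if "1.5" in arm else 0.0, "total",
                                 case.phantom.voxel_size), path)
                    files.append(path.name)
        for arm, rep in case.constraint_reports.items():
            path = cdir / f"constraints_{arm}.json"
            path.write_text(json.dumps(rep.checks, indent=1))
            files.append(path.name)
        manifest["files"][f"case{case.case_id:02d}"] = files
    if result.report is not None:
        (outdir / "comparison.json").write_text(
            result.report.to_frame().to_json(orient="records", indent=1)
        )
        (outdir / "comparison.txt").write_text(result.report.summary())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
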
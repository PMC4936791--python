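"""Step-and-shoot plan generation, inverse weight optimization,
prescription normalization and constraint checking.

Plans are created on the reference (peak-exhale) phase.  Segment shapes are
conformal apertures plus shrunken sub-apertures per beam; segment weights are
found by projected gradient descent on a one-sided quadratic penalty
(underdose on the PTV, overdose on the PTV ceiling and organs at risk)
against a precomputed dose-influence matrix.  The influence matrix is always
computed with the plan's own magnetic-field configuration, so the field is
genuinely inside the optimization loop.  Finally each plan is normalized so
that 95% of its PTV receives the prescription dose (54 Gy in 3 fractions),
which by linearity of the deterministic engine is an exact rescaling.

The shipped organ-at-risk thresholds are configuration defaults in the
spirit of the RTOG 1021 lung SBRT guideline, not authoritative reprints of
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dose_engine import DoseEngine, FieldConfig
from .fourd import metric_Dx, metric_mean, volume_at_least
from .machine import Beam, MachineModel, Prescription, Segment, TreatmentPlan, conformal_segment, validate_segment

__all__ = [
    "OarTerm",
    "ObjectiveSet",
    "ConstraintCheck",
    "ConstraintReport",
    "generate_segments",
    "build_objective_rows",
    "optimize_weights",
    "normalize_plan",
    "check_constraints",
    "make_plan",
]


@dataclass(frozen=True)
class OarTerm:
    structure: str
    kind: str          # 'mean' | 'overdose'
    weight: float
    threshold_gy: float


@dataclass(frozen=True)
class ConstraintCheck:
    name: str
    structure: str
    metric: str        # 'Vx' | 'Dx' | 'mean' | 'r50'
    x: float | None
    threshold: float
    sense: str         # 'ge' (value must be >= threshold) or 'le'


def _default_oar_terms() -> tuple[OarTerm, ...]:
    return (
        OarTerm("lungs", "overdose", 0.01, 5.0),
        OarTerm("skin", "overdose", 0.01, 15.0),
        OarTerm("vessels", "overdose", 0.01, 20.0),
        OarTerm("body", "overdose", 0.005, 27.0),
    )


def _default_constraints() -> tuple[ConstraintCheck, ...]:
    # configuration defaults in the spirit of RTOG 1021; not authoritative
    return (
        ConstraintCheck("gtv_coverage", "gtv", "Vx", 54.0, 100.0, "ge"),
        ConstraintCheck("r50_spillage", "ptv", "r50", None, 6.0, "le"),
        ConstraintCheck("skin_d2", "skin", "Dx", 2.0, 40.0, "le"),
        ConstraintCheck("lung_mean", "lungs", "mean", None, 8.0, "le"),
    )


@dataclass(frozen=True)
class ObjectiveSet:
    """Optimization objectives and the constraint table evaluated afterwards."""

    ptv_min_dose: float = 54.0
    ptv_under_weight: float = 1.0
    ptv_max_dose_target: float = 58.0   # 'similar maximum target dose' ceiling
    ptv_over_weight: float = 1.0
    oar_terms: tuple[OarTerm, ...] = field(default_factory=_default_oar_terms)
    constraint_table: tuple[ConstraintCheck, ...] = field(default_factory=_default_constraints)
    n_iterations: int = 500
    oar_sample_size: int = 3000

    def __post_init__(self) -> None:
        if self.ptv_under_weight < 0 or self.ptv_over_weight < 0:
            raise ValueError("weights must be non-negative")
        for t in self.oar_terms:
            if t.weight < 0 or t.threshold_gy < 0:
                raise ValueError("OAR weights and thresholds must be non-negative")


@dataclass
class ConstraintReport:
    checks: list[dict]

    @property
    def overall_pass(self) -> bool:
        return all(c["pass"] for c in self.checks)

    def to_text(self) -> str:
        lines = [f"{'check':<16}{'value':>10}{'limit':>10}  status"]
        for c in self.checks:
            status = "pass" if c["pass"] else "FAIL"
            lines.append(f"{c['name']:<16}{c['value']:>10.2f}{c['threshold']:>10.2f}  {status}")
        lines.append(f"overall: {'pass' if self.overall_pass else 'FAIL'}")
        return "\n".join(lines)


def generate_segments(
    ptv_mask: np.ndarray,
    beams: list[Beam],
    machine: MachineModel,
    voxel_size: float,
    n_subsegments: int = 2,
    shrink_fraction: float = 0.35,
    aperture_margin_mm: float = 5.0,
) -> list[Segment]:
    """Conformal aperture plus eroded sub-apertures per beam.

    The base aperture carries an isotropic BEV block margin (default 5 mm,
    about 1.7 penumbra sigmas) so the field's 50% level does not sit on the
    PTV surface.  Sub-segment ``j`` shrinks every leaf opening toward its
    center by ``j * shrink_fraction`` of its half-width, giving the optimizer
    simple modulation degrees of freedom.  All returned segments are
    machine-valid.
    """
    if not ptv_mask.any():
        raise ValueError("empty PTV")
    segments: list[Segment] = []
    for bi, beam in enumerate(beams):
        base = conformal_segment(ptv_mask, beam, machine, voxel_size,
                                 aperture_margin_mm)
        base.beam_index = bi
        segments.append(base)
        for j in range(1, n_subsegments + 1):
            edges = np.array(base.leaf_edges, dtype=float)
            center = edges.mean(axis=1)
            half = (edges[:, 1] - edges[:, 0]) / 2.0
            h = half * (1.0 - shrink_fraction * j)
            h = np.maximum(h, 0.0)
            sub = Segment(bi, np.stack([center - h, center + h], axis=1), 1.0)
            bad = validate_segment(sub, machine)
            if bad:
                raise ValueError(f"sub-segment violates machine limits: {bad}")
            segments.append(sub)
    return segments


def build_objective_rows(
    structures: dict[str, np.ndarray],
    ptv_mask: np.ndarray,
    objectives: ObjectiveSet,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Sampled voxel indices and per-row penalty vectors for the optimizer.

    All PTV voxels are kept; each OAR is subsampled (seeded) to at most
    ``oar_sample_size`` voxels, its penalty weight scaled by the inverse
    sampling fraction so the objective estimates the full-volume penalty.
    """
    rng = np.random.default_rng(seed)
    idx_list = [np.argwhere(ptv_mask)]
    low = [np.full(idx_list[0].shape[0], objectives.ptv_min_dose)]
    w_low = [np.full(idx_list[0].shape[0], objectives.ptv_under_weight)]
    high = [np.full(idx_list[0].shape[0], objectives.ptv_max_dose_target)]
    w_high = [np.full(idx_list[0].shape[0], objectives.ptv_over_weight)]

    for term in objectives.oar_terms:
        mask = structures.get(term.structure)
        if mask is None or not mask.any() or term.weight == 0:
            continue
        mask = mask & ~ptv_mask
        idx = np.argwhere(mask)
        if idx.shape[0] == 0:
            continue
        n = min(objectives.oar_sample_size, idx.shape[0])
        sel = rng.choice(idx.shape[0], size=n, replace=False)
        idx = idx[np.sort(sel)]
        scale = mask.sum() / n
        idx_list.append(idx)
        low.append(np.zeros(n))
        w_low.append(np.zeros(n))
        high.append(np.full(n, term.threshold_gy))
        w_high.append(np.full(n, term.weight * scale))

    rows = {
        "low": np.concatenate(low),
        "w_low": np.concatenate(w_low),
        "high": np.concatenate(high),
        "w_high": np.concatenate(w_high),
    }
    return np.concatenate(idx_list, axis=0), rows


def optimize_weights(
    influence: np.ndarray,
    rows: dict[str, np.ndarray],
    n_iterations: int = 500,
) -> tuple[np.ndarray, float]:
    """Projected gradient descent on the one-sided quadratic penalty.

    Deterministic: zero initialization, fixed iteration budget, step size
    1/L with L a power-iteration bound on the curvature.  Returns the
    non-negative weights and the final objective value.
    """
    a = np.asarray(influence, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] == 0:
        raise ValueError("influence matrix must be (n_voxels, n_segments)")
    if not np.any(a):
        raise ValueError("degenerate problem: all-zero influence")
    low, w_low = rows["low"], rows["w_low"]
    high, w_high = rows["high"], rows["w_high"]

    wmax = w_low + w_high
    v = np.ones(a.shape[1])
    for _ in range(30):
        v = a.T @ (wmax * (a @ v))
        nrm = np.linalg.norm(v)
        if nrm == 0:
            break
        v /= nrm
    lam = float(v @ (a.T @ (wmax * (a @ v)))) if np.linalg.norm(v) > 0 else 1.0
    lip = max(2.0 * lam, 1e-12)

    w = np.zeros(a.shape[1])
    for _ in range(n_iterations):
        d = a @ w
        under = np.maximum(low - d, 0.0)
        over = np.maximum(d - high, 0.0)
        grad = a.T @ (2.0 * (w_high * over - w_low * under))
        w = np.maximum(w - grad / lip, 0.0)

    d = a @ w
    obj = float(np.sum(w_low * np.maximum(low - d, 0.0) ** 2)
                + np.sum(w_high * np.maximum(d - high, 0.0) ** 2))
    return w, obj


def objective_value(influence: np.ndarray, rows: dict[str, np.ndarray], w: np.ndarray) -> float:
    d = np.asarray(influence) @ w
    return float(
        np.sum(rows["w_low"] * np.maximum(rows["low"] - d, 0.0) ** 2)
        + np.sum(rows["w_high"] * np.maximum(d - rows["high"], 0.0) ** 2)
    )


def normalize_plan(
    plan: TreatmentPlan,
    reference_dose: np.ndarray,
    ptv_mask: np.ndarray,
) -> tuple[TreatmentPlan, float]:
    """Scale all segment weights so D95(PTV) equals the prescription dose.

    ``reference_dose`` must be the plan's own dose on the planning phase; by
    linearity of the deterministic engine the recomputed D95 is then exactly
    the prescription.  Returns the rescaled plan (a copy) and the factor.
    """
    cov = plan.prescription.coverage_percent
    d_cov = metric_Dx(reference_dose, ptv_mask, cov)
    if d_cov <= 0:
        raise ValueError("D95 of the reference dose is zero; cannot normalize")
    factor = plan.prescription.total_dose / d_cov
    out = plan.copy()
    out.scale_weights(factor)
    out.log.append(f"normalized: factor {factor:.6f} to D{cov:g} = "
                   f"{plan.prescription.total_dose} Gy")
    return out, factor


def check_constraints(
    dose: np.ndarray,
    structures: dict[str, np.ndarray],
    constraint_table: tuple[ConstraintCheck, ...],
    prescription_gy: float = 54.0,
) -> ConstraintReport:
    """Evaluate the configured checks; failing plans are reported, not rejected."""
    checks = []
    for c in constraint_table:
        if c.metric == "r50":
            if "ptv" not in structures:
                raise KeyError("r50 check requires a 'ptv' structure")
            value = volume_at_least(dose, prescription_gy / 2.0) / max(
                int(structures["ptv"].sum()), 1
            )
        else:
            if c.structure not in structures:
                raise KeyError(f"constraint {c.name}: missing structure {c.structure}")
            mask = structures[c.structure]
            if c.metric == "Vx":
                vals = np.asarray(dose)[mask.astype(bool)]
                value = 100.0 * float((vals >= c.x).mean())
            elif c.metric == "Dx":
                value = metric_Dx(dose, mask, c.x)
            elif c.metric == "mean":
                value = metric_mean(dose, mask)
            else:
                raise ValueError(f"unknown metric {c.metric}")
        ok = value >= c.threshold if c.sense == "ge" else value <= c.threshold
        checks.append({"name": c.name, "value": float(value),
                       "threshold": c.threshold, "pass": bool(ok)})
    return ConstraintReport(checks)


def make_plan(
    ptv_mask: np.ndarray,
    structures: dict[str, np.ndarray],
    density: np.ndarray,
    beams: list[Beam],
    engine: DoseEngine,
    fieldcfg: FieldConfig,
    objectives: ObjectiveSet | None = None,
    target_label: str = "ITV+5mm",
    n_subsegments: int = 2,
    seed: int = 0,
    phase_key=None,
    aperture_margin_mm: float = 5.0,
) -> tuple[TreatmentPlan, float]:
    """Full planning chain: segments -> influence -> weights -> normalization.

    Returns the normalized plan and the pre-normalization objective value.
    """
    obj = objectives if objectives is not None else ObjectiveSet()
    segments = generate_segments(ptv_mask, beams, engine.machine, engine.voxel_size,
                                 n_subsegments, aperture_margin_mm=aperture_margin_mm)
    sample_idx, rows = build_objective_rows(structures, ptv_mask, obj, seed)
    infl = engine.influence(segments, beams, density, fieldcfg, sample_idx, phase_key)
    weights, final_obj = optimize_weights(infl, rows, obj.n_iterations)
    for seg, w in zip(segments, weights):
        seg.weight = float(w)
    plan = TreatmentPlan(
        beams=beams,
        segments=segments,
        prescription=Prescription(),
        target_label=target_label,
        field_strength=fieldcfg.b,
    )
    ref_dose = engine.plan_dose(plan, density, fieldcfg, phase_key)
    plan, factor = normalize_plan(plan, ref_dose.values, ptv_mask)
    return plan, final_obj
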
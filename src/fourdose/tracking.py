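"""Real-time MLC tumor tracking: per-phase aperture adaptation.

For tracked deliveries every segment is translated by the tumor's
beams-eye-view (BEV) displacement in each breathing phase.  The leaf-travel
component is continuous and applied exactly; the leaf-stack component is
quantized by the finite 7.15 mm leaf width and must be *resnapped* to the
leaf grid.

Resnapping rule: writing the stack shift as ``s = (k + f) * leaf_width`` with
integer ``k`` and fraction ``f in [0, 1)``, the adapted opening of leaf pair
``i`` interpolates the source openings of pairs ``i - k`` and ``i - k - 1``
with weights ``(1 - f)`` and ``f``.  When only one source pair is open the
new pair copies it iff its overlap fraction is at least one half, else it
closes; at integer shifts the rule is an exact row permutation and at zero
shift it is the identity.  Tracking uses the phantom's ground-truth tumor
centroids (perfect localization, no leaf-speed or latency limits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .machine import Beam, MachineModel, Segment, TreatmentPlan, bev_project
from .phantom import Phantom4D
from .targets import TargetSet

__all__ = ["PhaseShift", "phase_shifts", "adapt_segment", "build_tracked_plans"]


@dataclass
class PhaseShift:
    phase_index: int
    translation_3d: np.ndarray          # mm, phase GTV centroid - reference centroid
    bev_shifts: list[tuple[float, float]]  # per beam: (leaf travel, leaf stack) mm


def _centroid_mm(mask: np.ndarray, voxel_size: float) -> np.ndarray:
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty GTV mask")
    c = idx.mean(axis=0)
    return (c - (np.asarray(mask.shape) - 1) / 2.0) * voxel_size


def phase_shifts(
    phantom: Phantom4D,
    beams: list[Beam],
    use_analytic_centroids: bool = True,
) -> list[PhaseShift]:
    """Per-phase 3D tumor translation and its per-beam BEV components.

    Translations are continuous (no rounding).  By default the phantom's
    analytic centroid trajectory is used (perfect localization); the mask
    centroids give the same values to within voxelization error.
    """
    if use_analytic_centroids and phantom.tumor_centroids is not None:
        cents = np.asarray(phantom.tumor_centroids, dtype=float)
    else:
        cents = np.stack(
            [_centroid_mm(m, phantom.voxel_size) for m in phantom.gtv_masks]
        )
    ref = cents[phantom.reference_phase]
    out = []
    for p in range(phantom.n_phases):
        t = cents[p] - ref
        bev = [bev_project(t, beam) for beam in beams]
        out.append(PhaseShift(p, t, bev))
    return out


def adapt_segment(
    segment: Segment,
    bev_shift: tuple[float, float],
    machine: MachineModel,
    resnap: str = "interpolate",
) -> tuple[Segment, list[str]]:
    """Translate a segment by a BEV shift and resnap to the leaf grid.

    Returns the adapted segment and a list of warnings (apertures clamped at
    the field limits).  ``resnap='nearest'`` substitutes a nearest-row snap
    for sensitivity analyses.
    """
    du, dv = bev_shift
    edges = np.asarray(segment.leaf_edges, dtype=float)
    n = machine.n_leaf_pairs
    open_src = segment.open_rows()
    warnings: list[str] = []

    # leaf-travel component: continuous, clamp at field limits
    half_par = machine.max_field_parallel / 2.0
    new_edges = edges.copy()
    new_edges[open_src] += du
    if np.any(new_edges[open_src] < -half_par) or np.any(new_edges[open_src] > half_par):
        warnings.append(f"aperture clamped at leaf-travel limit (shift {du:+.1f} mm)")
        new_edges = np.clip(new_edges, -half_par, half_par)

    # leaf-stack component: resnap to the leaf grid
    w = machine.leaf_width_iso
    if resnap == "nearest":
        k = int(np.rint(dv / w))
        f = 0.0
    else:
        k = int(np.floor(dv / w))
        f = dv / w - k

    out = np.empty_like(new_edges)
    closed_at = new_edges[~open_src][:, 0] if np.any(~open_src) else np.array([0.0])
    fill = float(np.median(closed_at))
    for i in range(n):
        ia, ib = i - k, i - k - 1           # sources with weights (1 - f), f
        a_open = 0 <= ia < n and open_src[ia]
        b_open = 0 <= ib < n and open_src[ib]
        if f == 0.0:
            if a_open:
                out[i] = new_edges[ia]
            else:
                out[i] = (fill, fill)
        elif a_open and b_open:
            out[i] = (1.0 - f) * new_edges[ia] + f * new_edges[ib]
        elif a_open:
            out[i] = new_edges[ia] if (1.0 - f) >= 0.5 else (fill, fill)
        elif b_open:
            out[i] = new_edges[ib] if f >= 0.5 else (fill, fill)
        else:
            out[i] = (fill, fill)

    adapted = Segment(segment.beam_index, out, segment.weight)
    return adapted, warnings


def build_tracked_plans(
    plan: TreatmentPlan,
    shifts: list[PhaseShift],
    machine: MachineModel,
    resnap: str = "interpolate",
) -> list[TreatmentPlan]:
    """One adapted plan per breathing phase; segment weights are preserved."""
    plans = []
    for shift in shifts:
        p = plan.copy()
        new_segments = []
        for seg in p.segments:
            adapted, warns = adapt_segment(
                seg, shift.bev_shifts[seg.beam_index], machine, resnap
            )
            for msg in warns:
                p.log.append(f"phase {shift.phase_index}: {msg}")
            new_segments.append(adapted)
        p.segments = new_segments
        p.log.append(
            f"tracked phase {shift.phase_index}: shift "
            f"{np.round(shift.translation_3d, 2).tolist()} mm"
        )
        plans.append(p)
    return plans
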
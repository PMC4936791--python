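"""MR-linac beam and multileaf-collimator (MLC) geometry.

Models the treatment head of a 1.5 T MR-linac: a 7 MV beam shaped by an MLC
of 160 leaves (80 opposing pairs) with an isocenter-projected leaf width of
7.15 mm, collimator fixed at 90 deg (IEC-61217).  With that collimator angle
the leaves travel in the transverse plane while the leaf stack runs along the
superior-inferior axis — parallel to the magnetic field and to the dominant
direction of respiratory tumor motion, so stack-direction tracking shifts
must be resnapped to the finite leaf grid.

Coordinate conventions (documented once, used everywhere):

* patient axes: x to patient left, y anterior, z superior;
* gantry angle ``theta`` (deg): beam direction
  ``d = (-sin t, -cos t, 0)`` — at gantry 0 the beam enters anteriorly;
* beams-eye-view (BEV) axes: leaf travel ``u = (cos t, -sin t, 0)`` and leaf
  stack ``v = z``; at gantry 0 the mapping (x, z) -> (u, v) is the identity.

The projection is parallel (non-divergent): the tracking logic only needs
rigid BEV translations, for which beam divergence is a second-order effect
at lung depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MachineModel",
    "Beam",
    "Segment",
    "Prescription",
    "TreatmentPlan",
    "equidistant_beams",
    "beam_axes",
    "bev_project",
    "conformal_segment",
    "validate_segment",
]


@dataclass(frozen=True)
class MachineModel:
    """MLC and field-size limits of the MR-linac head.

    80 leaf pairs x 7.15 mm span 57.20 cm, marginally more than the 57.15 cm
    maximum perpendicular field; the machine enforces the 57.15 cm clamp and
    the outermost rows are simply never fully usable.
    """

    n_leaf_pairs: int = 80
    leaf_width_iso: float = 7.15           # mm at isocenter
    max_field_parallel: float = 272.0      # mm, along leaf travel
    max_field_perp: float = 571.5          # mm, along leaf stack
    collimator_angle: float = 90.0         # deg, fixed (IEC-61217)
    nominal_energy_label: str = "7 MV"
    source_axis_distance: float = 1000.0   # mm, not stated by vendor data here
    cryostat_attenuation: dict[float, float] | None = None  # gantry deg -> transmission

    def __post_init__(self) -> None:
        if self.n_leaf_pairs * self.leaf_width_iso < self.max_field_perp:
            raise ValueError("leaf stack does not cover the perpendicular field size")

    def leaf_centers(self) -> np.ndarray:
        """Stack-axis (z) centers of the leaf rows, mm at isocenter."""
        i = np.arange(self.n_leaf_pairs)
        return (i - (self.n_leaf_pairs - 1) / 2.0) * self.leaf_width_iso

    def row_of(self, z: np.ndarray | float) -> np.ndarray:
        """Leaf-row index containing stack position ``z`` (mm)."""
        idx = np.rint(np.asarray(z) / self.leaf_width_iso + (self.n_leaf_pairs - 1) / 2.0)
        return idx.astype(int)

    def transmission(self, gantry_angle: float) -> float:
        """Scalar cryostat transmission for a gantry angle (default 1.0)."""
        if not self.cryostat_attenuation:
            return 1.0
        angles = np.array(sorted(self.cryostat_attenuation))
        vals = np.array([self.cryostat_attenuation[a] for a in angles])
        # nearest-angle lookup on the circle
        d = np.abs((angles - gantry_angle + 180.0) % 360.0 - 180.0)
        return float(vals[np.argmin(d)])


@dataclass(frozen=True)
class Beam:
    gantry_angle: float  # deg in [0, 360)
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)  # fixed bore center

    def __post_init__(self) -> None:
        object.__setattr__(self, "gantry_angle", float(self.gantry_angle) % 360.0)


@dataclass
class Segment:
    """One step-and-shoot aperture: per-leaf-pair openings and a fluence weight."""

    beam_index: int
    leaf_edges: np.ndarray  # (n_leaf_pairs, 2) mm at isocenter, [left, right]
    weight: float = 1.0

    def open_rows(self, tol: float = 1e-9) -> np.ndarray:
        e = np.asarray(self.leaf_edges)
        return (e[:, 1] - e[:, 0]) > tol

    def copy(self) -> "Segment":
        return Segment(self.beam_index, np.array(self.leaf_edges, dtype=float), self.weight)


@dataclass(frozen=True)
class Prescription:
    total_dose: float = 54.0      # Gy
    n_fractions: int = 3
    coverage_percent: float = 95.0  # of the PTV volume


@dataclass
class TreatmentPlan:
    beams: list[Beam]
    segments: list[Segment]
    prescription: Prescription = field(default_factory=Prescription)
    target_label: str = "ITV+5mm"
    field_strength: float = 0.0  # tesla
    log: list[str] = field(default_factory=list)

    def scale_weights(self, factor: float) -> None:
        for s in self.segments:
            s.weight *= factor

    def segments_of_beam(self, beam_index: int) -> list[Segment]:
        return [s for s in self.segments if s.beam_index == beam_index]

    def copy(self) -> "TreatmentPlan":
        return TreatmentPlan(
            beams=list(self.beams),
            segments=[s.copy() for s in self.segments],
            prescription=self.prescription,
            target_label=self.target_label,
            field_strength=self.field_strength,
            log=list(self.log),
        )


def equidistant_beams(n: int, start_angle: float = 0.0) -> list[Beam]:
    """``n`` beams at equal gantry spacing of 360/n degrees."""
    if n < 1:
        raise ValueError("need at least one beam")
    return [Beam(start_angle + k * 360.0 / n) for k in range(n)]


def beam_axes(beam: Beam) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors (leaf travel u, beam direction d, leaf stack v) in patient axes."""
    t = np.deg2rad(beam.gantry_angle)
    u = np.array([np.cos(t), -np.sin(t), 0.0])
    d = np.array([-np.sin(t), -np.cos(t), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    return u, d, v


def bev_project(point: Sequence[float], beam: Beam) -> tuple[float, float]:
    """Parallel projection of a patient-frame point (mm) into BEV (u, v) mm."""
    p = np.asarray(point, dtype=float) - np.asarray(beam.isocenter, dtype=float)
    u, _, v = beam_axes(beam)
    return float(p @ u), float(p @ v)


def conformal_segment(
    ptv_mask: np.ndarray,
    beam: Beam,
    machine: MachineModel,
    voxel_size: float,
    aperture_margin_mm: float = 0.0,
) -> Segment:
    """Aperture conforming to the BEV silhouette of the PTV.

    Per leaf row, the opening spans the projected PTV voxel centers whose
    stack position falls within the row expanded by the aperture margin,
    padded along the travel axis by half a voxel plus the margin — an
    isotropic BEV block margin (e.g. to cover the penumbra).  Rows without
    target close at the silhouette's travel-axis midline.
    """
    idx = np.argwhere(ptv_mask)
    if idx.size == 0:
        raise ValueError("empty PTV mask")
    shape = ptv_mask.shape
    centers = (idx - (np.asarray(shape) - 1) / 2.0) * voxel_size
    u_ax, _, v_ax = beam_axes(beam)
    us = centers @ u_ax
    zs = centers @ v_ax
    rows = machine.row_of(zs)
    if rows.min() < 0 or rows.max() >= machine.n_leaf_pairs:
        raise ValueError("PTV projects outside the leaf stack")

    pad = voxel_size / 2.0 + aperture_margin_mm
    half_par = machine.max_field_parallel / 2.0
    half_w = machine.leaf_width_iso / 2.0
    row_centers = machine.leaf_centers()
    mid = float((us.min() + us.max()) / 2.0)
    edges = np.tile([mid, mid], (machine.n_leaf_pairs, 1)).astype(float)
    r_lo = max(int(rows.min()) - int(np.ceil(aperture_margin_mm / machine.leaf_width_iso)), 0)
    r_hi = min(int(rows.max()) + int(np.ceil(aperture_margin_mm / machine.leaf_width_iso)),
               machine.n_leaf_pairs - 1)
    for r in range(r_lo, r_hi + 1):
        sel = np.abs(zs - row_centers[r]) <= half_w + aperture_margin_mm
        if not sel.any():
            continue
        lo = max(us[sel].min() - pad, -half_par)
        hi = min(us[sel].max() + pad, half_par)
        edges[r] = (lo, hi)

    seg = Segment(beam_index=0, leaf_edges=edges, weight=1.0)
    violations = validate_segment(seg, machine)
    if violations:
        raise ValueError(f"PTV exceeds machine field limits: {violations}")
    return seg


def validate_segment(segment: Segment, machine: MachineModel) -> list[str]:
    """Report machine-limit violations; an empty list means the segment is valid."""
    out: list[str] = []
    e = np.asarray(segment.leaf_edges, dtype=float)
    if e.shape != (machine.n_leaf_pairs, 2):
        return [f"leaf_edges shape {e.shape} != ({machine.n_leaf_pairs}, 2)"]
    half_par = machine.max_field_parallel / 2.0
    half_perp = machine.max_field_perp / 2.0
    centers = machine.leaf_centers()
    open_rows = (e[:, 1] - e[:, 0]) > 1e-9
    for i in range(machine.n_leaf_pairs):
        left, right = e[i]
        if right < left:
            out.append(f"pair {i}: reversed edges ({left:.2f} > {right:.2f})")
        if open_rows[i]:
            if left < -half_par or right > half_par:
                out.append(
                    f"pair {i}: opening [{left:.2f}, {right:.2f}] outside "
                    f"+-{half_par:.1f} mm leaf-travel span"
                )
            row_lo = centers[i] - machine.leaf_width_iso / 2.0
            row_hi = centers[i] + machine.leaf_width_iso / 2.0
            if row_lo < -half_perp or row_hi > half_perp:
                out.append(
                    f"pair {i}: open row at {centers[i]:.2f} mm outside "
                    f"+-{half_perp:.2f} mm stack span"
                )
    if segment.weight < 0:
        out.append("negative weight")
    return out
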
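"""4D dose accumulation and dose-volume evaluation.

Per-phase doses are mapped onto the reference (peak-exhale) anatomy by
*direct dose mapping*: a pull-back through the known deformation vector
fields with trilinear interpolation, without mass- or energy-transfer
correction.  The accumulated dose is the equal-weight average over phases
(weight 1/10 for a 10-phase breathing cycle).

Metric conventions: ``Dx`` is the maximum dose level received by at least
x% of a structure's voxels (the inverse cumulative DVH with a lower
interpolation convention, i.e. a pure voxel-count percentile — exact and
oracle-checkable).  Integral deposited energy is
``sum_i rho_i * D_i * V_i`` in joules with rho in kg/m^3, D in Gy and V in
m^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose_engine import DoseGrid

__all__ = [
    "warp_dose",
    "accumulate",
    "dvh",
    "metric_Dx",
    "metric_mean",
    "integral_energy",
    "evaluate_case",
    "ARM_NAMES",
]

ARM_NAMES = ("conv_0T", "conv_1.5T", "track_0T", "track_1.5T")


def warp_dose(dose: np.ndarray | DoseGrid, dvf: np.ndarray, voxel_size: float = 2.5) -> np.ndarray:
    """Pull a phase dose back onto the reference grid.

    ``dvf`` holds, per reference voxel, the displacement (mm) to the
    corresponding phase-frame location; the phase dose is sampled there by
    trilinear interpolation, with zero contribution from outside the grid.
    """
    values = dose.values if isinstance(dose, DoseGrid) else dose
    if dvf.shape[:3] != values.shape:
        raise ValueError("DVF grid does not match the dose grid")
    if not np.any(dvf):
        return values.copy()
    idx = np.indices(values.shape, dtype=np.float32)
    coords = idx + np.moveaxis(dvf, -1, 0).astype(np.float32) / np.float32(voxel_size)
    return ndimage.map_coordinates(
        values.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )


def accumulate(
    phase_doses: list[np.ndarray | DoseGrid],
    dvfs: list[np.ndarray],
    voxel_size: float = 2.5,
) -> np.ndarray:
    """Equal-weight accumulation of per-phase doses on the reference grid."""
    if len(phase_doses) != len(dvfs):
        raise ValueError("one dose per phase required")
    n = len(phase_doses)
    if n == 0:
        raise ValueError("no phases")
    total = None
    for dose, dvf in zip(phase_doses, dvfs):
        warped = warp_dose(dose, dvf, voxel_size)
        total = warped if total is None else total + warped
    return total / np.float32(n)


def dvh(dose: np.ndarray, mask: np.ndarray, n_bins: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume curve: fraction of the structure receiving at
    least each dose level.  Monotone non-increasing from 1 to 0."""
    vals = np.asarray(dose)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    top = float(vals.max()) if vals.max() > 0 else 1.0
    levels = np.linspace(0.0, top * 1.001, n_bins)
    frac = np.array([(vals >= d).mean() for d in levels])
    return levels, frac


def metric_Dx(dose: np.ndarray, mask: np.ndarray, x: float) -> float:
    """Maximum dose level received by at least x% of the structure's voxels."""
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    vals = np.asarray(dose)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    k = int(np.ceil(x / 100.0 * vals.size))
    return float(np.sort(vals)[::-1][k - 1])


def metric_mean(dose: np.ndarray, mask: np.ndarray) -> float:
    vals = np.asarray(dose)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(vals.mean())


def integral_energy(dose: np.ndarray, density_gcc: np.ndarray, voxel_volume_cc: float) -> float:
    """Integral deposited energy in joules.

    density in g/cc -> kg/m^3 (x1000); voxel volume in cc -> m^3 (x1e-6);
    dose in Gy = J/kg.
    """
    if np.any(np.asarray(density_gcc) < 0):
        raise ValueError("negative density")
    rho_si = np.asarray(density_gcc, dtype=np.float64) * 1000.0
    v_si = voxel_volume_cc * 1e-6
    return float(np.sum(rho_si * np.asarray(dose, dtype=np.float64)) * v_si)


def volume_at_least(dose: np.ndarray, level: float) -> int:
    """Number of voxels receiving at least ``level`` Gy."""
    return int(np.count_nonzero(np.asarray(dose) >= level))


def evaluate_case(
    arm_doses: dict[str, np.ndarray],
    structures: dict[str, np.ndarray],
    density_gcc: np.ndarray,
    voxel_volume_cc: float,
    ptv_masks: dict[str, np.ndarray] | None = None,
    prescription_gy: float = 54.0,
    extra_metrics: list[tuple[str, str, float | None]] | None = None,
) -> pd.DataFrame:
    """Endpoint table for one case: one row per delivery arm.

    ``arm_doses`` maps arm name (see :data:`ARM_NAMES`) to the accumulated,
    total-treatment-scale dose on the reference grid.  ``ptv_masks`` maps arm
    name to the PTV used by that arm (for R50% and PTV D95).
    ``extra_metrics`` entries are ``(structure, 'mean' | 'Dx', x)``.
    """
    required = {"gtv", "skin", "lungs"}
    missing = required - set(structures)
    if missing:
        raise KeyError(f"missing structures: {sorted(missing)}")
    rows = []
    for arm in ARM_NAMES:
        if arm not in arm_doses:
            raise KeyError(f"missing arm {arm}")
        dose = np.asarray(arm_doses[arm])
        row: dict[str, float | str] = {"arm": arm}
        row["gtv_d98"] = metric_Dx(dose, structures["gtv"], 98.0)
        row["skin_d2"] = metric_Dx(dose, structures["skin"], 2.0)
        row["skin_mean"] = metric_mean(dose, structures["skin"])
        row["lung_mean"] = metric_mean(dose, structures["lungs"])
        if "vessels" in structures and structures["vessels"].any():
            row["vessels_d2"] = metric_Dx(dose, structures["vessels"], 2.0)
        row["integral_energy_j"] = integral_energy(dose, density_gcc, voxel_volume_cc)
        if ptv_masks is not None and arm in ptv_masks:
            ptv = ptv_masks[arm]
            row["ptv_d95"] = metric_Dx(dose, ptv, 95.0)
            row["r50"] = volume_at_least(dose, prescription_gy / 2.0) / max(
                int(ptv.sum()), 1
            )
        for name, kind, x in extra_metrics or []:
            col = f"{name}_{kind}{'' if x is None else int(x)}"
            if kind == "mean":
                row[col] = metric_mean(dose, structures[name])
            else:
                row[col] = metric_Dx(dose, structures[name], float(x))
        rows.append(row)
    return pd.DataFrame(rows).set_index("arm")
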
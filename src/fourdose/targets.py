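"""Target-volume construction: ITV, MTV and margin-expanded PTVs.

Two target strategies are compared downstream.  The internal target volume
(ITV) is the voxelwise union of the per-phase GTV masks in the fixed patient
frame and is the target for conventional, non-tracked delivery.  The moving
target volume (MTV) aligns every phase's GTV on the reference-phase centroid
before taking the union; it captures residual tumor *deformation* only, since
tracking compensates the centroid translation, and is the target for tracked
delivery.  Both are expanded by an isotropic setup margin (default 5 mm) into
planning target volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["TargetSet", "build_itv", "build_mtv", "expand_margin", "build_target_set"]


@dataclass
class TargetSet:
    gtv_ref: np.ndarray
    itv: np.ndarray
    mtv: np.ndarray
    ptv_itv: np.ndarray
    ptv_mtv: np.ndarray
    margin_mm: float = 5.0

    def ptv(self, strategy: str) -> np.ndarray:
        if strategy in ("itv", "conventional"):
            return self.ptv_itv
        if strategy in ("mtv", "tracked"):
            return self.ptv_mtv
        raise KeyError(strategy)


def build_itv(gtv_masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise union of the per-phase GTV masks on the common grid."""
    if not gtv_masks:
        raise ValueError("need at least one GTV mask")
    itv = np.zeros_like(gtv_masks[0], dtype=bool)
    for m in gtv_masks:
        if m.shape != itv.shape:
            raise ValueError("GTV masks must share one grid")
        itv |= m.astype(bool)
    return itv


def _centroid_vox(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    return idx.mean(axis=0)


def build_mtv(gtv_masks: list[np.ndarray], reference_phase: int = 0) -> np.ndarray:
    """Union of centroid-aligned per-phase GTV masks.

    Each phase mask is translated by the centroid difference to the reference
    phase, rounded to the nearest whole voxel (boolean masks are never
    resampled sub-voxel).  With purely rigid tumor motion the result equals
    the reference GTV; per-phase shape changes enlarge it.
    """
    if not gtv_masks:
        raise ValueError("need at least one GTV mask")
    c_ref = _centroid_vox(gtv_masks[reference_phase])
    mtv = np.zeros_like(gtv_masks[reference_phase], dtype=bool)
    for m in gtv_masks:
        shift = np.rint(c_ref - _centroid_vox(m)).astype(int)
        shifted = np.roll(m.astype(bool), shift, axis=(0, 1, 2))
        # np.roll wraps; zero out wrapped margins
        for ax, s in enumerate(shift):
            if s > 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(0, s)
                shifted[tuple(sl)] = False
            elif s < 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(s, None)
                shifted[tuple(sl)] = False
        mtv |= shifted
    return mtv


def expand_margin(mask: np.ndarray, margin_mm: float, voxel_size: float) -> np.ndarray:
    """Isotropic Euclidean expansion: voxels whose center lies within
    ``margin_mm`` of the input mask (distance-transform dilation)."""
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if margin_mm == 0 or not mask.any():
        return mask.astype(bool).copy()
    dist = ndimage.distance_transform_edt(~mask.astype(bool), sampling=voxel_size)
    return dist <= margin_mm


def build_target_set(
    gtv_masks: list[np.ndarray],
    reference_phase: int = 0,
    margin_mm: float = 5.0,
    voxel_size: float = 2.5,
) -> TargetSet:
    gtv_ref = gtv_masks[reference_phase].astype(bool)
    itv = build_itv(gtv_masks)
    mtv = build_mtv(gtv_masks, reference_phase)
    return TargetSet(
        gtv_ref=gtv_ref,
        itv=itv,
        mtv=mtv,
        ptv_itv=expand_margin(itv, margin_mm, voxel_size),
        ptv_mtv=expand_margin(mtv, margin_mm, voxel_size),
        margin_mm=margin_mm,
    )
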
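"""On-disk formats: NRRD volumes via SimpleITK, JSON plans and manifests.

Arrays are kept in (x, y, z) index order in memory; SimpleITK stores (z, y,
x), so every read/write transposes.  A phantom is one directory of NRRD
files (densities, masks, 3-component deformation fields) tied together by a
``manifest.json``; a treatment plan is a single JSON document with per-
segment leaf edge arrays in mm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .dose_engine import DoseGrid
from .machine import Beam, Prescription, Segment, TreatmentPlan
from .phantom import Phantom4D, PhantomConfig

__all__ = [
    "write_volume",
    "read_volume",
    "save_phantom",
    "load_phantom",
    "save_plan",
    "load_plan",
    "save_dose",
    "load_dose",
]


def write_volume(
    path: str | Path,
    array: np.ndarray,
    voxel_size: float,
    metadata: dict[str, str] | None = None,
) -> None:
    arr = np.asarray(array)
    is_vector = arr.ndim == 4
    if is_vector:
        img = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0, 3)).astype(np.float32),
                                     isVector=True)
    else:
        data = arr.astype(np.uint8) if arr.dtype == bool else arr.astype(np.float32)
        img = sitk.GetImageFromArray(np.transpose(data, (2, 1, 0)))
    img.SetSpacing((voxel_size,) * 3)
    for k, v in (metadata or {}).items():
        img.SetMetaData(k, str(v))
    sitk.WriteImage(img, str(path), useCompression=True)


def read_volume(path: str | Path) -> tuple[np.ndarray, float, dict[str, str]]:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4:
        arr = np.transpose(arr, (2, 1, 0, 3))
    else:
        arr = np.transpose(arr, (2, 1, 0))
    meta = {k: img.GetMetaData(k) for k in img.GetMetaDataKeys()}
    return arr, float(img.GetSpacing()[0]), meta


def save_phantom(phantom: Phantom4D, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    vs = phantom.voxel_size
    for p, (density, gtv, dvf) in enumerate(
        zip(phantom.phases, phantom.gtv_masks, phantom.dvfs)
    ):
        write_volume(d / f"density_p{p:02d}.nrrd", density, vs, {"phase": str(p)})
        write_volume(d / f"gtv_p{p:02d}.nrrd", gtv, vs, {"phase": str(p)})
        write_volume(d / f"dvf_p{p:02d}.nrrd", dvf, vs, {"phase": str(p)})
    for name, mask in phantom.organ_masks.items():
        write_volume(d / f"mask_{name}.nrrd", mask, vs)
    manifest = {
        "n_phases": phantom.n_phases,
        "reference_phase": phantom.reference_phase,
        "voxel_size": vs,
        "organ_masks": sorted(phantom.organ_masks),
        "tumor_centroids": np.asarray(phantom.tumor_centroids).tolist(),
        "config": dataclasses.asdict(phantom.config),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return d / "manifest.json"


def load_phantom(directory: str | Path) -> Phantom4D:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg_dict = manifest["config"]
    # JSON turns tuples into lists; restore the dataclass faithfully
    for key, val in list(cfg_dict.items()):
        if isinstance(val, list):
            cfg_dict[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
    config = PhantomConfig(**cfg_dict)
    n = manifest["n_phases"]
    phases, gtvs, dvfs = [], [], []
    for p in range(n):
        phases.append(read_volume(d / f"density_p{p:02d}.nrrd")[0])
        gtvs.append(read_volume(d / f"gtv_p{p:02d}.nrrd")[0].astype(bool))
        dvfs.append(read_volume(d / f"dvf_p{p:02d}.nrrd")[0])
    organs = {
        name: read_volume(d / f"mask_{name}.nrrd")[0].astype(bool)
        for name in manifest["organ_masks"]
    }
    return Phantom4D(
        config=config,
        phases=phases,
        gtv_masks=gtvs,
        organ_masks=organs,
        dvfs=dvfs,
        reference_phase=manifest["reference_phase"],
        tumor_centroids=np.asarray(manifest["tumor_centroids"]),
    )


def save_plan(plan: TreatmentPlan, path: str | Path, extra: dict | None = None) -> None:
    doc = {
        "beams": [{"gantry_angle": b.gantry_angle, "isocenter": list(b.isocenter)}
                  for b in plan.beams],
        "segments": [
            {
                "beam_index": s.beam_index,
                "leaf_edges_mm": np.asarray(s.leaf_edges).round(4).tolist(),
                "weight": s.weight,
            }
            for s in plan.segments
        ],
        "prescription": dataclasses.asdict(plan.prescription),
        "target_label": plan.target_label,
        "field_strength_t": plan.field_strength,
        "log": plan.log,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc))


def load_plan(path: str | Path) -> TreatmentPlan:
    doc = json.loads(Path(path).read_text())
    return TreatmentPlan(
        beams=[Beam(b["gantry_angle"], tuple(b["isocenter"])) for b in doc["beams"]],
        segments=[
            Segment(s["beam_index"], np.asarray(s["leaf_edges_mm"], dtype=float),
                    s["weight"])
            for s in doc["segments"]
        ],
        prescription=Prescription(**doc["prescription"]),
        target_label=doc["target_label"],
        field_strength=doc["field_strength_t"],
        log=list(doc.get("log", [])),
    )


def save_dose(dose: DoseGrid, path: str | Path) -> None:
    write_volume(
        path, dose.values, dose.voxel_size,
        {"phase": str(dose.phase_index), "field_strength_t": str(dose.field_strength),
         "scale": dose.scale},
    )


def load_dose(path: str | Path) -> DoseGrid:
    arr, vs, meta = read_volume(path)
    return DoseGrid(
        values=arr,
        phase_index=int(meta.get("phase", 0)),
        field_strength=float(meta.get("field_strength_t", 0.0)),
        scale=meta.get("scale", "total"),
        voxel_size=vs,
    )
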
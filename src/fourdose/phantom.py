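"""Synthetic 4D digital thorax phantom with a mobile lung tumor.

The phantom stands in for a respiratory-binned 4DCT scan: ``n_phases`` density
volumes (g/cc), a gross tumor volume (GTV) mask per phase, reference-phase
organ masks (body, lungs, skin shell, great vessels) and *analytically known*
deformation vector fields tying every phase to the reference (peak-exhale)
phase.  Because the deformation is constructed rather than estimated, dose
accumulation downstream is free of registration error.

Geometry: patient axes are x (left), y (anterior), z (superior).  The body is
an ellipsoid of soft tissue containing two lung ellipsoids; the tumor is a
sphere inside one lung.  The tumor centroid follows a smooth periodic
breathing trajectory, ``1 - cos^2`` per axis, scaled to a prescribed
peak-to-peak amplitude; phase 0 sits at the rest (peak-exhale) extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "Phantom4D",
    "generate_phantom",
    "make_cohort",
    "breathing_trajectory",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic 4D thorax.

    Lengths are millimetres, densities g/cc.  The default 96x96x80 grid at
    2.5 mm isotropic spacing matches the dose-grid resolution the pipeline
    evaluates on while keeping a full experiment tractable on one CPU.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 80)
    voxel_size: float = 2.5
    body_half_axes: tuple[float, float, float] = (105.0, 80.0, 96.0)
    lung_centers: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (-50.0, 0.0, 0.0),
        (50.0, 0.0, 0.0),
    )
    lung_half_axes: tuple[float, float, float] = (38.0, 52.0, 74.0)
    tumor_radius: float = 13.4  # ~10.1 cc, the cohort mean volume
    tumor_rest_center: tuple[float, float, float] = (50.0, 0.0, -10.0)
    motion_peak_to_peak: tuple[float, float, float] = (1.0, 1.5, 5.4)  # |.| ~ 5.7 mm, cohort mean
    n_phases: int = 10
    density_air: float = 0.001
    density_lung: float = 0.26
    density_soft: float = 1.0
    density_tumor: float = 1.0
    skin_shell_thickness: float = 5.0
    vessel_radius: float = 12.0
    include_ribs: bool = False
    tumor_radius_modulation: float = 0.0  # fractional per-phase radius change
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        for name in ("density_air", "density_lung", "density_soft", "density_tumor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.tumor_radius <= 0:
            raise ValueError("tumor_radius must be positive")


@dataclass
class Phantom4D:
    """A generated 4D phantom on a single voxel grid.

    ``dvfs[p]`` holds, for every reference-phase voxel, the displacement (mm)
    to the corresponding location in phase ``p`` — the pull-back field used
    for direct dose mapping.  The reference phase's field is identically zero.
    """

    config: PhantomConfig
    phases: list[np.ndarray]            # density volumes, g/cc
    gtv_masks: list[np.ndarray]         # boolean, per phase
    organ_masks: dict[str, np.ndarray]  # reference phase: body, lungs, skin, vessels[, ribs]
    dvfs: list[np.ndarray]              # (nx, ny, nz, 3) mm, reference -> phase
    reference_phase: int = 0
    tumor_centroids: np.ndarray | None = None  # (n_phases, 3) mm, analytic

    @property
    def voxel_size(self) -> float:
        return self.config.voxel_size

    @property
    def voxel_volume_cc(self) -> float:
        return (self.config.voxel_size / 10.0) ** 3

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def reference_density(self) -> np.ndarray:
        return self.phases[self.reference_phase]

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return grid_coords(self.config.grid_shape, self.config.voxel_size)

    def motion_amplitude(self) -> float:
        """3D peak-to-peak amplitude (mm) of the tumor centroid trajectory."""
        c = np.asarray(self.tumor_centroids)
        return float(np.linalg.norm(c.max(axis=0) - c.min(axis=0)))


def grid_coords(shape: Sequence[int], voxel_size: float) -> tuple[np.ndarray, ...]:
    """Physical voxel-center coordinates (mm), origin at the grid center."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel_size for n in shape]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def breathing_trajectory(config: PhantomConfig) -> np.ndarray:
    """Tumor centroid displacement from rest per phase, shape (n_phases, 3) mm.

    Displacement along each axis is ``A * (1 - cos^2(pi * p / n))`` which is
    zero at phase 0 (peak-exhale) and peaks at mid-cycle (peak-inhale) with
    peak-to-peak amplitude ``A``.
    """
    p = np.arange(config.n_phases)
    w = 1.0 - np.cos(np.pi * p / config.n_phases) ** 2
    amp = np.asarray(config.motion_peak_to_peak, dtype=float)
    return w[:, None] * amp[None, :]


def _ellipsoid_mask(coords, center, half_axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = half_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere_mask(coords, center, radius) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return 3.0 * s**2 - 2.0 * s**3


def _tumor_radius_at_phase(config: PhantomConfig, phase: int) -> float:
    if config.tumor_radius_modulation == 0.0:
        return config.tumor_radius
    # sinusoidal radius modulation, extreme at peak-inhale
    w = 1.0 - np.cos(np.pi * phase / config.n_phases) ** 2
    return config.tumor_radius * (1.0 + config.tumor_radius_modulation * (2.0 * w - 1.0))


def generate_phantom(config: PhantomConfig) -> Phantom4D:
    """Build the 4D phantom: densities, masks and deformation fields.

    Deformation is a rigid tumor translation inside a C^1 radial decay
    envelope around the tumor rest position, clipped to the lungs and zero
    elsewhere; the plateau of the envelope covers the tumor at every phase so
    the tumor region deforms exactly rigidly.
    """
    coords = grid_coords(config.grid_shape, config.voxel_size)
    traj = breathing_trajectory(config)
    rest = np.asarray(config.tumor_rest_center, dtype=float)
    centroids = rest[None, :] + traj

    body = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), config.body_half_axes)
    lungs = np.zeros_like(body)
    for c in config.lung_centers:
        lungs |= _ellipsoid_mask(coords, c, config.lung_half_axes)
    lungs &= body

    # tumor containment check, analytic: sphere inside its lung ellipsoid
    for p in range(config.n_phases):
        r_p = _tumor_radius_at_phase(config, p)
        inside = False
        for c in config.lung_centers:
            d = (centroids[p] - np.asarray(c)) / np.asarray(config.lung_half_axes)
            # conservative: shrink ellipsoid by tumor radius along each axis
            shrunk = (np.asarray(config.lung_half_axes) - r_p)
            if np.all(shrunk > 0):
                d2 = (centroids[p] - np.asarray(c)) / shrunk
                if float(np.sum(d2**2)) <= 1.0:
                    inside = True
                    break
        if not inside:
            raise ValueError(
                f"tumor leaves the lung at phase {p} "
                f"(centroid {centroids[p]}, radius {r_p:.1f} mm)"
            )

    # skin shell: outermost shell of the body, via distance to the exterior
    inside_dist = ndimage.distance_transform_edt(body, sampling=config.voxel_size)
    skin = body & (inside_dist <= config.skin_shell_thickness)

    # great vessels: mediastinal cylinder along z
    x, y, z = coords
    vessels = body & ~lungs & (x**2 + (y - 10.0) ** 2 <= config.vessel_radius**2)

    organ_masks = {"body": body, "lungs": lungs, "skin": skin, "vessels": vessels}
    if config.include_ribs:
        # coarse rib surrogate: soft-tissue shell directly around the lungs
        lung_dist = ndimage.distance_transform_edt(~lungs, sampling=config.voxel_size)
        organ_masks["ribs"] = body & ~lungs & (lung_dist <= 6.0) & (inside_dist > 10.0)

    phases: list[np.ndarray] = []
    gtv_masks: list[np.ndarray] = []
    for p in range(config.n_phases):
        r_p = _tumor_radius_at_phase(config, p)
        gtv = _sphere_mask(coords, centroids[p], r_p)
        density = np.full(config.grid_shape, config.density_air, dtype=np.float32)
        density[body] = config.density_soft
        density[lungs] = config.density_lung
        density[gtv] = config.density_tumor
        phases.append(density)
        gtv_masks.append(gtv)

    # DVF envelope: plateau radius covers the tumor at every displacement
    max_disp = float(np.max(np.linalg.norm(traj, axis=1)))
    r_inner = config.tumor_radius * (1.0 + abs(config.tumor_radius_modulation)) + max_disp + 2.0
    r_outer = r_inner + 15.0
    x0, y0, z0 = rest
    r_rest = np.sqrt((x - x0) ** 2 + (y - y0) ** 2 + (z - z0) ** 2)
    envelope = 1.0 - _smoothstep((r_rest - r_inner) / (r_outer - r_inner))
    envelope = np.where(lungs, envelope, 0.0).astype(np.float32)

    dvfs: list[np.ndarray] = []
    for p in range(config.n_phases):
        dvf = envelope[..., None] * traj[p][None, None, None, :].astype(np.float32)
        dvfs.append(dvf.astype(np.float32))

    return Phantom4D(
        config=config,
        phases=phases,
        gtv_masks=gtv_masks,
        organ_masks=organ_masks,
        dvfs=dvfs,
        reference_phase=0,
        tumor_centroids=centroids,
    )


def _radius_from_volume_cc(volume_cc: float) -> float:
    return float((3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def make_cohort(
    n_cases: int,
    motion_range: tuple[float, float] = (1.5, 14.1),
    volume_range: tuple[float, float] = (3.3, 25.5),
    seed: int = 0,
    base_config: PhantomConfig | None = None,
) -> list[Phantom4D]:
    """Sample a patient-like cohort of phantoms.

    Tumor volumes (cc) and 3D peak-to-peak motion amplitudes (mm) are drawn
    uniformly from the given ranges; motion is predominantly superior-inferior
    with small left-right and anterior-posterior components, as for lower-lobe
    lung tumors.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    for lo, hi in (motion_range, volume_range):
        if hi < lo:
            raise ValueError("empty range")
    rng = np.random.default_rng(seed)
    base = base_config if base_config is not None else PhantomConfig()
    cohort = []
    for i in range(n_cases):
        volume = float(rng.uniform(*volume_range))
        motion = float(rng.uniform(*motion_range))
        # direction: dominant z with modest transverse components
        frac_x, frac_y = rng.uniform(0.05, 0.25, size=2)
        direction = np.array([frac_x, frac_y, 1.0])
        direction /= np.linalg.norm(direction)
        cfg = replace(
            base,
            tumor_radius=_radius_from_volume_cc(volume),
            motion_peak_to_peak=tuple(motion * direction),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(generate_phantom(cfg))
    return cohort
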
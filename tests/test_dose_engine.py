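import numpy as np
import pytest

from fourdose import (
    Beam,
    BeamModel,
    DoseEngine,
    DoseGrid,
    FieldConfig,
    MachineModel,
    Segment,
    compute_plan_dose,
    compute_segment_dose,
    ere_perturb,
    radiological_depth,
)
from fourdose.dose_engine import ere_apply_beam_frame
from fourdose.machine import TreatmentPlan

VS = 2.5


def open_segment(machine, half_u=50.0, half_z=50.0, weight=1.0):
    edges = np.zeros((machine.n_leaf_pairs, 2))
    centers = machine.leaf_centers()
    rows = np.abs(centers) <= half_z
    edges[rows] = (-half_u, half_u)
    return Segment(0, edges, weight)


@pytest.fixture(scope="module")
def machine():
    return MachineModel()


@pytest.fixture(scope="module")
def water_slab():
    """Uniform water volume, beam at gantry 0 travels along -y."""
    return np.ones((48, 48, 40), dtype=np.float32)


# ---------------------------------------------------------------- depth


def test_radiological_depth_uniform_water(water_slab):
    beam = Beam(0)
    # beam enters at the y-max face; voxel 19.5 voxels deep = 48.75 mm water
    d = radiological_depth(water_slab, beam, VS, voxel=(24, 28, 20))
    assert abs(d - (47 - 28 + 0.5) * VS) < 1e-3


def test_radiological_depth_tissue_lung_slab():
    """20 mm tissue + 40 mm lung at 0.26 g/cc is 30.4 mm water-equivalent."""
    vol = np.full((40, 60, 40), 1e-4, np.float32)
    vol[:, 52:60, :] = 1.0   # 8 voxels = 20 mm tissue at the entry (y-max) side
    vol[:, 36:52, :] = 0.26  # 16 voxels = 40 mm lung
    beam = Beam(0)           # travels -y
    d = radiological_depth(vol, beam, VS, voxel=(20, 35, 20))
    expect = (8 * 1.0 + 16 * 0.26 + 0.5 * 1e-4) * VS  # 30.4 mm
    assert abs(d - expect) < 0.05


def test_radiological_depth_matches_voxel_sum_oracle():
    """Axis-aligned beams: depth equals a brute-force cumulative voxel sum."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        vol = rng.uniform(0.1, 1.5, size=(20, 20, 12)).astype(np.float32)
        beam = Beam(rng.choice([0, 90, 180, 270]))
        depth = radiological_depth(vol, beam, VS)
        i = int(rng.integers(0, 20))
        j = int(rng.integers(0, 20))
        k = int(rng.integers(0, 12))
        # oracle: walk the ray in the patient frame
        t = np.deg2rad(beam.gantry_angle)
        step = np.array([-np.sin(t), -np.cos(t), 0.0])
        acc, pos = 0.0, None
        # enumerate voxels upstream of (i, j, k) along the beam
        ii, jj = i, j
        path = []
        while 0 <= ii < 20 and 0 <= jj < 20:
            path.append((int(round(ii)), int(round(jj))))
            ii -= step[0]
            jj -= step[1]
        path = path[::-1]
        acc = sum(vol[a, b, k] for a, b in path[:-1]) + 0.5 * vol[path[-1][0], path[-1][1], k]
        assert abs(depth[i, j, k] - acc * VS) < 0.05


def test_depth_at_entry_surface_is_small(water_slab):
    d = radiological_depth(water_slab, Beam(0), VS, voxel=(24, 47, 20))
    assert d <= VS  # within half a voxel of zero, plus own-voxel half


def test_depth_dose_curve_unimodal():
    bm = BeamModel()
    d = np.linspace(0, 300, 1000)
    y = bm.depth_dose(d)
    peak = int(np.argmax(y))
    assert np.all(np.diff(y[:peak]) >= -1e-7)
    assert np.all(np.diff(y[peak:]) <= 1e-7)
    assert np.isclose(y.max(), 1.0, atol=1e-3)
    assert abs(d[peak] - bm.depth_of_maximum()) < 1.0


# ---------------------------------------------------------------- kernel dose


def test_zero_weight_gives_zero_dose(water_slab, machine):
    seg = open_segment(machine, weight=0.0)
    dose = compute_segment_dose(seg, Beam(0), water_slab, FieldConfig(b=0.0),
                                machine=machine, voxel_size=VS)
    assert not np.any(dose.values)


def test_central_axis_profile_matches_depth_dose(water_slab, machine):
    """Open 10x10 cm field in water: the central-axis dose equals the 1D
    depth-dose curve times calibration."""
    bm = BeamModel()
    seg = open_segment(machine)
    dose = compute_segment_dose(seg, Beam(0), water_slab, FieldConfig(b=0.0),
                                beam_model=bm, machine=machine, voxel_size=VS)
    iy = np.arange(48)
    depth = ((47 - iy) + 0.5) * VS  # beam enters at the y-max face
    expected = bm.depth_dose(depth) * bm.mu_to_gy
    profile = dose.values[24, :, 20]
    assert np.allclose(profile, expected, atol=0.02)


def test_linearity_and_homogeneity(water_slab, machine):
    seg = open_segment(machine, 20, 20, weight=1.0)
    beam = Beam(40)
    plan1 = TreatmentPlan([beam], [seg])
    seg2 = open_segment(machine, 20, 20, weight=1.0)
    plan2 = TreatmentPlan([beam], [seg, seg2])
    d1 = compute_plan_dose(plan1, water_slab, FieldConfig(b=0.0), machine=machine,
                           voxel_size=VS)
    d2 = compute_plan_dose(plan2, water_slab, FieldConfig(b=0.0), machine=machine,
                           voxel_size=VS)
    assert np.allclose(d2.values, 2.0 * d1.values, atol=1e-5)
    seg3 = open_segment(machine, 20, 20, weight=3.0)
    d3 = compute_plan_dose(TreatmentPlan([beam], [seg3]), water_slab,
                           FieldConfig(b=0.0), machine=machine, voxel_size=VS)
    assert np.allclose(d3.values, 3.0 * d1.values, atol=1e-5)


def test_plan_dose_equals_sum_of_segment_doses(water_slab, machine):
    """Independent re-summation over per-beam doses."""
    beams = [Beam(0), Beam(120), Beam(240)]
    segs = [open_segment(machine, 25, 25) for _ in beams]
    for i, s in enumerate(segs):
        s.beam_index = i
    plan = TreatmentPlan(beams, segs)
    total = compute_plan_dose(plan, water_slab, FieldConfig(b=0.0), machine=machine,
                              voxel_size=VS)
    resum = np.zeros_like(total.values)
    for s in segs:
        resum += compute_segment_dose(s, beams[s.beam_index], water_slab,
                                      FieldConfig(b=0.0), machine=machine,
                                      voxel_size=VS).values
    assert np.allclose(total.values, resum, atol=1e-4)


def test_empty_plan_rejected(water_slab, machine):
    with pytest.raises(ValueError):
        compute_plan_dose(TreatmentPlan([Beam(0)], []), water_slab,
                          FieldConfig(b=0.0), machine=machine, voxel_size=VS)


def test_cryostat_transmission_scales_beam(water_slab):
    machine = MachineModel(cryostat_attenuation={0.0: 0.5})
    seg = open_segment(machine, 20, 20)
    plan = TreatmentPlan([Beam(0)], [seg])
    half = compute_plan_dose(plan, water_slab, FieldConfig(b=0.0), machine=machine,
                             voxel_size=VS)
    full = compute_plan_dose(plan, water_slab, FieldConfig(b=0.0),
                             machine=MachineModel(), voxel_size=VS)
    assert np.allclose(half.values, 0.5 * full.values, atol=1e-5)


def test_stochastic_mode_two_percent_noise(water_slab, machine):
    seg = open_segment(machine)
    det = compute_segment_dose(seg, Beam(0), water_slab, FieldConfig(b=0.0),
                               machine=machine, voxel_size=VS)
    sto = compute_segment_dose(seg, Beam(0), water_slab, FieldConfig(b=0.0),
                               machine=machine, voxel_size=VS, mode="stochastic", seed=4)
    sel = det.values > 0.5
    ratio = sto.values[sel] / det.values[sel]
    assert abs(ratio.mean() - 1.0) < 0.005
    assert abs(ratio.std() - 0.02) < 0.005
    sto2 = compute_segment_dose(seg, Beam(0), water_slab, FieldConfig(b=0.0),
                                machine=machine, voxel_size=VS, mode="stochastic", seed=4)
    assert np.array_equal(sto.values, sto2.values)


# ---------------------------------------------------------------- ERE


def _ere_1d_oracle(dose, rho, alpha, thr, n_run, n_b):
    """Independent 1D recoding of the interface redistribution rule
    (no lateral neighbor): energy units are rho * dose."""
    dose = dose.astype(float).copy()
    n = dose.size
    # exits
    for j in range(n - 1):
        if rho[j] - rho[j + 1] > thr:
            gathered = 0.0
            for o in range(1, n_run + 1):
                if j + o >= n or not rho[j + o] < rho[j] - thr:
                    break
                gathered += alpha * dose[j + o] * rho[j + o]
                dose[j + o] *= 1.0 - alpha
            dose[j] += gathered / rho[j]
    # entries
    for e in range(1, n):
        if rho[e] - rho[e - 1] > thr:
            gathered = 0.0
            for o in range(1, n_b):
                if e + o >= n or not rho[e + o] > rho[e] - thr:
                    break
                gathered += alpha * dose[e + o] * rho[e + o]
                dose[e + o] *= 1.0 - alpha
            dose[e] += gathered / rho[e]
    return dose


def test_ere_zero_field_is_identity(water_slab, machine):
    seg = open_segment(machine)
    base = compute_segment_dose(seg, Beam(0), water_slab, FieldConfig(b=0.0),
                                machine=machine, voxel_size=VS)
    out = ere_perturb(base, water_slab, Beam(0), FieldConfig(b=0.0))
    assert np.array_equal(out.values, base.values)


def test_ere_matches_1d_oracle_on_water_air_water_slab():
    """Laterally uniform water-air-water geometry: the 3D redistribution
    reduces to the independently coded 1D rule on interior rays."""
    fc = FieldConfig(b=1.5)
    rho = np.full((40, 48, 32), 1.0, np.float32)
    rho[:, 20:28, :] = 0.001  # air gap, beam along -y (gantry 0)
    rng = np.random.default_rng(3)
    dose_b = np.tile(rng.uniform(0.5, 1.5, size=48).astype(np.float32)[None, :, None],
                     (40, 1, 32))
    # apply directly in the beam frame: beam axis is +axis1 there
    pert, flagged = ere_apply_beam_frame(dose_b.copy(), rho, fc, VS)
    n_run = int(round(fc.ere_run_length_mm / VS))
    n_b = int(round(fc.ere_buildup_mm / VS))
    oracle = _ere_1d_oracle(dose_b[20, :, 16], rho[20, :, 16], fc.alpha,
                            fc.interface_gradient_threshold, n_run, n_b)
    # interior ray: lateral deposits from neighbors cancel the lateral export
    assert np.allclose(pert[20, :, 16], oracle, atol=1e-4)
    # hot spot before the cavity, cooled run inside it
    assert pert[20, 19, 16] > dose_b[20, 19, 16]
    assert pert[20, 22, 16] < dose_b[20, 22, 16]
    assert flagged[20, 19, 16] and flagged[20, 22, 16]


def test_ere_conserves_integral_energy(default_phantom, machine):
    from fourdose.fourd import integral_energy

    ph = default_phantom
    seg = open_segment(machine, 40, 40)
    for ang in (0.0, 90.0):
        base = compute_segment_dose(seg, Beam(ang), ph.reference_density,
                                    FieldConfig(b=0.0), machine=machine, voxel_size=VS)
        pert = ere_perturb(base, ph.reference_density, Beam(ang), FieldConfig(b=1.5))
        e0 = integral_energy(base.values, ph.reference_density, ph.voxel_volume_cc)
        e1 = integral_energy(pert.values, ph.reference_density, ph.voxel_volume_cc)
        assert abs(e1 - e0) / e0 < 0.005


def test_ere_locality_single_beam(default_phantom, machine):
    """B-on and B-off doses agree exactly outside the flagged neighborhoods."""
    from fourdose.dose_engine import ere_flagged_mask

    ph = default_phantom
    seg = open_segment(machine, 40, 40)
    beam = Beam(40)
    d0 = compute_segment_dose(seg, beam, ph.reference_density, FieldConfig(b=0.0),
                              machine=machine, voxel_size=VS)
    d1 = compute_segment_dose(seg, beam, ph.reference_density, FieldConfig(b=1.5),
                              machine=machine, voxel_size=VS)
    flag = ere_flagged_mask(ph.reference_density, beam, FieldConfig(b=1.5), VS)
    diff = np.abs(d1.values - d0.values)
    assert diff[~flag].max() == 0.0
    assert diff[flag].max() > 0.1


def test_ere_skin_hot_spot_on_phantom(default_phantom, machine):
    """Fixed open beam on the thorax: skin-shell D2% increases at 1.5 T."""
    from fourdose.fourd import metric_Dx

    ph = default_phantom
    seg = open_segment(machine, 40, 40)
    beam = Beam(0)
    d0 = compute_segment_dose(seg, beam, ph.reference_density, FieldConfig(b=0.0),
                              machine=machine, voxel_size=VS)
    d1 = compute_segment_dose(seg, beam, ph.reference_density, FieldConfig(b=1.5),
                              machine=machine, voxel_size=VS)
    skin = ph.organ_masks["skin"]
    assert metric_Dx(d1.values, skin, 2.0) > metric_Dx(d0.values, skin, 2.0)


def test_field_config_validation():
    with pytest.raises(ValueError):
        FieldConfig(direction=(1.0, 0.0, 0.0))
    assert FieldConfig(b=0.0).alpha == 0.0
    assert FieldConfig(b=1.5).alpha == 0.35
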
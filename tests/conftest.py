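import numpy as np
import pytest

from fourdose import (
    DoseEngine,
    FieldConfig,
    PhantomConfig,
    build_target_set,
    equidistant_beams,
    generate_phantom,
)
from fourdose.planning import make_plan


@pytest.fixture(scope="session")
def default_phantom():
    """The default 4D thorax phantom (96x96x80 at 2.5 mm, ~5.7 mm motion)."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def default_targets(default_phantom):
    ph = default_phantom
    return build_target_set(ph.gtv_masks, ph.reference_phase, 5.0, ph.voxel_size)


@pytest.fixture(scope="session")
def default_engine():
    return DoseEngine(voxel_size=2.5)


@pytest.fixture(scope="session")
def planned_default(default_phantom, default_targets, default_engine):
    """A normalized conventional (ITV+5mm) plan at B=0 on the default phantom,
    with its recomputed planning-phase dose."""
    ph, ts = default_phantom, default_targets
    beams = equidistant_beams(9)
    structures = {"gtv": ts.gtv_ref, **ph.organ_masks}
    fieldcfg = FieldConfig(b=0.0)
    plan, _ = make_plan(
        ts.ptv_itv, structures, ph.reference_density, beams, default_engine,
        fieldcfg, seed=0, phase_key="planned_default",
    )
    dose = default_engine.plan_dose(
        plan, ph.reference_density, fieldcfg, phase_key="planned_default"
    )
    return plan, dose
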
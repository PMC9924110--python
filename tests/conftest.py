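import numpy as np
import pytest

from protonwet.ct_calibration import default_calibration
from protonwet.override_dose import OverrideRecord
from protonwet.synthetic_data import (
    BraggModelParams,
    CaseSpec,
    DeviceSpec,
    GridSpec,
    OARSpec,
    generate_idd,
    generate_patient_phantom,
)


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def noiseless_params():
    return BraggModelParams(noise_cv=0.0)


@pytest.fixture(scope="session")
def reference_curve(noiseless_params):
    return generate_idd(noiseless_params, 0.0)


@pytest.fixture
def ramp_curve():
    """Plateau 1.0 up to 100 mm, linear falloff to 0.0 at 110 mm, 2 mm sampling."""
    depths = np.arange(0.0, 112.0, 2.0)
    signal = np.clip((110.0 - depths) / 10.0, 0.0, 1.0)
    from protonwet.idd_wet import DepthDoseCurve

    return DepthDoseCurve(depths, signal)


@pytest.fixture(scope="session")
def cushion_spec(calibration):
    """Low-SPR cushion whose reported HU injects a -20.8% TPS SPR error."""
    return DeviceSpec(
        name="device",
        true_rsp=0.101,
        thickness_mm=30.0,
        reported_hu=calibration.hu_for_rsp(0.080),
    )


@pytest.fixture(scope="session")
def hn_setup(calibration, cushion_spec):
    """Patient-like phantom with a posterior cushion, a proximal and a distal OAR.

    The 180-degree beam enters posteriorly through the cushion; the proximal
    OAR sits on its SOBP proximal ramp, the distal OAR on the distal falloff.
    """
    case = CaseSpec(
        device=cushion_spec,
        oars=(
            OARSpec("proximal_oar", (16.0, 106.0, 96.0), 5.0, "proximal"),
            OARSpec("distal_oar", (16.0, 52.0, 96.0), 5.0, "distal"),
        ),
    )
    phantom, masks, plan = generate_patient_phantom(case, calibration)
    return case, phantom, masks, plan


@pytest.fixture(scope="session")
def cushion_override(calibration, cushion_spec):
    tps = float(calibration.hu_to_rsp(cushion_spec.reported_hu))
    return OverrideRecord(device="device", tps_spr=tps, measured_spr=cushion_spec.true_rsp)


@pytest.fixture(scope="session")
def pullback_setup(calibration, cushion_spec):
    """1-mm axial grid variant for resolving sub-millimetre range shifts."""
    case = CaseSpec(
        grid=GridSpec(shape=(8, 160, 160), spacing_mm=(2.0, 1.0, 1.0)),
        body_radius_mm=55.0,
        ctv_radius_mm=12.0,
        device=cushion_spec,
    )
    phantom, masks, plan = generate_patient_phantom(case, calibration)
    return case, phantom, masks, plan
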
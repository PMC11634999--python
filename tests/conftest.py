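import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_record(**kw):
    """A valid VF test record with overridable fields."""
    from vfhome import Device, Eye, Setting, VFTestRecord

    base = dict(
        patient_id="P001", eye=Eye.OD, device=Device.HOME_VR,
        setting=Setting.HOME, t_days=0, md_db=-5.0, psd_db=3.0,
        vfi_pct=85.0, fp_pct=4.7, fn_pct=5.0, fl_pct=9.6,
    )
    base.update(kw)
    return VFTestRecord(**base)
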
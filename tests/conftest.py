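import numpy as np
import pytest

from filokin.params import PRESETS, DevParams, DevState


@pytest.fixture(scope="session")
def control():
    return PRESETS["control"]


@pytest.fixture
def flat_drive_params():
    """Time-frozen parameter set: constant drive, f_FB pinned near 1.

    With t_half tiny, f_FB(t) ~ 1 for all t of interest, so the only
    time-dependence left is removed and closed-form stationary results
    apply.
    """
    return DevParams(
        genotype_label="flat",
        c1_sF=2.0, c1_lF=0.5, c2_sF=0.5, c2_lF=0.1,
        c3=0.01, c4=1.0 / 120.0, c5=0.02, c6=0.01,
        B50=2.0, t_half=1e-6,
        poly_coeffs=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    )


@pytest.fixture
def zero_state():
    return DevState(t=0.0)
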
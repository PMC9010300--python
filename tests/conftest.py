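import numpy as np
import pytest

from cpmgdisp import DispersionCurve, ExperimentGeometry, TwoStateParams


@pytest.fixture
def mq_geometry_800():
    """MQ grid 80-1000 Hz at 800 MHz, constant-time delay 25 ms."""
    counts = (2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25)
    return ExperimentGeometry("MQ_HC", 800.0, 0.025, tuple(n / 0.025 for n in counts))


@pytest.fixture
def sq_geometry_800():
    counts = (2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25)
    return ExperimentGeometry("SQ_C", 800.0, 0.025, tuple(n / 0.025 for n in counts))


@pytest.fixture
def atp_like_params():
    """Exchange parameters of the slow, sparsely populated regime."""
    return TwoStateParams(kex=510.0, p_b=0.0083, dw_h=0.03, dw_c=1.5, r2_0=15.0)


def make_curve(residue, geometry, r2eff, sigma=0.3):
    """Wrap a model/array of R2eff values into a DispersionCurve."""
    r2eff = np.asarray(r2eff, dtype=float)
    nu = geometry.nu_actual
    sig = np.full_like(r2eff, sigma)
    return DispersionCurve(residue, geometry, np.column_stack([nu, r2eff, sig]))
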
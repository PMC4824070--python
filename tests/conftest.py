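import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import termcouple as tc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_params():
    """Published tR2 coupling parameters (TE0=0.9, alpha=27, c_W=15, c_R=7)."""
    return tc.tr2_reference_params()


@pytest.fixture(scope="session")
def reference_design():
    return tc.ConstructDesign(
        construct_id="I21", series="custom", distance_nt=0, true_te=0.0,
        is_reference=True,
    )


@pytest.fixture(scope="session")
def reference_series(reference_design):
    """Noiseless terminator-free reference replicate."""
    return tc.make_growth_series(reference_design)[0]


def clean_series(construct_id="C", mu=0.02, slope_rfp=2000.0, slope_gfp=800.0,
                 od0=0.005, t_max=300.0, dt=30.0):
    """Hand-built noiseless GrowthSeries with known slopes (test helper)."""
    t = np.arange(0.0, t_max + 1, dt)
    od = od0 * np.exp(mu * t)
    return tc.GrowthSeries(
        construct_id=construct_id, time=t, od=od,
        f_rfp=slope_rfp * od, f_gfp=slope_gfp * od,
    )
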
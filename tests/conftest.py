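import numpy as np
import pytest

from neutraldrift import Schedule, simulate, table3_params


@pytest.fixture(scope="session")
def table3_small():
    """Table-3 rates on a small molecule budget (off regime, N_T << N_star)."""
    return table3_params(100)


@pytest.fixture(scope="session")
def drift_run():
    """A consolidated neutral-drift run: k_on=0, 5 clans, supercritical."""
    params = table3_params(60).with_(k_on=0.0, k_fb=0.45, D_m=0.2)
    traj = simulate(
        params,
        Schedule(t_end=25.0, record_every=0.1),
        membrane_fraction=0.67,
        n_clans=5,
        seed=42,
    )
    return params, traj
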
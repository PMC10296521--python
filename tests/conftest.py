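import numpy as np
import pytest

from axondrift import (
    CORTICAL_PDMS_D7,
    AxonGrowthModel,
    ProtocolConfig,
    generate_experiment,
)


@pytest.fixture(scope="session")
def ref_params():
    """Reference fitted parameter set (7 um-period micropatterned PDMS)."""
    return CORTICAL_PDMS_D7


@pytest.fixture(scope="session")
def recovery_study(ref_params):
    """20 replicate synthetic experiments at the reference design.

    Each replicate: 9 observation times 0-40 h, 150 cones per time,
    5-min frames over 30-min windows, 0.1 um measurement noise; joint
    GLS fit with a 100-replicate case bootstrap.  Returns a list of
    dicts with point estimates and 95% CIs.
    """
    proto = ProtocolConfig(n_per_obs=150)
    out = []
    for seed in range(20):
        table = generate_experiment(ref_params, proto, seed=seed)
        res = AxonGrowthModel.from_tracks(table, v0=ref_params.v0_mean).fit(
            n_boot=100, seed=1000 + seed
        )
        out.append(
            {
                "seed": seed,
                "point": np.array([res.a0, res.gamma1, res.sigma2]),
                "ci": res.fit_result.ci,
            }
        )
    return out


@pytest.fixture()
def small_table(ref_params):
    """A small synthetic track table (2 observation times, 5 cones each)."""
    proto = ProtocolConfig(obs_times_hr=(0.0, 5.0), n_per_obs=5)
    return generate_experiment(ref_params, proto, seed=42)
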
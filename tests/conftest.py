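import numpy as np
import pandas as pd
import pytest

from taukinetics import fkpp, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def replication_limited_stage_profiles(D=0.35, P_max=500.0, t_start=5.0, kappa=0.14,
                              noise_sigma=0.0, rng=None):
    """Stage-by-region signal table generated by the region-chain simulator.

    D/kappa = 0.1 r_max² reproduces the fitted human configuration; the
    Braak-III profile decays geometrically away from the EC.
    """
    geom = fkpp.Geometry.region_chain()
    stage_times = {"III": 0.0, "IV": 21.0, "V": 29.0, "VI": 34.0}
    f0 = 1e-3 * 0.3 ** np.arange(6)
    preds = fkpp._simulate_stages(f0, D, kappa, geom, stage_times, t_start,
                                  dt=0.25 / kappa)
    rows = []
    for s, prof in preds.items():
        for r, v in zip(geom.region_labels, P_max * prof):
            val = v * 10 ** rng.normal(0, noise_sigma) if noise_sigma else v
            rows.append({"stage": s, "region": r, "value": val})
    return pd.DataFrame(rows), stage_times


@pytest.fixture
def devos_like():
    return synthetic.gen_seed_dataset(
        synthetic.GeneratorSpec(seed=7, scenario="devos-like"))
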
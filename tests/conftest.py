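import numpy as np
import pandas as pd
import pytest

import micronet as mn


@pytest.fixture()
def tiny_profile():
    """4 units x 6 samples, strictly positive, with labels."""
    rng = np.random.default_rng(0)
    ab = pd.DataFrame(
        rng.lognormal(size=(4, 6)),
        index=[f"U{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series(["case"] * 3 + ["control"] * 3, index=ab.columns)
    return mn.AbundanceProfile(abundance=ab, level="KO", labels=labels)


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard planted fixture: 500 units, 3 modules, 100+100 samples."""
    cfg = mn.SynthConfig.standard(seed=42)
    profile, truth = mn.generate_profile(cfg)
    return cfg, profile, truth


@pytest.fixture(scope="session")
def standard_networks(standard_fixture):
    """PCC and RF networks from the standard fixture at relative threshold 1.5.

    The RF ensemble is run at 100 trees (the package's reduced scale for
    the 500-unit fixture); shared session-wide because the RF fit is the
    expensive step.
    """
    _, profile, truth = standard_fixture
    w_pcc = mn.pcc_weight_matrix(profile)
    net_pcc = mn.threshold_network(w_pcc, 1.5)
    w_rf = mn.symmetrize(mn.rf_weight_matrix(profile, n_trees=100, seed=7))
    net_rf = mn.threshold_network(w_rf, 1.5)
    return net_pcc, net_rf, truth
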
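import numpy as np
import pytest

from matemeta import (SimulationTruth, build_model, simulate_dataset,
                      tree_from_string)
from matemeta.phylogeny import grafen_calibrate


@pytest.fixture(scope="session")
def caterpillar3():
    """((A,B),C) Grafen-calibrated: A-B share depth 0.5."""
    return grafen_calibrate(tree_from_string("((A,B),C);"))


@pytest.fixture(scope="session")
def default_dataset():
    """One draw at the standard recovery design, with mild censoring."""
    truth = SimulationTruth(seed=77, censor_prob=0.25)
    ds, latent = simulate_dataset(truth)
    return truth, ds, latent


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    from matemeta import fit_reml
    _, ds, _ = default_dataset
    return fit_reml(build_model(ds))


@pytest.fixture()
def rng():
    return np.random.default_rng(20231114)
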
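import numpy as np
import pandas as pd
import pytest

import enhancerdose as ed


@pytest.fixture(scope="session")
def small_config():
    """A reduced experiment: one reporter kept cheap for unit tests."""
    return ed.SynthConfig(
        reporters=("Distal", "FullLength"),
        n_batches=2,
        embryos_per_batch_per_dose=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return ed.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def study_experiment():
    """Full default-design experiment shared by the heavier tests."""
    return ed.simulate_experiment(ed.SynthConfig(seed=5))


@pytest.fixture()
def simple_embryos():
    """Hand-built two-batch embryo table with known normalization answers."""
    rows = []
    # batch1: FullLength DMSO SEVs {2, 4} -> mean 3; one treated embryo SEV 3
    rows.append(("e1", "FullLength", 0.0, True, "b1", 2.0))
    rows.append(("e2", "FullLength", 0.0, True, "b1", 4.0))
    rows.append(("e3", "FullLength", 1.0, False, "b1", 3.0))
    # batch2 scaled 10x: same biology, different electroporation efficiency
    rows.append(("e4", "FullLength", 0.0, True, "b2", 20.0))
    rows.append(("e5", "FullLength", 0.0, True, "b2", 40.0))
    rows.append(("e6", "FullLength", 1.0, False, "b2", 30.0))
    return pd.DataFrame(
        rows, columns=["embryo_id", "reporter", "dose_um", "vehicle", "batch_id", "sev"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
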
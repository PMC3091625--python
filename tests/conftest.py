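import numpy as np
import pandas as pd
import pytest

from beadnorm.io import SampleDesign
from beadnorm.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 400-probe, 3x4 simulated experiment shared across read-only tests."""
    cfg = SimulationConfig(n_probes=400, n_negative_controls=120, seed=7)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def medium_experiment():
    """A 3000-probe experiment for distribution-level checks."""
    cfg = SimulationConfig(n_probes=3000, n_negative_controls=300, seed=19)
    return simulate_experiment(cfg)


@pytest.fixture()
def design_3x4():
    samples = [f"{g}_r{r}" for g in ("2h", "4h", "12h") for r in (1, 2, 3, 4)]
    return SampleDesign(pd.DataFrame({
        "sample_id": samples,
        "group": [s.split("_")[0] for s in samples],
        "replicate": [int(s[-1]) for s in samples],
    }))


@pytest.fixture()
def random_matrix_3x4(design_3x4):
    rng = np.random.default_rng(123)
    return pd.DataFrame(
        rng.normal(8.0, 1.0, (60, 12)),
        index=[f"p{i}" for i in range(60)],
        columns=design_3x4.sample_ids,
    )
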
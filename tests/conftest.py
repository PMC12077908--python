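import numpy as np
import pandas as pd
import pytest

from pyroscore import SimulationConfig


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """A small cohort that keeps every downstream stage fast."""
    return SimulationConfig(
        seed=11,
        n_proteins=200,
        n_pathway=30,
        n_informative=10,
        n_hd=20,
        n_rrms=40,
        n_prog=40,
        n_treated=9,
        protein_severity_beta=1.0,
        n_patients=9,
    )


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    data = np.exp(rng.normal(5, 1, size=(8, 4)))
    return pd.DataFrame(
        data,
        index=[f"S{i}" for i in range(8)],
        columns=["P1", "P2", "P3", "P4"],
    )
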
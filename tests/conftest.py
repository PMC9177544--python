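import numpy as np
import pandas as pd
import pytest

from episig.core_io import BetaMatrix, SampleSheet
from episig.synth import SimulationConfig, simulate_cohort
from episig.workflow import run_discovery


@pytest.fixture(scope="session")
def small_sim():
    """Compact synthetic study reused across modules (seeded)."""
    cfg = SimulationConfig(
        seed=11,
        n_probes=3000,
        n_signature_cpgs=40,
        n_other_signature_cpgs=40,
        n_deconv_cpgs=200,
        n_clock_cpgs=50,
        n_validation_control=20,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Full discovery pass on the compact study."""
    return run_discovery(
        small_sim.beta,
        small_sim.sheet,
        small_sim.manifest,
        small_sim.cell_reference,
        small_sim.clock,
        seed=11,
    )


@pytest.fixture()
def toy_beta():
    return BetaMatrix(
        pd.DataFrame(
            {
                "S1": [0.1, 0.5, 0.9],
                "S2": [0.2, 0.6, 0.8],
            },
            index=["cg1", "cg2", "cg3"],
        )
    )


@pytest.fixture()
def toy_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2"],
                "group": ["case", "control"],
                "role": ["discovery_case", "discovery_control"],
                "sex": ["F", "M"],
                "age_years": [10.0, 12.0],
            }
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
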
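import numpy as np
import pandas as pd
import pytest

from pestewas import SimulationConfig, simulate_study
from pestewas.preprocess import CELL_TYPES


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study with planted probes, shared across tests."""
    cfg = SimulationConfig(
        n_cases=60, n_controls=40, n_probes=1500,
        effect_probes=25, effect_size_r=0.35, seed=5,
    )
    return simulate_study(cfg)


def make_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """A valid covariate table (with op_count) for residualization tests."""
    rng = np.random.default_rng(seed)
    cells = rng.dirichlet([3, 7, 3, 2, 4, 30], size=n)
    smoking = rng.choice(["never", "former", "current"], n)
    smoking[:3] = ["never", "former", "current"]  # keep the design full rank
    return pd.DataFrame(
        {
            "age": rng.normal(68, 10, n),
            "sex": rng.choice(["F", "M"], n),
            "ancestry": rng.integers(0, 2, n),
            "smoking": smoking,
            "wave": rng.choice(["PEG1", "PEG2"], n),
            **{c: cells[:, i] for i, c in enumerate(CELL_TYPES)},
            "op_count": rng.integers(0, 20, n).astype(float),
            "pd_status": rng.integers(0, 2, n),
        },
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="participant_id"),
    )
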
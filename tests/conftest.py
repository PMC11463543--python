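import numpy as np
import pandas as pd
import pytest

import endolyso as el


@pytest.fixture(scope="session")
def ip_sim():
    """One simulated dual-IP experiment with defaults, shared across tests."""
    cfg = el.SimConfig(n_proteins=300, seed=1)
    matrix, design, truth = el.simulate_ip_experiment(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def endo_results(ip_sim):
    _, matrix, design, _ = ip_sim
    return el.EnrichmentModel(matrix, design, stratum=("endo", "iNeuron")).fit()


@pytest.fixture()
def small_design():
    """Single-stratum 3+3 design."""
    rows = [{"channel": f"{cond}_{r}", "condition": cond, "ip_type": "endo",
             "cell_state": "iNeuron", "replicate": r}
            for cond in ("tagged", "control") for r in (1, 2, 3)]
    return el.DesignTable(pd.DataFrame(rows))


def log2_matrix(values: np.ndarray, design: el.DesignTable,
                proteins=None) -> el.IntensityMatrix:
    """Build a log2-scale IntensityMatrix from a plain array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=proteins, columns=design.channels)
    return el.IntensityMatrix(values=frame, design=design, log2=True)
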
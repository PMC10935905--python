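import numpy as np
import pandas as pd
import pytest

from sortgain import ScenarioConfig, simulate_population


@pytest.fixture(scope="session")
def k0_population():
    """Moderate-size population with no sorting on the gain (K = 0)."""
    return simulate_population(
        ScenarioConfig(knowledge_share=0.0, n_patients=20_000, seed=42)
    )


@pytest.fixture(scope="session")
def k1_population():
    """Full-knowledge population with a noise scale in the calibrated
    range, so sorting on the gain is strong."""
    return simulate_population(
        ScenarioConfig(knowledge_share=1.0, n_patients=20_000,
                       noise_sd=58.5, seed=43)
    )


def make_population(te, t, y, s=None, x=None):
    """Assemble a minimal hand-built population frame for fixtures."""
    n = len(te)
    s = np.zeros(n) if s is None else np.asarray(s, float)
    frame = {f"x{k}": np.zeros(n, dtype=int) for k in range(1, 7)}
    if x is not None:
        for k in range(x.shape[1]):
            frame[f"x{k + 1}"] = x[:, k]
    frame.update({
        "s": s, "u": np.zeros(n),
        "te": np.asarray(te, float), "ete": np.asarray(te, float),
        "evt": np.zeros(n), "t": np.asarray(t, float),
        "p_cure": np.full(n, 0.5), "y": np.asarray(y, float),
    })
    return pd.DataFrame(frame)
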
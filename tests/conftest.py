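import numpy as np
import pandas as pd
import pytest

from fdbind import SynthConfig, generate_dataset, normalize_columns, average_bscores


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic benchmark reused across tests (40 compounds)."""
    return generate_dataset(SynthConfig(n_compounds=40, n_proteins=60, seed=11))


@pytest.fixture(scope="session")
def small_xy(small_dataset):
    """Normalized descriptors and normalized average-Bscore target."""
    avg = average_bscores(small_dataset.B)
    Xn, _ = normalize_columns(small_dataset.X)
    yn, scaler = normalize_columns(avg.to_frame())
    return Xn, yn.iloc[:, 0], scaler


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def table3_bscores():
    """The seven least-active fullerenes' printed binding scores."""
    return pd.Series(
        {
            "FD168": 3938.3,  # pristine C60 (reference)
            "FD50": 4224.3,   # C70
            "FD169": 4398.5,  # C80H2
            "FD160": 4192.2,  # C60(OH)4
            "FD57": 4412.7,   # C60-CH-COOH
            "FD61": 4725.1,   # C60H34(OH)20
            "FD93": 4735.3,   # C60H26(OH)24
        }
    )
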
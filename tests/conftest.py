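import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: reduced montage with one electrode per cluster, for cheap pipeline tests
MONTAGE_9 = ("AF3", "F3", "FC3", "C3", "CP3", "P3", "PO3", "T7", "Cz")

#: the four temporal-cluster electrodes used for integrated-information tests
MONTAGE_T4 = ("T7", "T8", "TP7", "TP8")


@pytest.fixture(scope="session")
def small_synthetic_dataset():
    """One subject, 4 trials per condition, single-electrode clusters."""
    from imaware import synth

    cfg = synth.EffectConfig(seed=5, channels=MONTAGE_9)
    return synth.generate_subject(0, 4, cfg)
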
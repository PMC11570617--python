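import numpy as np
import pandas as pd
import pytest

from pdsubtype import synthio


@pytest.fixture
def behavior_table():
    """Six-rat crafted table spanning both groups and the rotation gate."""
    return pd.DataFrame(
        {
            "subject_id": [f"r{i}" for i in range(1, 7)],
            "group": ["control", "lesioned", "lesioned", "lesioned", "lesioned", "lesioned"],
            "rotations_per_min": [0, 4, 3, 10, 6, 5],
            "latency_s": [110.0, 30.0, 100.0, 25.0, 95.0, 40.0],
            "crossings": [70, 20, 65, 18, 60, 25],
            "mnss": [0, 8, 1, 9, 2, 7],
            "emg_area": [4.0, 5.0, 4.5, 20.0, 18.0, 4.2],
        }
    )


@pytest.fixture
def omics_config():
    return synthio.OmicsConfig(seed=7)


@pytest.fixture
def small_counts():
    """Hand-sized count matrix where sample s2 = 2 x sample s1."""
    return pd.DataFrame(
        {
            "s1": [10, 20, 30, 40, 50],
            "s2": [20, 40, 60, 80, 100],
        },
        index=pd.Index([f"g{i}" for i in range(1, 6)], name="gene_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
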
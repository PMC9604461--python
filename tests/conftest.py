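import numpy as np
import pandas as pd
import pytest

from diaphos.io import QuantMatrix


def make_design(stages=("D", "PD", "FPD"), n_replicates=3) -> pd.DataFrame:
    rows = [
        (f"{s}_{r + 1}", s, r + 1) for s in stages for r in range(n_replicates)
    ]
    return pd.DataFrame(rows, columns=["sample", "stage", "replicate"]).set_index("sample")


def make_matrix(values, feature_ids=None, stages=("D", "PD", "FPD"), n_replicates=3) -> QuantMatrix:
    """Linear-scale QuantMatrix from an array of shape (features, stages*reps)."""
    values = np.asarray(values, dtype=float)
    design = make_design(stages, n_replicates)
    if feature_ids is None:
        feature_ids = [f"F{i + 1}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=feature_ids, columns=list(design.index))
    return QuantMatrix(frame, design, scale="linear")


@pytest.fixture
def design():
    return make_design()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
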
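import numpy as np
import pandas as pd
import pytest

from escctraj.matrix import ExpressionMatrix
from escctraj.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared across tests (seed fixed)."""
    cfg = SimConfig(seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast structural tests."""
    cfg = SimConfig(seed=7, n_healthy=10, n_patients=40, n_proteins=300,
                    subtype_signature_size=60, cell_signature_size=15,
                    n_risk_proteins=10)
    return generate_cohort(cfg)


def tissue_samples(meta: pd.DataFrame, tissue: str) -> list[str]:
    return meta.loc[meta["tissue"] == tissue, "sample_id"].tolist()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_matrix():
    data = pd.DataFrame(
        [[0.0, 1.0, -1.0], [2.0, np.nan, 0.5], [-0.3, 0.1, 0.2]],
        index=["P1", "P2", "P3"], columns=["S1", "S2", "S3"])
    return ExpressionMatrix(data)
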
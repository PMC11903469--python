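import numpy as np
import pandas as pd
import pytest

from gesig.cohort import ClinicalTable, ExpressionMatrix
from gesig.simulate import SimulationConfig, generate_cohort


def make_clinical_frame(n: int, seed: int = 0) -> pd.DataFrame:
    """A small hand-constructed clinical table, one subject per sample."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "subject_id": [f"P{i}" for i in range(n)],
            "arm": ["axi-cel"] * n,
            "timepoint": ["pretreatment"] * n,
            "collection_date": ["2020-01-01"] * n,
            "batch_id": list(range(1, n + 1)),
            "coding_read_fraction": [0.5] * n,
            "coo": ["GCB"] * n,
            "hgbl_flag": ["not_applicable"] * n,
            "double_expressor_flag": ["not_applicable"] * n,
            "myc_rearranged_flag": ["not_applicable"] * n,
            "responder_flag": ["yes"] * n,
            "dor_time": rng.uniform(10, 400, n).round(2),
            "dor_event": rng.integers(0, 2, n).astype(float),
            "efs_time": rng.uniform(10, 400, n).round(2),
            "efs_event": rng.integers(0, 2, n).astype(float),
            "pfs_time": rng.uniform(10, 400, n).round(2),
            "pfs_event": rng.integers(0, 2, n).astype(float),
        }
    )


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["S0", "S1"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture
def toy_clinical() -> ClinicalTable:
    return ClinicalTable(make_clinical_frame(5))


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated cohort with strong planted effects, reused across tests."""
    cfg = SimulationConfig(n_samples=150, n_genes=30, seed=7)
    return generate_cohort(cfg)
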
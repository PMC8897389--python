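import numpy as np
import pandas as pd
import pytest

from gammatc.counts_io import CountMatrix
from gammatc.simulate import SimConfig, generate_counts, generate_study_tables


def make_count_matrix(values: np.ndarray, genes=None, times=None, doses=None):
    """Small CountMatrix helper: one sample per column."""
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    times = times if times is not None else [0.0] * n_samples
    doses = doses if doses is not None else [0.5] * n_samples
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samples)],
        "time_h": times, "dose_gy": doses,
        "replicate": list(range(1, n_samples + 1)),
    })
    df = pd.DataFrame(values.astype(float), index=genes,
                      columns=sheet["sample_id"])
    return CountMatrix(values=df, samples=sheet)


@pytest.fixture(scope="session")
def sim_small():
    """Small planted simulation shared across tests (8-fold, baseline ~200)."""
    cfg = SimConfig(seed=11, n_genes=500,
                    baseline_log_mean=float(np.log(200.0)),
                    baseline_log_sd=0.3, dispersion=0.05)
    cm, truth = generate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def study_tables():
    return generate_study_tables(seed=20240901 % (2**31))
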
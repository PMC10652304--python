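import numpy as np
import pandas as pd
import pytest

from redoxsens.datasets import load_oa_joint_top20
from redoxsens.synthetic import SyntheticConfig, generate_proteome


@pytest.fixture(scope="session")
def top20():
    """Bundled reference ranking of top-scoring OA joint proteins."""
    return load_oa_joint_top20()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_proteins_total=60,
        n_detected=30,
        length_range=(50, 300),
        n_replicates=3,
        noise_scale=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_proteome(small_config):
    records, truth = generate_proteome(small_config)
    return records, truth


def make_evidence(rows):
    """Build an evidence frame from (protein, site, mod, condition, rep, qty)."""
    return pd.DataFrame(
        rows,
        columns=["protein_id", "site", "modification", "condition", "replicate", "quantity"],
    )
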
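import numpy as np
import pandas as pd
import pytest

from crdmarkers import pipeline, simulate


@pytest.fixture(scope="session")
def paper_design():
    """The full array design: 24 baseline + 2 protocols x 4 stages x 6 ZTs x 2."""
    return simulate.generate_design()


@pytest.fixture(scope="session")
def small_config():
    """Reduced study: 340 genes, full design — fast but non-trivial."""
    return pipeline.validate_config(
        {"genes": {"n_null": 300, "n_circadian": 30, "n_crd": 10, "n_crd_secreted": 5,
                   "noise_sd": 0.2}}
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """One in-memory run of the reduced study, shared across tests."""
    return pipeline.run_study(small_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240501)


def make_probe_matrix(values_by_scan: dict, probes, spots) -> pd.DataFrame:
    """Assemble a spot-level probe matrix from per-(sample, channel) vectors."""
    cols = pd.MultiIndex.from_tuples(values_by_scan.keys(), names=["sample_id", "channel"])
    idx = pd.MultiIndex.from_product([probes, spots], names=["probe_id", "spot"])
    return pd.DataFrame(
        np.column_stack(list(values_by_scan.values())), index=idx, columns=cols
    )
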
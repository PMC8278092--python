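import pandas as pd
import pytest

from cernet.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A small but complete cohort configuration used across tests."""
    return CohortConfig(n_mrna=60, n_lncrna=20, n_mirna=20, n_stable_mirna=4,
                        n_per_group=15, n_circuits=3, n_decoys=10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def two_group_labels():
    def make(n_per_group, prefix=("a", "b")):
        samples = [f"{prefix[0]}{i}" for i in range(n_per_group)] + \
                  [f"{prefix[1]}{i}" for i in range(n_per_group)]
        return pd.Series([prefix[0]] * n_per_group + [prefix[1]] * n_per_group,
                         index=samples)
    return make
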
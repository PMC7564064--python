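import warnings

import pytest

import ecoqsar as eq
from ecoqsar.synthetic import SyntheticQSARSpec, generate_synthetic_qsar

DMP_SMILES = "COC(=O)c1ccccc1C(=O)OC"
DAP_SMILES = "C=CCOC(=O)c1ccccc1C(=O)OCC=C"


@pytest.fixture(scope="session")
def table1():
    return eq.load_fixture("table1")


@pytest.fixture(scope="session")
def table7():
    return eq.load_fixture("table7")


@pytest.fixture(scope="session")
def table9():
    return eq.load_fixture("table9")


@pytest.fixture(scope="session")
def derivative_records(table7):
    """The derivative rows of the reference effect table (parents excluded)."""
    return table7[table7["parent"].notna() & (table7["parent"] != "")]


@pytest.fixture(scope="session")
def dmp_prepared():
    """DMP embedded, minimized, and parameterized (shared; treat as read-only)."""
    return eq.prepare(DMP_SMILES, "DMP")


@pytest.fixture(scope="session")
def synthetic_noiseless():
    return generate_synthetic_qsar(SyntheticQSARSpec(seed=11, noise_sigma=0.0))


@pytest.fixture(scope="session")
def synthetic_noisy():
    return generate_synthetic_qsar(SyntheticQSARSpec(seed=11, noise_sigma=None, snr=3.0))


@pytest.fixture(scope="session")
def group_summary_frame(table9, table7):
    from ecoqsar.coupling import coupling_table, group_summaries
    from ecoqsar.fixtures import group_volumes

    cdf = coupling_table(table9, group_volumes())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the propyl group has no effect rows
        return group_summaries(cdf, table7[table7["parent"].notna()])
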
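import numpy as np
import pytest

from ctrlrisk.cli_io import load_schizophrenia_records
from ctrlrisk.data_model import ModelParams, StudyRecord
from ctrlrisk.observed import observed_from_records


@pytest.fixture(scope="session")
def schizo_records():
    return load_schizophrenia_records()


@pytest.fixture(scope="session")
def schizo_triples(schizo_records):
    triples, _ = observed_from_records(schizo_records)
    return triples


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_exact_records():
    """Five synthetic two-arm studies for exact-likelihood oracle checks."""
    rng = np.random.default_rng(5)
    records = []
    for i in range(5):
        n_treat, n_control = rng.integers(15, 201, 2)
        xi = rng.standard_normal()
        eta = xi + np.sqrt(0.5) * rng.standard_normal()
        p_eta = 1.0 / (1.0 + np.exp(-eta))
        p_xi = 1.0 / (1.0 + np.exp(-xi))
        records.append(StudyRecord(
            study_id=f"s{i}",
            y_events=int(rng.binomial(n_treat, p_eta)), n_treat=int(n_treat),
            x_events=int(rng.binomial(n_control, p_xi)), n_control=int(n_control),
        ))
    return records


@pytest.fixture(scope="session")
def classical_params():
    return ModelParams(beta0=0.1, beta1=0.9, mu_xi=-0.2, tau2=0.3, sigma_xi2=0.8)
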
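import logging

import pytest

from evprot.batch import correct_batches
from evprot.io import to_log10
from evprot.simulate import SimulationConfig, bridge_pairs, simulate_cohort

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def cohort():
    """One default-size cohort shared across tests (seed fixed)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A lighter cohort for plumbing tests."""
    return simulate_cohort(SimulationConfig(seed=7, n_proteins=120))


@pytest.fixture(scope="session")
def corrected_serum(cohort):
    pairs = bridge_pairs(cohort.info, "serum")
    return correct_batches(cohort.tables["serum"], cohort.info, pairs)


@pytest.fixture(scope="session")
def log_serum(corrected_serum):
    return to_log10(corrected_serum)
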
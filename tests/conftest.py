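import numpy as np
import pandas as pd
import pytest

from senosig import synthetic_data as syn
from senosig import signature_derivation as sig


@pytest.fixture(scope="session")
def default_catalog():
    """Default synthetic catalog with planted truth (shared, read-only)."""
    return syn.simulate_catalog(syn.CatalogSimConfig(seed=11))


@pytest.fixture(scope="session")
def default_records(default_catalog):
    catalog, _ = default_catalog
    return sig.catalog_differential_records(catalog)


@pytest.fixture(scope="session")
def default_cohort(default_catalog):
    """Default cohort aligned with the default catalog truth."""
    _, truth = default_catalog
    cohort, truth = syn.simulate_cohort(
        syn.CohortSimConfig(n_participants=800, seed=12), truth
    )
    return cohort, truth


def make_records(rows):
    """DifferentialRecord table from (protein, cell_type, induction, lfc, p)."""
    return pd.DataFrame(
        rows, columns=["protein", "cell_type", "induction", "log2fc", "p_adj"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
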
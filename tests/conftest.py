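import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles module

from bglccr import (
    SimulationConfig,
    classify_records,
    default_reference,
    gen_sequences,
)


@pytest.fixture(scope="session")
def profile():
    return default_reference()


@pytest.fixture(scope="session")
def small_gene_set():
    """Twelve synthetic genes (half tolerant) plus their planted truth."""
    config = SimulationConfig(n_genes=12, seed=7)
    records, truth = gen_sequences(config)
    return records, truth


@pytest.fixture(scope="session")
def small_calls(small_gene_set, profile):
    records, _ = small_gene_set
    return classify_records(records, profile)


@pytest.fixture()
def truth_calls_frame():
    """A call table straight from planted labels, for TE-side tests that do
    not need the sequence classifier."""

    def _make(truth):
        return pd.DataFrame(
            {"gene_id": list(truth.labels), "call": list(truth.labels.values())}
        )

    return _make
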
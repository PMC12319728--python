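import numpy as np
import pandas as pd
import pytest

from modality_iwas import SimParams, simulate_dataset, dataset_to_tables
from modality_iwas.sumstats_io import GWAS_COLUMNS, GwasTable


@pytest.fixture(scope="session")
def small_dataset():
    """A small continuous-trait dataset shared across tests."""
    return simulate_dataset(SimParams(n=500, J=12, K=3, seed=7))


@pytest.fixture(scope="session")
def small_tables(small_dataset):
    return dataset_to_tables(small_dataset)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from modality_iwas.fixtures import write_fixture_set

    out = tmp_path_factory.mktemp("toy")
    paths = write_fixture_set(out, seed=3)
    return out, paths


def make_gwas_table(rows, trait_id="t"):
    """Build a GwasTable from (snp_id, chrom, pos, a1, a2, z, n) tuples."""
    df = pd.DataFrame(rows, columns=GWAS_COLUMNS)
    return GwasTable(df, trait_id=trait_id)
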
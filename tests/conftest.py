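import numpy as np
import pandas as pd
import pytest

from clonecna import SimConfig, simulate_cohort
from clonecna.genome import GenomeModel


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-tumour noise-free cohort with planted truth, shared across tests."""
    return simulate_cohort(SimConfig(seed=42, n_tumours=12))


@pytest.fixture()
def one_chrom_genome():
    return GenomeModel(("chr1",), (50_000_000,))


def make_segments(rows):
    """rows: (region_id, chromosome, start, end, total_cn) in internal coords."""
    return pd.DataFrame(rows, columns=["region_id", "chromosome", "start", "end", "total_cn"])


def make_meta(rows):
    """rows: (region_id, tumour_id, ploidy)."""
    return pd.DataFrame(rows, columns=["region_id", "tumour_id", "ploidy"])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
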
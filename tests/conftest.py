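import numpy as np
import pandas as pd
import pytest

from molqtl import synth
from molqtl.datatypes import PhenotypeMatrix, SimConfig


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale panel configuration shared across tests."""
    return SimConfig(
        n_strains=40, n_snps=300, n_chromosomes=5, chrom_length_bp=20_000_000,
        n_transcripts=60, n_peptides=90, n_traits=6, n_genes=40,
        seed=1234,
    )


@pytest.fixture(scope="session")
def panel(small_cfg):
    return synth.simulate_panel(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def replicated_matrix(values, n_strains, n_reps, kind="transcript"):
    """Features x (strain, replicate) PhenotypeMatrix from a 2-D array."""
    cols = pd.MultiIndex.from_product(
        [[f"S{i:03d}" for i in range(n_strains)],
         [f"rep{j + 1}" for j in range(n_reps)]],
        names=["strain", "replicate"],
    )
    vals = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"f{i}" for i in range(len(values))], columns=cols,
    )
    return PhenotypeMatrix(values=vals, kind=kind)
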
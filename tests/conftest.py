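import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cytopred.core import GenotypeMatrix
from cytopred.synthio import SimConfig, simulate_cohort


def make_genotypes(dosages, chrom="1", start_pos=1_000_000, spacing=10_000,
                   ids=None):
    """Small hand-specified genotype panel for fixtures."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "chrom": [chrom] * m,
        "pos": [start_pos + i * spacing for i in range(m)],
        "id": ids if ids is not None else [f"v{i}" for i in range(m)],
        "ref": ["A"] * m,
        "alt": ["G"] * m,
    })
    return GenotypeMatrix(dosages=dosages, variants=variants)


@pytest.fixture(scope="session")
def tcr_cohort():
    """Small genetics-dominant cohort reused across tests."""
    return simulate_cohort(SimConfig.tcr_like(n_individuals=300, seed=11,
                                              n_blocks=20, block_size=20))


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(SimConfig.null(n_individuals=200, seed=13,
                                          n_blocks=10, block_size=20))
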
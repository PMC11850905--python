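import numpy as np
import pandas as pd
import pytest

from sacscreen import io, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_library():
    return simulate.make_library(n_genes=5, guides_per_gene=2, seed=11)


@pytest.fixture
def paired_sheet():
    return io.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["control_r1", "treated_r1", "control_r2", "treated_r2"],
                "barcode": ["AACCGG", "CCGGTT", "GGTTAA", "TTAACC"],
                "condition": ["control", "treated", "control", "treated"],
                "replicate": ["r1", "r1", "r2", "r2"],
            }
        )
    )


@pytest.fixture
def screen_sim(paired_sheet):
    """A 50-guide paired screen: library, counts and ground-truth ledger."""
    library = simulate.make_library(n_genes=25, guides_per_gene=2, seed=21)
    config = simulate.ScreenSimConfig(
        n_replicates=2, depth_per_guide=30.0, nb_dispersion=0.1, seed=22
    )
    counts, ledger = simulate.simulate_counts(library, config)
    return library, counts, ledger
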
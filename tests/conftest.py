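import warnings

import numpy as np
import pandas as pd
import pytest

from paincell import synthio

# generator warnings (e.g. planned all-zero annotations on tiny fixtures)
# are exercised explicitly in the tests that assert them
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (6,000 variants / 60 blocks / 600 genes / 8 clusters)
    shared by tests that only need a consistent, signal-bearing bundle."""
    return synthio.simulate_study(
        n_variants=6_000, n_blocks=60, n_genes=600, n_clusters=8, seed=11
    )


@pytest.fixture(scope="session")
def small_panel():
    return synthio.simulate_ld_panel(2_000, 20, within_block_correlation=0.5, seed=0)


@pytest.fixture()
def all_ones_annotation(small_panel):
    ann = pd.DataFrame(
        {"all": np.ones(small_panel.n_variants)},
        index=small_panel.variants["SNP"].to_numpy(),
    )
    ann.index.name = "SNP"
    return ann
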
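import numpy as np
import pandas as pd
import pytest

from streamdapc import OtuTable, SiteMetadata, SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def moderate_dataset():
    """82-site community with a moderate planted condition signal."""
    return simulate_dataset(SyntheticConfig(seed=42, effect_size=1.0))


@pytest.fixture(scope="session")
def strong_dataset():
    """Low-noise community where 5 planted taxa carry the whole signal."""
    return simulate_dataset(
        SyntheticConfig(seed=7, effect_size=4.0, n_signal_taxa=5, dispersion=2000.0)
    )


def make_table(counts, sample_ids=None, taxon_ids=None, attrs=None):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"S{i}" for i in range(counts.shape[0])]
    taxon_ids = taxon_ids or [f"Otu{j}" for j in range(counts.shape[1])]
    return OtuTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids), attrs
    )


def make_metadata(bibi, sample_ids=None, **extra):
    sample_ids = sample_ids or [f"S{i}" for i in range(len(bibi))]
    return SiteMetadata(pd.DataFrame({"bibi": bibi, **extra}, index=sample_ids))
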
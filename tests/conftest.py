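import numpy as np
import pandas as pd
import pytest

from ewsrepo import SynConfig, syndata


@pytest.fixture(scope="session")
def syn_small() -> SynConfig:
    """Compact study: small universe, a few planted drugs, zero noise."""
    return SynConfig(seed=11, n_genes=400, n_drugs=30, instances_per_drug=(1, 3),
                     n_planted_reversers=3, n_planted_mimics=2,
                     signature_size=20, noise_sd=0.0)


@pytest.fixture(scope="session")
def disease_sig(syn_small):
    return syndata.gen_signature(syn_small, "disease")


@pytest.fixture(scope="session")
def drug_db(syn_small, disease_sig):
    return syndata.gen_drug_profiles(syn_small, disease_sig)


def ranking_from_order(genes_in_rank_order) -> pd.Series:
    """gene -> rank Series; first listed gene gets rank 1 (most up)."""
    return pd.Series(np.arange(1, len(genes_in_rank_order) + 1),
                     index=list(genes_in_rank_order), dtype=float)
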
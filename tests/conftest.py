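import numpy as np
import pytest

from kanpm.core_data import ModelConfig
from kanpm.synthetic_data import SyntheticConfig, gen_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SyntheticConfig(
        n_proteins=8, n_drugs=8, n_pairs=48,
        protein_len_range=(12, 24), drug_atoms_range=(3, 12),
        embed_dim_protein=16, embed_dim_drug=8,
        latent_dim=2, noise_sd=0.1, seed=7,
    )
    return cfg, gen_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_model_config():
    """A model configuration small enough for second-scale forward passes."""
    return ModelConfig.tiny(
        tf_dim=16, tf_ff_dim=16, tf_heads=4,
        protein_graph_hidden=8, protein_graph_out=8,
        drug_graph_hidden=8, drug_graph_out=8,
        fusion_att_dim=4, kan_hidden=(8,),
        protein_embed_dim=16, drug_embed_dim=8, protein_graph_in=16,
        epochs=4, batch_size=16,
    )
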
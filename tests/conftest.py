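import numpy as np
import pytest

from scpareto import SimSpec, TrainConfig, simulate_zinb_dataset
from scpareto.vae import ZinbVae, compute_library_prior


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-batch, three-type count dataset with known truth."""
    ds, truth = simulate_zinb_dataset(SimSpec(n=400, G=25, seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def tiny_train_config():
    """Scaled-down training configuration for fast exercises."""
    return TrainConfig(K=3, d_z=4, hidden=16, mine_hidden=16, mine_layers=2,
                       pre_epochs=4, pre_adv_epochs=3, pre_adv_lr=1e-3,
                       epochs=3, init_epochs=1, adv_epochs=1, adv_lr=1e-3,
                       mine_warmup_epochs=3, eval_mine_epochs=4,
                       eval_shuffles=5, batch_size=64, seed=5)


@pytest.fixture(scope="session")
def tiny_vae(small_dataset):
    ds, _ = small_dataset
    prior = compute_library_prior(ds)
    vae = ZinbVae(ds.n_genes, ds.n_batches, d_z=3, hidden=16,
                  library_log_mean=float(np.log(ds.counts.sum(1)).mean()),
                  seed=3)
    return vae, ds, prior
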
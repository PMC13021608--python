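import numpy as np
import pytest

from lesionbai.ban import BanConfig, build_network, split_dataset, train
from lesionbai.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 phantoms, half glioma, fixed seed; shared read-only across tests."""
    return generate_cohort(
        PhantomConfig(n_subjects=20, glioma_fraction=0.5, seed=1)
    )


@pytest.fixture(scope="session")
def tiny_trained_ban(small_cohort):
    """A briefly trained tiny network on the small cohort's controls.

    Deliberately under-trained (3 epochs): sufficient for contracts that do
    not depend on accuracy (determinism, lesion invariance, geometry
    checks).
    """
    co = small_cohort
    ages = co.subjects["age"].to_numpy()
    controls = np.flatnonzero((co.subjects["grade"] == "none").to_numpy())
    cfg = BanConfig(
        conv_channels=(2, 4), blocks_per_stage=(1, 1), max_epochs=3,
        batch_size=8, learning_rate=0.01, seed=3,
    )
    model = build_network(cfg)
    return train(
        model, co.volumes, co.masks, ages, (controls[:-2], controls[-2:]), cfg
    )
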
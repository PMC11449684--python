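import numpy as np
import pytest

from actsign import (ActivationSpec, PhantomSpec, SplitSpec, TrainConfig,
                     build_network, default_network, generate_phantoms,
                     split_dataset, train)


@pytest.fixture(scope="session")
def small_phantoms():
    """A small, quick 4-class phantom set (64x64, 30 per class)."""
    return generate_phantoms(
        PhantomSpec(n_per_class=30, image_size=(64, 64), noise_sd=0.05, seed=11))


@pytest.fixture(scope="session")
def trained_small_model(small_phantoms):
    """A briefly trained small model plus its splits (shared across tests)."""
    tr, va, te = split_dataset(small_phantoms, SplitSpec(seed=5))
    net = default_network(input_shape=(64, 64, 3))
    model = build_network(net, ActivationSpec("rectified_softsign"), seed=5)
    model, history = train(model, tr, va,
                           TrainConfig(max_epochs=25, batch_size=8, seed=5))
    return {"model": model, "net": net, "history": history,
            "train": tr, "val": va, "test": te}
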
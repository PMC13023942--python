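import numpy as np
import pytest

from fenoct import (NetConfig, PhantomConfig, desk_preset, make_dataset,
                    make_phantom, train)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trained_denoiser():
    """The scaled-down self-supervised training run: 320 steps on 64 noisy
    64x64 phantoms (speckle k=4 + periodic background), fixed seed.

    Session-scoped because training takes minutes; shared by the
    end-to-end denoising-gain check and the inference-stability check.
    Returns (network, held-out PhantomTruth list, manifest).
    """
    cfg = PhantomConfig(size=(64, 64), stripe_count=0, seed=100)
    truths = make_dataset(cfg, 88)
    train_set = [t.noisy for t in truths[:64]]
    val_set = [t.noisy for t in truths[64:72]]
    tc = desk_preset(seed=1, epochs=20, steps_per_epoch=16)  # 320 steps
    net, manifest = train(train_set, val_set, NetConfig(base_channels=32), tc)
    return net, truths[72:88], manifest


@pytest.fixture(scope="session")
def small_phantom():
    """A 64x64 phantom with all three noise types (session-cached)."""
    return make_phantom(PhantomConfig(size=(64, 64), seed=7))


@pytest.fixture(scope="session")
def clean_noisy_128():
    """A 128x128 phantom, speckle + background only."""
    return make_phantom(PhantomConfig(size=(128, 128), stripe_count=0, seed=11))
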
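import numpy as np
import pytest

from bladdervol.frames import LONGITUDINAL, TRANSVERSE
from bladdervol.phantom import PhantomSpec, generate_dataset, generate_phantom


def make_spec(**kwargs) -> PhantomSpec:
    """PhantomSpec with small-image defaults suitable for fast tests."""
    defaults = dict(
        semi_axes=(2.0, 1.6, 2.4),
        pixel_spacing=(0.5, 0.5),
        image_size=(256, 192),
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture
def noiseless_pair():
    """A clean, untruncated phantom pair (no speckle, no blur)."""
    return generate_phantom(make_spec(speckle_scale=0.0, blur_sigma=0.0))


@pytest.fixture
def speckle_pair():
    """A phantom pair with default speckle and blur."""
    return generate_phantom(make_spec(seed=11))


@pytest.fixture(scope="session")
def scaled_training():
    """One scaled-down network training run shared by the slow tests.

    100 two-section phantoms (200 frame/mask training pairs) plus 15
    held-out phantoms, trained at 96x64 for 10 epochs with a raised
    learning rate and class-weighted loss appropriate for the short
    schedule.
    """
    from bladdervol.segmentation import AugmentationConfig, TrainingConfig
    from bladdervol.segmentation.train import train

    pairs, _ = generate_dataset(115, seed=42)
    data = []
    for p in pairs:
        data.append((p.transverse_frame, p.transverse_mask))
        data.append((p.longitudinal_frame, p.longitudinal_mask))
    train_set, val_set = data[:200], data[200:230]
    config = TrainingConfig(
        epochs=10,
        initial_lr=0.1,
        lr_step_epochs=50,
        batch_size=4,
        seed=0,
        class_weights=(1.0, 3.0),
        augmentation=AugmentationConfig(resize_to=(96, 64)),
    )
    model, history = train(train_set, config, validation=val_set)
    return {
        "model": model,
        "history": history,
        "config": config,
        "train_set": train_set,
        "val_set": val_set,
        "holdout_phantoms": pairs[100:],
    }
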
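"""Both segmentation backends, augmentation and the training loop."""

import numpy as np
import pytest

from bladdervol.evaluation import dice
from bladdervol.frames import NoBladderDetected, TRANSVERSE, UltrasoundFrame
from bladdervol.geometry import postprocess_mask
from bladdervol.phantom import generate_dataset, generate_phantom
from bladdervol.segmentation import (
    AugmentationConfig,
    FCNQuarterVGG,
    SegmentationModelSpec,
    TrainingConfig,
    augment,
    classical_segment,
    predict_mask,
)
from bladdervol.segmentation.fcn import QUARTER_VGG16_CHANNELS
from bladdervol.segmentation.train import train

from .conftest import make_spec


class TestClassical:
    def test_noiseless_phantom_high_dice(self, noiseless_pair):
        for frame, truth in (
            (noiseless_pair.transverse_frame, noiseless_pair.transverse_mask),
            (noiseless_pair.longitudinal_frame, noiseless_pair.longitudinal_mask),
        ):
            mask = postprocess_mask(classical_segment(frame))
            assert dice(mask, truth) >= 0.98

    def test_default_speckle_phantom_dice(self):
        pairs, _ = generate_dataset(8, seed=21)
        for p in pairs:
            mask = postprocess_mask(classical_segment(p.transverse_frame))
            assert dice(mask, p.transverse_mask) >= 0.90

    def test_uniform_frame_raises(self):
        frame = UltrasoundFrame(
            image=np.full((96, 128), 0.4, dtype=np.float32), section=TRANSVERSE, spacing=0.5
        )
        with pytest.raises(NoBladderDetected):
            classical_segment(frame)

    def test_flip_equivariance(self, speckle_pair):
        frame = speckle_pair.transverse_frame
        flipped = UltrasoundFrame(
            image=frame.image[:, ::-1].copy(), section=frame.section, spacing=frame.spacing
        )
        m = classical_segment(frame)
        mf = classical_segment(flipped)
        assert np.array_equal(mf, m[:, ::-1])


class TestAugment:
    def _identity_config(self, size):
        return AugmentationConfig(
            brightness_range=(0.0, 0.0),
            contrast_range=(1.0, 1.0),
            horizontal_flip_probability=1.0,
            resize_to=size,
        )

    def test_double_flip_is_involution(self, noiseless_pair):
        frame = noiseless_pair.transverse_frame
        mask = noiseless_pair.transverse_mask
        cols, rows = frame.shape[1], frame.shape[0]
        config = self._identity_config((cols, rows))
        f1, m1 = augment(frame, mask, config, seed=0)
        f2, m2 = augment(f1, m1, config, seed=0)
        assert np.allclose(f2.image, frame.image, atol=1e-6)
        assert np.array_equal(m2, mask)

    def test_photometric_only_leaves_mask_untouched(self, speckle_pair):
        frame = speckle_pair.transverse_frame
        mask = speckle_pair.transverse_mask
        config = AugmentationConfig(
            horizontal_flip_probability=0.0, resize_to=(frame.shape[1], frame.shape[0])
        )
        _, m = augment(frame, mask, config, seed=4)
        assert np.array_equal(m, mask)

    def test_output_resized_to_network_size(self, speckle_pair):
        config = AugmentationConfig(resize_to=(512, 384))
        f, m = augment(speckle_pair.transverse_frame, speckle_pair.transverse_mask, config, 1)
        assert f.shape == (384, 512)
        assert m.shape == (384, 512)

    def test_resize_rescales_spacing(self, speckle_pair):
        frame = speckle_pair.transverse_frame  # 256x192 at 0.5 mm/px
        config = AugmentationConfig(horizontal_flip_probability=0.0, resize_to=(128, 96))
        f, _ = augment(frame, speckle_pair.transverse_mask, config, 0)
        assert f.spacing[0] == pytest.approx(0.5 * 192 / 96)
        assert f.spacing[1] == pytest.approx(0.5 * 256 / 128)

    def test_deterministic_given_seed(self, speckle_pair):
        config = AugmentationConfig(resize_to=(128, 96))
        f1, m1 = augment(speckle_pair.transverse_frame, speckle_pair.transverse_mask, config, 9)
        f2, m2 = augment(speckle_pair.transverse_frame, speckle_pair.transverse_mask, config, 9)
        assert np.array_equal(f1.image, f2.image) and np.array_equal(m1, m2)


class TestArchitecture:
    def test_encoder_channels_are_quarter_vgg16(self):
        assert QUARTER_VGG16_CHANNELS == ((16, 16), (32, 32), (64, 64, 64), (128, 128, 128), (128, 128, 128))
        model = FCNQuarterVGG(SegmentationModelSpec(input_size=(64, 32)))
        convs = [l for block in model.blocks for l in block if hasattr(l, "weight")]
        got = tuple(c.weight.shape[0] for c in convs)
        assert got == (16, 16, 32, 32, 64, 64, 64, 128, 128, 128, 128, 128, 128)

    def test_input_size_must_allow_five_poolings(self):
        with pytest.raises(ValueError):
            SegmentationModelSpec(input_size=(100, 60))

    def test_logits_shape_matches_input(self):
        model = FCNQuarterVGG(SegmentationModelSpec(input_size=(64, 32)))
        out = model.forward(np.zeros((2, 1, 32, 64), dtype=np.float32))
        assert out.shape == (2, 2, 32, 64)


class TestLearningRateSchedule:
    def test_closed_form_at_step_boundaries(self):
        config = TrainingConfig(epochs=200, initial_lr=1e-4, lr_step_epochs=50)
        assert config.learning_rate(0) == pytest.approx(1e-4)
        assert config.learning_rate(49) == pytest.approx(1e-4)
        assert config.learning_rate(50) == pytest.approx(1e-5)
        assert config.learning_rate(100) == pytest.approx(1e-6)
        assert config.learning_rate(150) == pytest.approx(1e-7)

    def test_matches_closed_form_every_epoch(self):
        config = TrainingConfig(epochs=200, initial_lr=1e-4, lr_step_epochs=50)
        for e in range(200):
            assert config.learning_rate(e) == 1e-4 / 10 ** (e // 50)


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainingConfig(epochs=1))

    def test_history_length_and_improvement_small_run(self):
        pairs, _ = generate_dataset(
            15, seed=5, base_spec=make_spec()
        )
        data = []
        for p in pairs:
            data.append((p.transverse_frame, p.transverse_mask))
            data.append((p.longitudinal_frame, p.longitudinal_mask))
        config = TrainingConfig(
            epochs=3,
            initial_lr=0.1,
            class_weights=(1.0, 3.0),
            seed=0,
            augmentation=AugmentationConfig(resize_to=(64, 32)),
        )
        model, history = train(data, config)
        assert len(history["loss"]) == 3
        assert history["dice"][-1] > history["dice"][0]
        assert history["lr"] == [0.1, 0.1, 0.1]

    def test_predict_mask_shape_and_threshold(self):
        model = FCNQuarterVGG(SegmentationModelSpec(input_size=(64, 32)))
        pair = generate_phantom(make_spec())
        mask = predict_mask(model, pair.transverse_frame)
        assert mask.shape == pair.transverse_frame.shape
        assert mask.dtype == bool


class TestTrainedModel:
    def test_validation_dice_on_noiseless_phantom(self, scaled_training):
        model = scaled_training["model"]
        pair = generate_phantom(make_spec(speckle_scale=0.0, blur_sigma=0.0, seed=99))
        mask = predict_mask(model, pair.transverse_frame)
        assert dice(mask, pair.transverse_mask) >= 0.90
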
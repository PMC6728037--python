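"""Quarter-width VGG16 encoder with an FCN-8s decoder, in numpy.

The encoder is the 13-convolution VGG16 stack with every channel count
divided by four — blocks of (16, 16), (32, 32), (64, 64, 64),
(128, 128, 128), (128, 128, 128) channels, each followed by 2x2 max
pooling.  The decoder is FCN-8s: 1x1 score layers on the stride-8,
stride-16 and stride-32 feature maps, fused by successive 2x upsampling
and addition, then upsampled 8x to a per-pixel two-class label map.
Upsampling uses fixed bilinear resampling.

Input frames are resized to the configured network size (512x384 by
default), intensities centred to [-0.5, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from ..frames import UltrasoundFrame
from .nn import BilinearResize, Conv2d, LeakyReLU, MaxPool2, softmax

#: VGG16 per-block channel counts divided by four
QUARTER_VGG16_CHANNELS: Tuple[Tuple[int, ...], ...] = (
    (16, 16),
    (32, 32),
    (64, 64, 64),
    (128, 128, 128),
    (128, 128, 128),
)


@dataclass
class SegmentationModelSpec:
    """Architecture description recorded alongside checkpoints."""

    input_size: Tuple[int, int] = (512, 384)  # (width, height)
    num_classes: int = 2
    encoder_channels: Tuple[Tuple[int, ...], ...] = QUARTER_VGG16_CHANNELS
    head_channels: int = 256
    pretrained_encoder: Optional[str] = None

    def __post_init__(self):
        w, h = self.input_size
        if w % 32 or h % 32:
            raise ValueError("input size must be divisible by 32 (five pooling stages)")


class FCNQuarterVGG:
    """The segmentation network: quarter-VGG16 encoder + FCN-8s decoder."""

    def __init__(self, spec: Optional[SegmentationModelSpec] = None, seed: int = 0):
        self.spec = spec if spec is not None else SegmentationModelSpec()
        rng = np.random.default_rng(seed)
        w, h = self.spec.input_size
        nc = self.spec.num_classes

        self.blocks: List[List] = []
        in_ch = 1
        for chans in self.spec.encoder_channels:
            layers = []
            for out_ch in chans:
                layers.append(Conv2d(in_ch, out_ch, 3, rng))
                layers.append(LeakyReLU())
                in_ch = out_ch
            layers.append(MaxPool2())
            self.blocks.append(layers)

        hc = self.spec.head_channels
        ch3 = self.spec.encoder_channels[2][-1]
        ch4 = self.spec.encoder_channels[3][-1]
        ch5 = self.spec.encoder_channels[4][-1]
        self.fc6 = Conv2d(ch5, hc, 3, rng)
        self.relu6 = LeakyReLU()
        self.fc7 = Conv2d(hc, hc, 1, rng)
        self.relu7 = LeakyReLU()
        self.score_fr = Conv2d(hc, nc, 1, rng, zero_init=True)
        self.score_pool4 = Conv2d(ch4, nc, 1, rng, zero_init=True)
        self.score_pool3 = Conv2d(ch3, nc, 1, rng, zero_init=True)

        self.up_to_16 = BilinearResize((h // 16, w // 16))
        self.up_to_8 = BilinearResize((h // 8, w // 8))
        self.up_to_full = BilinearResize((h, w))

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (N, num_classes, H, W) for a centred input batch."""
        h = x.astype(np.float32)
        taps = {}
        for bi, layers in enumerate(self.blocks):
            for layer in layers:
                h = layer.forward(h)
            taps[bi] = h
        f6 = self.relu6.forward(self.fc6.forward(taps[4]))
        f7 = self.relu7.forward(self.fc7.forward(f6))
        score = self.score_fr.forward(f7)

        s4 = self.score_pool4.forward(taps[3])
        s3 = self.score_pool3.forward(taps[2])
        u16 = self.up_to_16.forward(score) + s4
        u8 = self.up_to_8.forward(u16) + s3
        return self.up_to_full.forward(u8)

    def backward(self, grad_logits: np.ndarray) -> None:
        g8 = self.up_to_full.backward(grad_logits)
        g_s3 = g8
        g16 = self.up_to_8.backward(g8)
        g_s4 = g16
        g_score = self.up_to_16.backward(g16)

        g = self.score_fr.backward(g_score)
        g = self.fc7.backward(self.relu7.backward(g))
        g = self.fc6.backward(self.relu6.backward(g))

        skip = {3: self.score_pool4.backward(g_s4), 2: self.score_pool3.backward(g_s3)}
        for bi in range(4, -1, -1):
            if bi in skip:
                g = g + skip[bi]
            for layer in reversed(self.blocks[bi]):
                g = layer.backward(g)

    def parameters(self):
        params = []
        for layers in self.blocks:
            for layer in layers:
                params.extend(layer.parameters())
        for layer in (self.fc6, self.fc7, self.score_fr, self.score_pool4, self.score_pool3):
            params.extend(layer.parameters())
        return params

    # ------------------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Bladder-class probability map for a centred input batch."""
        return softmax(self.forward(x))[:, 1]

    def state_dict(self) -> dict:
        return {f"param_{i}": p for i, (p, _) in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        for i, (p, _) in enumerate(self.parameters()):
            p[...] = state[f"param_{i}"]


def prepare_input(image: np.ndarray, input_size: Tuple[int, int]) -> np.ndarray:
    """Resize a [0, 1] grayscale image to the network size and centre it."""
    w, h = input_size
    resized = _sk_resize(image.astype(np.float64), (h, w), order=1, anti_aliasing=True)
    return (resized - 0.5).astype(np.float32)


def predict_mask(
    model: FCNQuarterVGG, frame: UltrasoundFrame, threshold: float = 0.5
) -> np.ndarray:
    """Segment a frame with a trained network.

    The frame is resized to the network input size, the probability map
    is thresholded at ``threshold`` and resized back to the original
    frame resolution.  An empty mask is a legal output (downstream
    measurement raises "no bladder detected").
    """
    rows, cols = frame.shape
    if rows < 16 or cols < 16:
        raise ValueError("frame too small to segment")
    x = prepare_input(frame.image, model.spec.input_size)[None, None]
    prob = model.predict_proba(x)[0]
    prob_full = _sk_resize(prob.astype(np.float64), (rows, cols), order=1)
    return prob_full >= threshold
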
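"""Deterministic classical bladder segmentation.

Urine is anechoic, so the bladder lumen is the darkest coherent region
of the frame.  The baseline smooths the image, splits dark from bright
tissue with Otsu's threshold, tidies the dark class morphologically and
keeps the largest dark component.  Fully deterministic, and equivariant
under horizontal flips (all structuring elements are symmetric).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from ..frames import NoBladderDetected, UltrasoundFrame

#: minimum dark-component area (px) below which "no bladder" is reported
MIN_AREA_PX = 100
#: minimum intensity spread for the frame to contain any structure
MIN_DYNAMIC_RANGE = 0.05


def classical_segment(
    frame: UltrasoundFrame,
    smooth_sigma: float = 2.0,
    min_area_px: int = MIN_AREA_PX,
) -> np.ndarray:
    """Segment the bladder lumen as the largest dark component.

    Raises :class:`NoBladderDetected` when the frame is (near-)uniform
    or no dark component reaches ``min_area_px``.
    """
    img = np.asarray(frame.image, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(img, smooth_sigma)
    if float(smoothed.max() - smoothed.min()) < MIN_DYNAMIC_RANGE:
        raise NoBladderDetected("no bladder detected: uniform frame")

    dark = smoothed < threshold_otsu(smoothed)
    dark = closing(dark, disk(3))
    dark = ndimage.binary_fill_holes(dark)

    labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise NoBladderDetected("no bladder detected: no dark component")
    sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_area_px:
        raise NoBladderDetected("no bladder detected: dark component too small")
    return labels == largest
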
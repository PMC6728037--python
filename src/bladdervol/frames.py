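"""Core in-memory containers shared across the pipeline.

An :class:`UltrasoundFrame` couples a grayscale image with the physical
pixel spacing and the anatomical section it depicts; masks are plain
boolean arrays aligned pixel-for-pixel to their frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

TRANSVERSE = "transverse"
LONGITUDINAL = "longitudinal"
SECTIONS = (TRANSVERSE, LONGITUDINAL)


class NoBladderDetected(RuntimeError):
    """Raised when a frame contains no measurable bladder region."""


def as_spacing(spacing) -> Tuple[float, float]:
    """Normalise a pixel spacing argument to (row_mm, col_mm).

    Accepts a scalar (isotropic) or a (row, col) pair, in mm per pixel.
    """
    arr = np.atleast_1d(np.asarray(spacing, dtype=float))
    if arr.size == 1:
        sr = sc = float(arr[0])
    elif arr.size == 2:
        sr, sc = float(arr[0]), float(arr[1])
    else:
        raise ValueError("spacing must be a scalar or a (row, col) pair")
    if sr <= 0 or sc <= 0:
        raise ValueError("pixel spacing must be positive (mm/px)")
    return sr, sc


@dataclass
class UltrasoundFrame:
    """A single 2D grayscale ultrasound frame.

    Parameters
    ----------
    image:
        2D float array with intensities in [0, 1], shape (rows, cols).
    section:
        ``"transverse"`` or ``"longitudinal"``.
    spacing:
        Physical pixel spacing in mm per pixel, ``(row_mm, col_mm)``.
    """

    image: np.ndarray
    section: str
    spacing: Tuple[float, float]

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError("frame image must be 2D grayscale")
        if self.section not in SECTIONS:
            raise ValueError(f"section must be one of {SECTIONS}")
        self.spacing = as_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.image.shape


@dataclass(frozen=True)
class Chord:
    """A measured caliper line between two bladder-contour pixels.

    Endpoints are 0-based (row, col) pixel centres; ``angle_deg`` is the
    orientation against the image horizontal (width) axis in [0, 180).
    """

    p0: Tuple[int, int]
    p1: Tuple[int, int]
    length_mm: float
    angle_deg: float

    @property
    def length_cm(self) -> float:
        return self.length_mm / 10.0


@dataclass(frozen=True)
class DiameterTriple:
    """The three axial bladder diameters, in cm.

    ``a`` is the transverse width; ``b`` the maximal diameter of the
    longitudinal section; ``c`` the longitudinal diameter orthogonal to
    ``b`` (so ``b >= c`` by construction).
    """

    a_cm: float
    b_cm: float
    c_cm: float
    source_chords: tuple = field(default=(), compare=False)

    def __post_init__(self):
        if not (self.a_cm > 0 and self.b_cm > 0 and self.c_cm > 0):
            raise ValueError("diameters must be positive")
        if self.b_cm < self.c_cm - 1e-9:
            raise ValueError("b must be the maximal longitudinal diameter (b >= c)")
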
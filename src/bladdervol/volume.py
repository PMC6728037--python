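"""Ellipsoid volume estimation and clinical threshold classification.

The bladder is treated as a prolate ellipsoid: with the three orthogonal
diameters a, b, c in cm, the urine volume in ml is

    V = (pi / 6) * a * b * c

since 1 cm^3 = 1 ml.  pi/6 (~0.524) is the exact ellipsoid constant and
the standard clinical choice; alternative correction coefficients used
by some devices can be supplied explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .frames import DiameterTriple

ELLIPSOID_COEFFICIENT = math.pi / 6.0

ABOVE = "above"
BELOW = "below"


@dataclass(frozen=True)
class VolumeEstimate:
    """An estimated bladder volume with its provenance."""

    volume_ml: float
    diameters: DiameterTriple
    coefficient: float = ELLIPSOID_COEFFICIENT
    backend: Optional[str] = None
    mode: Optional[str] = None


def ellipsoid_volume(
    diameters: DiameterTriple,
    coefficient: float = ELLIPSOID_COEFFICIENT,
    backend: Optional[str] = None,
    mode: Optional[str] = None,
) -> VolumeEstimate:
    """Volume (ml) of the ellipsoid with the given diameters (cm)."""
    d = diameters
    volume = coefficient * d.a_cm * d.b_cm * d.c_cm
    return VolumeEstimate(
        volume_ml=volume, diameters=d, coefficient=coefficient, backend=backend, mode=mode
    )


def classify(estimate: VolumeEstimate, threshold_ml: float) -> str:
    """Classify a volume against a clinical threshold.

    The boundary is inclusive: a volume exactly at the threshold counts
    as ``"above"`` (matching the ">= threshold" convention of clinical
    residual-volume tables).
    """
    if threshold_ml <= 0:
        raise ValueError("threshold must be positive")
    return ABOVE if estimate.volume_ml >= threshold_ml else BELOW


def estimate_pair(
    transverse_frame,
    longitudinal_frame,
    backend: str = "classical",
    mode: str = "chord",
    segmenter=None,
    coefficient: float = ELLIPSOID_COEFFICIENT,
    horizontal_tolerance_deg: float | None = None,
    orthogonal_tolerance_deg: float | None = None,
) -> VolumeEstimate:
    """Run the full pipeline on one transverse/longitudinal frame pair.

    Segments each frame (``backend`` ``"classical"`` or a trained-network
    callable passed via ``segmenter``), cleans the masks, measures the
    transverse width ``a`` and the longitudinal diameters ``b``/``c``
    (``mode`` ``"chord"`` for maximal chords, ``"ellipse"`` for a
    least-squares ellipse fit) and applies the ellipsoid formula.

    A frame in which no bladder can be found raises
    :class:`~bladdervol.frames.NoBladderDetected`, tagged with the
    offending section.
    """
    from . import geometry
    from .frames import LONGITUDINAL, NoBladderDetected, TRANSVERSE, DiameterTriple
    from .segmentation.classical import classical_segment

    if segmenter is None:
        if backend != "classical":
            raise ValueError("pass segmenter= for non-classical backends")
        segmenter = classical_segment

    masks = {}
    for frame in (transverse_frame, longitudinal_frame):
        try:
            masks[frame.section] = geometry.postprocess_mask(segmenter(frame))
        except NoBladderDetected as exc:
            raise NoBladderDetected(f"{exc} [{frame.section} frame]") from exc

    t_mask, l_mask = masks[TRANSVERSE], masks[LONGITUDINAL]
    try:
        if mode == "chord":
            kwargs_a = {}
            if horizontal_tolerance_deg is not None:
                kwargs_a["horizontal_tolerance_deg"] = horizontal_tolerance_deg
            kwargs_c = {}
            if orthogonal_tolerance_deg is not None:
                kwargs_c["orthogonal_tolerance_deg"] = orthogonal_tolerance_deg
            a_cm, a_chord = geometry.measure_transverse(
                t_mask, transverse_frame.spacing, **kwargs_a
            )
            b_cm, c_cm, (b_chord, c_chord) = geometry.measure_longitudinal(
                l_mask, longitudinal_frame.spacing, **kwargs_c
            )
            chords = tuple(ch for ch in (a_chord, b_chord, c_chord) if ch is not None)
        elif mode == "ellipse":
            a_cm, _, _ = _transverse_from_ellipse(t_mask, transverse_frame.spacing)
            b_cm, c_cm, _ = geometry.fit_ellipse(l_mask, longitudinal_frame.spacing)
            chords = ()
        else:
            raise ValueError(f"unknown measurement mode {mode!r}")
    except NoBladderDetected as exc:
        raise NoBladderDetected(str(exc)) from exc

    diam = DiameterTriple(a_cm=a_cm, b_cm=b_cm, c_cm=min(c_cm, b_cm), source_chords=chords)
    return ellipsoid_volume(diam, coefficient=coefficient, backend=backend, mode=mode)


def _transverse_from_ellipse(mask, spacing):
    """Transverse width from an ellipse fit: the horizontal extent.

    The fitted ellipse's axis closest to horizontal plays the role of
    the width diameter.
    """
    from . import geometry

    major_cm, minor_cm, angle = geometry.fit_ellipse(mask, spacing)
    dev = min(angle, 180.0 - angle)
    a = major_cm if dev <= 45.0 else minor_cm
    return a, (major_cm, minor_cm), angle

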
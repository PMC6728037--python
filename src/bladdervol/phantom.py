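"""Synthetic ultrasound-like bladder phantoms with exact ground truth.

The bladder is modelled as a triaxial ellipsoid with semi-axes along the
anatomical transverse, anteroposterior (AP) and superoinferior (SI)
directions, filled with anechoic (dark) urine and embedded in brighter
speckle-textured tissue.  Two orthogonal planes through the ellipsoid
centre are imaged:

* the transverse section samples the (transverse, AP) plane — image
  columns run along the transverse axis, rows along AP;
* the longitudinal section samples the (SI, AP) plane — columns along
  SI, rows along AP.

Each section therefore shows an ellipse whose half-axes are the two
in-plane ellipsoid semi-axes, optionally rotated in plane and offset
from the image centre.  Speckle is multiplicative unit-mean gamma noise
followed by a Gaussian blur; the noise affects intensities only, never
the ground-truth mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .frames import LONGITUDINAL, TRANSVERSE, DiameterTriple, UltrasoundFrame, as_spacing
from .volume import ELLIPSOID_COEFFICIENT, ellipsoid_volume


class DegeneratePhantomError(ValueError):
    """The requested ellipse does not intersect the image at all."""


@dataclass
class PhantomSpec:
    """Full description of one synthetic phantom.

    Parameters
    ----------
    semi_axes:
        Ellipsoid semi-axes in cm, ordered (transverse, anteroposterior,
        superoinferior).
    center_offset:
        Per-section in-plane offset of the ellipse centre from the image
        centre, in cm, as ``{"transverse": (dx, dy), "longitudinal": ...}``
        where dx runs along columns and dy along rows.
    rotation_deg:
        Per-section in-plane rotation of the ellipse, degrees.
    pixel_spacing:
        mm per pixel, isotropic or (row, col), shared by both sections.
    image_size:
        (width, height) in pixels.
    interior_level, tissue_level:
        Mean gray levels of the anechoic lumen and of surrounding tissue,
        on [0, 1]; the lumen must be darker than the tissue.
    speckle_scale:
        Standard deviation of the unit-mean multiplicative speckle; 0
        disables noise.
    blur_sigma:
        Gaussian point-spread blur in pixels.
    truncation_fraction:
        Largest fraction of the ellipse area allowed to protrude beyond
        the field of view, in [0, 0.5).
    seed:
        Seed for the intensity noise (the mask is seed-independent).
    """

    semi_axes: Tuple[float, float, float] = (2.5, 2.0, 3.0)
    center_offset: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {TRANSVERSE: (0.0, 0.0), LONGITUDINAL: (0.0, 0.0)}
    )
    rotation_deg: Dict[str, float] = field(
        default_factory=lambda: {TRANSVERSE: 0.0, LONGITUDINAL: 0.0}
    )
    pixel_spacing: Tuple[float, float] = (0.35, 0.35)
    image_size: Tuple[int, int] = (512, 384)
    interior_level: float = 0.08
    tissue_level: float = 0.55
    speckle_scale: float = 0.35
    blur_sigma: float = 1.0
    truncation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if not self.interior_level < self.tissue_level:
            raise ValueError("bladder lumen must be darker than tissue")
        if not (0.0 <= self.truncation_fraction < 0.5):
            raise ValueError("truncation_fraction must lie in [0, 0.5)")
        self.pixel_spacing = as_spacing(self.pixel_spacing)

    def section_semi_axes(self, section: str) -> Tuple[float, float]:
        """In-plane (column-axis, row-axis) semi-axes for a section, cm."""
        ax_t, ax_ap, ax_si = self.semi_axes
        if section == TRANSVERSE:
            return ax_t, ax_ap
        if section == LONGITUDINAL:
            return ax_si, ax_ap
        raise ValueError(f"unknown section {section!r}")


@dataclass
class PhantomPair:
    """One phantom imaged in both sections, with its analytic truth."""

    spec: PhantomSpec
    transverse_frame: UltrasoundFrame
    longitudinal_frame: UltrasoundFrame
    transverse_mask: np.ndarray
    longitudinal_mask: np.ndarray
    true_diameters: DiameterTriple
    true_volume_ml: float
    truncated: bool


def _pixel_grid_cm(spec: PhantomSpec):
    width, height = spec.image_size
    sr, sc = spec.pixel_spacing
    # pixel-centre coordinates, cm, origin at the image centre
    x = (np.arange(width) - (width - 1) / 2.0) * sc / 10.0
    y = (np.arange(height) - (height - 1) / 2.0) * sr / 10.0
    return np.meshgrid(x, y)


def render_section(spec: PhantomSpec, section: str) -> Tuple[UltrasoundFrame, np.ndarray]:
    """Render one cross-section of the phantom.

    Returns the speckled/blurred frame and the exact ground-truth mask
    (the rasterized ellipse clipped to the field of view).  The image is
    deterministic given ``spec.seed``; the mask does not depend on the
    seed at all.
    """
    rx, ry = spec.section_semi_axes(section)
    cx, cy = spec.center_offset.get(section, (0.0, 0.0))
    theta = math.radians(spec.rotation_deg.get(section, 0.0))

    xx, yy = _pixel_grid_cm(spec)
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    if not mask.any():
        raise DegeneratePhantomError("degenerate phantom: ellipse entirely outside image")

    img = np.where(mask, spec.interior_level, spec.tissue_level).astype(np.float64)
    if spec.speckle_scale > 0:
        # unit-mean gamma speckle: shape k = 1/scale^2 gives sd = speckle_scale
        k = 1.0 / spec.speckle_scale**2
        stream = 0 if section == TRANSVERSE else 1
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))
        img *= rng.gamma(shape=k, scale=1.0 / k, size=img.shape)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    img = np.clip(img, 0.0, 1.0)

    frame = UltrasoundFrame(image=img, section=section, spacing=spec.pixel_spacing)
    return frame, mask


def _truncated_fraction(spec: PhantomSpec, section: str, mask: np.ndarray) -> float:
    """Fraction of the analytic ellipse area lying outside the frame."""
    rx, ry = spec.section_semi_axes(section)
    sr, sc = spec.pixel_spacing
    pixel_area_cm2 = (sr / 10.0) * (sc / 10.0)
    analytic = math.pi * rx * ry
    inside = mask.sum() * pixel_area_cm2
    return max(0.0, 1.0 - inside / analytic)


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render both sections and assemble ground truth.

    ``true_volume_ml`` is computed by the ellipsoid formula from the true
    diameters (2x the semi-axes), so the pair is exactly self-consistent.
    """
    t_frame, t_mask = render_section(spec, TRANSVERSE)
    l_frame, l_mask = render_section(spec, LONGITUDINAL)

    ax_t, ax_ap, ax_si = spec.semi_axes
    a = 2.0 * ax_t
    b = 2.0 * max(ax_ap, ax_si)
    c = 2.0 * min(ax_ap, ax_si)
    diam = DiameterTriple(a_cm=a, b_cm=b, c_cm=c)
    vol = ellipsoid_volume(diam).volume_ml

    trunc = max(
        _truncated_fraction(spec, TRANSVERSE, t_mask),
        _truncated_fraction(spec, LONGITUDINAL, l_mask),
    )
    return PhantomPair(
        spec=spec,
        transverse_frame=t_frame,
        longitudinal_frame=l_frame,
        transverse_mask=t_mask,
        longitudinal_mask=l_mask,
        true_diameters=diam,
        true_volume_ml=vol,
        truncated=trunc > 0.005,
    )


#: Default sampling ranges for random phantom datasets.  Semi-axes and
#: the volume ceiling emulate a study population voiding < 150 ml; the
#: jitter and rotation ranges keep the bladder fully in view at the
#: default spacing and frame size.
DEFAULT_RANGES: Dict[str, tuple] = {
    "semi_axis_cm": (1.0, 3.3),
    "rotation_deg": (-20.0, 20.0),
    "center_jitter_cm": (-0.8, 0.8),
    "max_volume_ml": (150.0,),
}


def _sample_spec(rng: np.random.Generator, ranges: Dict[str, tuple], base: PhantomSpec) -> PhantomSpec:
    lo, hi = ranges["semi_axis_cm"]
    max_vol = ranges["max_volume_ml"][0]
    for _ in range(1000):
        axes = tuple(rng.uniform(lo, hi, size=3))
        vol = ELLIPSOID_COEFFICIENT * 8.0 * axes[0] * axes[1] * axes[2]
        if vol < max_vol:
            break
    else:  # pragma: no cover - ranges would have to be inconsistent
        raise ValueError("could not sample a spec under the volume ceiling")
    rlo, rhi = ranges["rotation_deg"]
    jlo, jhi = ranges["center_jitter_cm"]
    return replace(
        base,
        semi_axes=axes,
        rotation_deg={
            TRANSVERSE: float(rng.uniform(rlo, rhi)),
            LONGITUDINAL: float(rng.uniform(rlo, rhi)),
        },
        center_offset={
            TRANSVERSE: tuple(rng.uniform(jlo, jhi, size=2)),
            LONGITUDINAL: tuple(rng.uniform(jlo, jhi, size=2)),
        },
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n: int,
    ranges: Optional[Dict[str, tuple]] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
) -> Tuple[List[PhantomPair], pd.DataFrame]:
    """Sample ``n`` random phantoms and a manifest describing them.

    The manifest records every spec field plus the true diameters (cm)
    and true volume (ml); (ranges, seed) fully determine the output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    use_ranges = dict(DEFAULT_RANGES)
    if ranges:
        use_ranges.update(ranges)
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)

    pairs: List[PhantomPair] = []
    rows = []
    for i in range(n):
        spec = _sample_spec(rng, use_ranges, base)
        pair = generate_phantom(spec)
        pairs.append(pair)
        d = pair.true_diameters
        rows.append(
            {
                "id": i,
                "semi_axis_t_cm": spec.semi_axes[0],
                "semi_axis_ap_cm": spec.semi_axes[1],
                "semi_axis_si_cm": spec.semi_axes[2],
                "rotation_t_deg": spec.rotation_deg[TRANSVERSE],
                "rotation_l_deg": spec.rotation_deg[LONGITUDINAL],
                "offset_t_x_cm": spec.center_offset[TRANSVERSE][0],
                "offset_t_y_cm": spec.center_offset[TRANSVERSE][1],
                "offset_l_x_cm": spec.center_offset[LONGITUDINAL][0],
                "offset_l_y_cm": spec.center_offset[LONGITUDINAL][1],
                "spacing_row_mm": spec.pixel_spacing[0],
                "spacing_col_mm": spec.pixel_spacing[1],
                "width_px": spec.image_size[0],
                "height_px": spec.image_size[1],
                "speckle_scale": spec.speckle_scale,
                "blur_sigma": spec.blur_sigma,
                "seed": spec.seed,
                "a_cm": d.a_cm,
                "b_cm": d.b_cm,
                "c_cm": d.c_cm,
                "true_volume_ml": pair.true_volume_ml,
                "truncated": pair.truncated,
            }
        )
    manifest = pd.DataFrame(rows)
    return pairs, manifest
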
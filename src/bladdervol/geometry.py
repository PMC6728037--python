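"""Diameter measurement on binary bladder masks.

The three axial diameters are taken as maximal chords between bladder
contour pixels, mirroring the caliper placements of clinical practice:

* ``a`` (transverse section): longest chord whose orientation lies
  within a small tolerance of the image horizontal axis;
* ``b`` (longitudinal section): longest chord, unconstrained;
* ``c`` (longitudinal section): longest chord orthogonal to ``b``.

The contour is the set of 8-connected boundary pixels of the cleaned
mask; chord endpoints are pixel centres in 0-based (row, col)
coordinates with the origin at the top-left, and the "horizontal axis"
is the image width axis.  The chord search is an exact maximisation
over all contour point pairs with deterministic tie-breaking (largest
length, then smallest orientation angle in [0, 180), then
lexicographically smallest endpoints), so results are bit-reproducible.

An ellipse-fitting measurement mode is provided as an alternative: a
least-squares ellipse through the contour whose axis lengths replace
the chord lengths.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel

from .frames import Chord, NoBladderDetected, as_spacing

#: default tolerance (deg) around horizontal for the transverse chord a
HORIZONTAL_TOLERANCE_DEG = 10.0
#: tolerance (deg) around perpendicular-to-b for chord c, and widened fallback
ORTHOGONAL_TOLERANCE_DEG = 2.0
ORTHOGONAL_TOLERANCE_WIDE_DEG = 5.0

_STRUCT8 = np.ones((3, 3), dtype=bool)


def postprocess_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest connected component and fill interior holes.

    Empty masks pass through unchanged; the operation is idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    else:
        mask = labels == 1
    return ndimage.binary_fill_holes(mask)


def contour_points(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a mask (pixels with any 8-neighbour outside).

    Returns an (n, 2) int array of (row, col), sorted lexicographically.
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    boundary = mask & ~eroded
    pts = np.argwhere(boundary)
    return pts  # np.argwhere is already in lexicographic (row, col) order


def _angle_deg(dr: np.ndarray, dc: np.ndarray) -> np.ndarray:
    """Orientation of segments vs the horizontal axis, mapped to [0, 180)."""
    ang = np.degrees(np.arctan2(dr, dc))
    ang = np.mod(ang, 180.0)
    ang[np.isclose(ang, 180.0)] = 0.0
    return ang


def _angular_distance(angle: np.ndarray, center: float) -> np.ndarray:
    """Distance between undirected orientations, on the 180-deg circle."""
    d = np.mod(angle - center, 180.0)
    return np.minimum(d, 180.0 - d)


def longest_chord(
    mask: np.ndarray,
    spacing,
    angle_constraint: Optional[Tuple[float, float]] = None,
) -> Chord:
    """Longest chord between contour pixels, optionally angle-constrained.

    Parameters
    ----------
    mask:
        Binary mask (assumed already postprocessed).
    spacing:
        Pixel spacing in mm/px, scalar or (row, col).
    angle_constraint:
        Optional ``(center_deg, tolerance_deg)``: only pairs whose
        orientation lies within ``tolerance_deg`` of ``center_deg`` (on
        the 180-degree orientation circle) are considered.

    Raises
    ------
    NoBladderDetected
        If the mask is empty.
    ValueError
        If the constraint admits no contour pair.
    """
    sr, sc = as_spacing(spacing)
    pts = contour_points(mask)
    if len(pts) == 0:
        raise NoBladderDetected("no bladder detected: empty mask")

    if len(pts) < 2:
        raise ValueError("mask has fewer than 2 contour points")

    rows = pts[:, 0].astype(np.float64)
    cols = pts[:, 1].astype(np.float64)

    best = None  # (length_mm, angle, i, j)
    n = len(pts)
    chunk = max(1, int(4e6) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # pairs (i, j) with i < j; endpoints ordered so p0 is lexicographically first
        i_idx = np.arange(start, stop)
        dy = (rows[None, :] - rows[i_idx, None]) * sr
        dx = (cols[None, :] - cols[i_idx, None]) * sc
        jj, ii = np.meshgrid(np.arange(n), i_idx)
        upper = jj > ii
        if not upper.any():
            continue
        dy, dx = dy[upper], dx[upper]
        ii, jj = ii[upper], jj[upper]
        length = np.hypot(dx, dy)
        angle = _angle_deg(dy, dx)
        if angle_constraint is not None:
            center, tol = angle_constraint
            ok = _angular_distance(angle, center) <= tol
            if not ok.any():
                continue
            length, angle, ii, jj = length[ok], angle[ok], ii[ok], jj[ok]
        cand = _select_best(length, angle, ii, jj, pts)
        if best is None or _chord_key(cand, pts) < _chord_key(best, pts):
            best = cand

    if best is None:
        raise ValueError("angle constraint admits no contour pair")
    length_mm, angle, i, j = best
    return Chord(
        p0=tuple(int(v) for v in pts[i]),
        p1=tuple(int(v) for v in pts[j]),
        length_mm=float(length_mm),
        angle_deg=float(angle),
    )


def _select_best(length, angle, ii, jj, pts):
    m = length == length.max()
    length, angle, ii, jj = length[m], angle[m], ii[m], jj[m]
    m = angle == angle.min()
    length, angle, ii, jj = length[m], angle[m], ii[m], jj[m]
    # contour points are lexicographically sorted, so smallest index wins
    order = np.lexsort((jj, ii))
    k = order[0]
    return (float(length[k]), float(angle[k]), int(ii[k]), int(jj[k]))


def _chord_key(cand, pts):
    length, angle, i, j = cand
    return (-length, angle, tuple(pts[i]), tuple(pts[j]))


def measure_transverse(
    mask: np.ndarray,
    spacing,
    horizontal_tolerance_deg: float = HORIZONTAL_TOLERANCE_DEG,
) -> Tuple[float, Chord]:
    """Transverse width ``a`` (cm): longest near-horizontal chord."""
    chord = longest_chord(mask, spacing, angle_constraint=(0.0, horizontal_tolerance_deg))
    return chord.length_cm, chord


def _perpendicular_extent_mm(mask: np.ndarray, spacing, angle_deg: float) -> float:
    """Feret extent of the contour along the direction ``angle_deg``.

    Used as the fallback width when no contour pair is orthogonal to b
    within tolerance (degenerate, near-1D shapes): the projection span
    of the contour plus one pixel footprint along that direction.
    """
    sr, sc = as_spacing(spacing)
    pts = contour_points(mask).astype(np.float64)
    ur = math.sin(math.radians(angle_deg))
    uc = math.cos(math.radians(angle_deg))
    proj = pts[:, 0] * sr * ur + pts[:, 1] * sc * uc
    footprint = abs(ur) * sr + abs(uc) * sc
    return float(proj.max() - proj.min() + footprint)


def measure_longitudinal(
    mask: np.ndarray,
    spacing,
    orthogonal_tolerance_deg: float = ORTHOGONAL_TOLERANCE_DEG,
) -> Tuple[float, float, Tuple[Chord, Optional[Chord]]]:
    """Longitudinal diameters ``b`` and ``c`` (cm).

    ``b`` is the unconstrained longest chord; ``c`` the longest chord
    orthogonal to ``b`` (tolerance widened automatically from the
    default to +/-5 degrees when the rasterized contour has no pair close
    enough to perpendicular, then falling back to the perpendicular
    Feret extent).  Guarantees ``b >= c``.
    """
    b_chord = longest_chord(mask, spacing)
    perp = (b_chord.angle_deg + 90.0) % 180.0

    c_chord: Optional[Chord] = None
    for tol in (orthogonal_tolerance_deg, ORTHOGONAL_TOLERANCE_WIDE_DEG):
        try:
            c_chord = longest_chord(mask, spacing, angle_constraint=(perp, tol))
            break
        except ValueError:
            continue
    if c_chord is not None:
        c_mm = c_chord.length_mm
    else:
        c_mm = _perpendicular_extent_mm(mask, spacing, perp)
    c_mm = min(c_mm, b_chord.length_mm)
    return b_chord.length_cm, c_mm / 10.0, (b_chord, c_chord)


def fit_ellipse(mask: np.ndarray, spacing) -> Tuple[float, float, float]:
    """Least-squares ellipse through the mask contour.

    Returns ``(major_diameter_cm, minor_diameter_cm, angle_deg)`` where
    the angle is the major-axis orientation vs the horizontal in
    [0, 180).  The fit is done in physical (mm) coordinates so that
    anisotropic pixel spacing is handled correctly.
    """
    sr, sc = as_spacing(spacing)
    pts = contour_points(mask)
    if len(pts) < 5:
        raise ValueError("ellipse fit needs at least 5 contour points")
    xy = np.column_stack([pts[:, 1] * sc, pts[:, 0] * sr])  # (x, y) in mm
    if np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        raise ValueError("degenerate contour: points are collinear")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(xy.astype(np.float64))
        if not model:
            raise ValueError("ellipse fit failed")
        a_mm, b_mm = model.axis_lengths
        theta = model.theta
    else:  # older scikit-image
        model = EllipseModel()
        if not model.estimate(xy.astype(np.float64)):
            raise ValueError("ellipse fit failed")
        _, _, a_mm, b_mm, theta = model.params
    major_mm, minor_mm = (2 * a_mm, 2 * b_mm) if a_mm >= b_mm else (2 * b_mm, 2 * a_mm)
    angle = math.degrees(theta) % 180.0
    if a_mm < b_mm:
        angle = (angle + 90.0) % 180.0
    return major_mm / 10.0, minor_mm / 10.0, angle
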
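"""Independent brute-force oracles used to check the geometry module.

The chord oracle enumerates every contour point pair in an explicit
loop and applies the same constraint and tie-break conventions as the
library (largest length, then smallest orientation angle in [0, 180),
then lexicographically smallest endpoint pair), so agreement must be
exact, not approximate.
"""

from __future__ import annotations

import numpy as np


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one 8-neighbour outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    pts = []
    for r, c in np.argwhere(mask):
        window = padded[r : r + 3, c : c + 3]
        if not window.all():
            pts.append((r, c))
    return np.array(sorted(pts), dtype=int).reshape(-1, 2)


def brute_force_longest_chord(mask, spacing, angle_constraint=None):
    """All-pairs maximal chord; returns (p0, p1, length_mm, angle_deg)."""
    sr, sc = (float(spacing), float(spacing)) if np.isscalar(spacing) else map(float, spacing)
    pts = boundary_points(mask)
    n = len(pts)
    best = None
    best_key = None
    for i in range(n):
        for j in range(i + 1, n):
            dy = (pts[j, 0] - pts[i, 0]) * sr
            dx = (pts[j, 1] - pts[i, 1]) * sc
            length = float(np.hypot(dx, dy))
            angle = float(np.mod(np.degrees(np.arctan2(dy, dx)), 180.0))
            if np.isclose(angle, 180.0):
                angle = 0.0
            if angle_constraint is not None:
                center, tol = angle_constraint
                d = np.mod(angle - center, 180.0)
                if min(d, 180.0 - d) > tol:
                    continue
            key = (-length, angle, tuple(pts[i]), tuple(pts[j]))
            if best_key is None or key < best_key:
                best_key = key
                best = (tuple(pts[i]), tuple(pts[j]), length, angle)
    return best
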
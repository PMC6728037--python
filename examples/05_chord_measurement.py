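"""Measure bladder diameters on a binary mask, chord vs ellipse mode.

The three diameters follow clinical caliper placement: a is the longest
near-horizontal chord of the transverse section; b the longest chord of
the longitudinal section; c the longest chord orthogonal to b.  An
alternative mode fits a least-squares ellipse to the contour and reads
off its axes — on clean, convex masks the two agree closely.
"""

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from bladdervol import fit_ellipse, measure_longitudinal, measure_transverse

mask = np.zeros((384, 512), dtype=bool)
rr, cc = draw_ellipse(192, 256, 80, 140, shape=mask.shape, rotation=np.deg2rad(15))
mask[rr, cc] = True
spacing = 0.35  # mm per pixel

a_cm, a_chord = measure_transverse(mask, spacing)
b_cm, c_cm, (b_chord, _) = measure_longitudinal(mask, spacing)
major_cm, minor_cm, angle = fit_ellipse(mask, spacing)

print(f"chord a (near-horizontal): {a_cm:.2f} cm  at {a_chord.angle_deg:.1f} deg")
print(f"chord b (maximal):         {b_cm:.2f} cm  at {b_chord.angle_deg:.1f} deg")
print(f"chord c (orthogonal to b): {c_cm:.2f} cm")
print(f"ellipse fit:               major {major_cm:.2f} cm, minor {minor_cm:.2f} cm, "
      f"axis at {angle:.1f} deg")
# chord b and the fitted major axis should agree within a few percent.
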
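"""Estimate bladder volume from one transverse/longitudinal frame pair.

The pipeline segments the dark lumen (classical backend here, so the
run is deterministic), measures the transverse width a and the
longitudinal maximal and orthogonal diameters b and c as maximal
chords, and applies V = pi/6 * a * b * c.  Volumes at or above a
threshold are classified "above" (the inclusive >= convention of
post-void residual tables).
"""

from bladdervol import PhantomSpec, classify, estimate_pair, generate_phantom

pair = generate_phantom(PhantomSpec(semi_axes=(3.0, 2.5, 4.0), seed=7))
est = estimate_pair(pair.transverse_frame, pair.longitudinal_frame)

d = est.diameters
print(f"measured diameters (cm): a={d.a_cm:.2f}  b={d.b_cm:.2f}  c={d.c_cm:.2f}")
print(f"estimated volume (ml):   {est.volume_ml:.1f}   (truth {pair.true_volume_ml:.1f})")
print(f"relative error:          "
      f"{abs(est.volume_ml - pair.true_volume_ml) / pair.true_volume_ml:.1%}")
for thr in (50.0, 100.0):
    print(f"classification at {thr:.0f} ml: {classify(est, thr)}")
# The caliper chords used for each diameter are in est.diameters.source_chords.
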
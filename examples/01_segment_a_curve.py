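"""Segment a synthetic ligament tensile curve into toe/linear/subfailure.

Generates one noise-free anterior-longitudinal-ligament (ALL) curve from
the built-in cohort statistics, extracts its characteristic points and
compares them with the construction values.
"""

from ligfit import characteristic_points
from ligfit.synthetic import LIGAMENTS, GeneratorConfig, specimen_curve

stats = LIGAMENTS["ALL"]
true_pts = stats.mean_points()
curve = specimen_curve(true_pts, GeneratorConfig(noise_sd_rel=0.0))

rec = characteristic_points(curve)
print(f"curve: {len(curve)} samples, stretch 1 .. {curve.lam[-1]:.2f}")
for label, true, got in [("I transition", true_pts.ptI, rec.ptI),
                         ("II transition", true_pts.ptII, rec.ptII),
                         ("failure", true_pts.fail, rec.fail)]:
    print(f"{label:14s} true (lam={true[0]:.3f}, P={true[1]:5.2f} MPa)"
          f"   recovered (lam={got[0]:.3f}, P={got[1]:5.2f} MPa)")
# The recovered transitions should sit within a few sample spacings of the
# construction points; the failure point (maximum stress) is exact.
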
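"""Critical-threshold propagation from fitted marker relationships.

The extraction/delivery relation of a perfused kidney is biphasic: flat
while delivery is adequate, steep below a critical delivery.  Starting from
the regression coefficients of that relation (here: the published porcine
NMP fits), the companion thresholds chain out of one another.
"""

from renalnmp.thresholds import (
    LineFit,
    Poly2Fit,
    TwoSegmentFit,
    propagate_critical,
)

# ERO2 ~ DO2, two segments (percent extraction vs mL/min/100 g delivery)
steep = LineFit(slope=-33.337, intercept=109.43, r_squared=1.0, x_range=(0, 2))
flat = LineFit(slope=0.2292, intercept=50.933, r_squared=1.0, x_range=(1, 9))
# RBF ~ DO2, linear; RBF ~ AP, quadratic
rbf_do2 = LineFit(slope=12.57, intercept=1.3984, r_squared=0.97, x_range=(0, 9))
rbf_ap = Poly2Fit(a=0.0093, b=-3.2127, c=297.6, r_squared=0.96,
                  x_range=(90, 200))

cp = propagate_critical(TwoSegmentFit(steep, flat, breakpoint=1.74),
                        rbf_do2, rbf_ap)

print(f"DO2_crit  = {cp.do2_crit}  mL/min/100 g   (raw {cp.raw.do2_crit:.4f})")
print(f"ERO2_crit = {cp.ero2_crit:.0f}   %              (raw {cp.raw.ero2_crit:.2f})")
print(f"RBF_crit  = {cp.rbf_crit:.0f}   mL/min/100 g   (raw {cp.raw.rbf_crit:.2f})")
print(f"VO2_crit  = {cp.vo2_crit}  mL/min/100 g   (raw {cp.raw.vo2_crit:.3f})")
print(f"AP_crit   = {cp.ap_crit:.0f}  mmHg           (raw {cp.raw.ap_crit:.1f})")

# Below DO2_crit the tissue can no longer raise extraction enough to meet
# demand; RBF_crit is the flow delivering exactly DO2_crit, VO2_crit the
# consumption at the elbow, and AP_crit the pressure at which autoregulation
# has collapsed flow to RBF_crit.
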
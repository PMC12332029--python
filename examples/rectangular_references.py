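"""Rectangular-pulse reference calculations.

Prints the on-resonance 90-degree calibrations 1/(4 nu1) for common
amplitudes, and the null-placed durations t90 = sqrt(15)/(4 nu) and
t180 = sqrt(3)/(2 nu) that put the first excitation null at +/- nu Hz —
the classic trick for independently controlling two bands (e.g. CO vs
Calpha) with hard pulses.
"""

import numpy as np

import pulseforge as pf

for khz in (25.0, 23.0, 20.2, 17.6, 9.76, 6.85):
    print(f"t90 at {khz:5.2f} kHz : {pf.rectangular_t90_us(khz):7.2f} us")

nu = 10e3  # place the excitation null 10 kHz from the carrier
t90, t180 = pf.null_durations_us(nu)
print(f"\nnull-placed t90  = {t90:.2f} us, t180 = {t180:.2f} us (null at +/-{nu/1e3:g} kHz)")

# Verify by simulation: transverse excitation at the null offsets vanishes.
for t_us, angle in ((t90, 90.0), (t180, 180.0)):
    t = t_us * 1e-6
    nu1 = angle / (360.0 * t)
    vecs = pf.rectangular_profile(nu1, t, [-nu, 0.0, nu])
    mxy = np.hypot(vecs[:, 0], vecs[:, 1])
    print(f"{angle:.0f} deg pulse: |Mxy| on-resonance {mxy[1]:.3f}, at nulls {mxy[[0, 2]].max():.2e}")
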
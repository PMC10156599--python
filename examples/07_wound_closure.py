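"""Wound-healing closure velocity from a two-straight-line fit.

The covered area grows slowly during a lag phase and then linearly at the
maximal closure velocity; the fit locates the breakpoint by exhaustive scan
and reports the second-segment slope.
"""

import numpy as np

from nucleoflow import dynamics

rng = np.random.default_rng(0)
t = np.linspace(0, 24, 49)                       # h
area = np.where(t < 6, 0.05 * t, 0.3 + 2.4 * (t - 6))   # 1e4 um^2
area = area + rng.normal(0, 0.15, len(t))

breakpoint_h, v_max = dynamics.wound_closure_velocity(t, area)
print(f"lag phase ends at   : {breakpoint_h:.1f} h (planted 6 h)")
print(f"max closure velocity: {v_max:.2f} x10^4 um^2/h (planted 2.4)")
# The second-segment slope is the maximal closure velocity after the lag.
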
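"""Organoid rotation analysis: angular velocity, classification, Q(τ).

Simulates a rotating organoid with internal Brownian rearrangements,
decomposes the nuclear motion into a rigid rotation plus residuals, and
computes the overlap parameter and its relaxation time — internal fluidity
measured independently of the global rotation.
"""

import numpy as np

import nucleoflow as nf
from nucleoflow import organoid

df, omega_true = nf.simulate_organoid(n_cells=80, radius=50.0,
                                      omega=(0.0, 0.0, 0.04),
                                      residual_D=3.0, dt=15.0, n_frames=40,
                                      seed=6)
clouds = organoid.clouds_from_table(df)
rm = organoid.rigid_motion_3d(clouds, dt=15.0)
d0 = organoid.default_overlap_cutoff(clouds[0])
q, tau_star = organoid.overlap_parameter(rm.residuals, d0, rm.dt)

print(f"planted angular speed : {np.linalg.norm(omega_true):.3f} cycles/h")
print(f"measured angular speed: {rm.mean_speed:.3f} cycles/h "
      f"-> {organoid.classify_rotation(rm.angular_speed)}")
print(f"overlap cutoff d0     : {d0:.1f} um "
      f"(half the mean nearest-neighbour distance)")
print(f"relaxation time tau*  : {tau_star:.2f} h")
print(f"Q at first/last lag   : {q['Q'].iloc[0]:.2f} / {q['Q'].iloc[-1]:.2f}")
# tau* halves when the internal diffusivity doubles: rotating organoids
# with fast internal dynamics have short relaxation times.
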
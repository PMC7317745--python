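"""Random walks with permeable membranes: sanity physics.

Free diffusion must obey the Einstein relation MSD = 6 D t; impermeable
membranes must trap walkers in their starting compartment; the membrane
transit probability p maps to a physical permeability k = p*sqrt(D/(6 dt)).
"""

import numpy as np

from dexsy import WalkParams, build_sphere_substrate, simulate
from dexsy.montecarlo import permeability_from_probability

params = WalkParams(n_walkers=5000, duration=0.1, n_steps=1000, seed=2)
ens = simulate(None, params, save_every=1000)  # no membranes
disp = ens.displacements()[:, -1, :]
msd = np.mean(np.sum(disp**2, axis=1))
print(f"free diffusion: MSD / (6 D t) = {msd/(6*2e-9*0.1):.4f} "
      "(should be ~1)")

sub = build_sphere_substrate(seed=2)
params = WalkParams(n_walkers=3000, duration=0.05, n_steps=2000,
                    transit_prob=0.0, seed=3)
ens = simulate(sub, params, save_every=100)
changes = int((ens.labels != ens.labels[:, :1]).sum())
print(f"impermeable spheres: {changes} compartment changes across "
      f"{ens.n_walkers} walkers (should be 0)")
print(f"intracellular walker fraction {np.mean(ens.labels[:,0] >= 0):.3f} "
      f"(packing fraction is {sub.packing_fraction})")

dt = 0.4 / 16000
for p in (0.0001, 0.00055):
    k = permeability_from_probability(p, dt, 2e-9)
    print(f"transit probability {p} <-> permeability {k*1e6:.2f} um/s")
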
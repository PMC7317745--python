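"""Build the two cell-mimicking substrates and inspect their geometry.

The cylinder lattice models a nerve bundle (gamma-distributed axon radii in
a periodic square cell); the sphere packing models a dense yeast suspension
(500 equal spheres at volume fraction 0.62).
"""

import numpy as np

from dexsy import build_cylinder_substrate, build_sphere_substrate
from dexsy.substrates import save_substrate

cyl = build_cylinder_substrate(seed=1)
print("cylinder substrate:")
print(f"  {cyl.n_cylinders} cylinders in a {cyl.lattice_size*1e6:.2f} um cell")
print(f"  mean radius {cyl.radii.mean()*1e6:.3f} um "
      f"(gamma mean = shape*scale = "
      f"{cyl.gamma_shape*cyl.gamma_scale*1e6:.3f} um)")
print(f"  intracellular area fraction {cyl.intracellular_fraction:.3f}")

sph = build_sphere_substrate(seed=1)
print("sphere substrate:")
print(f"  {sph.n_spheres} spheres of diameter {2*sph.radius*1e6:.1f} um "
      f"in a {sph.box_side*1e6:.2f} um box")
print(f"  packing fraction {sph.packing_fraction}")
gaps = []  # nearest-neighbour surface gap distribution
from scipy.spatial import cKDTree
tree = cKDTree(sph.centers % sph.box_side, boxsize=sph.box_side)
d, _ = tree.query(sph.centers % sph.box_side, k=2)
print(f"  min center distance / diameter = {d[:,1].min()/(2*sph.radius):.6f}"
      " (>= 1: no overlaps)")

save_substrate(sph, "yeast_substrate.txt")
print("wrote yeast_substrate.txt (text header + sphere centers)")
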
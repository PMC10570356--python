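"""Field-induced descriptors and their symmetry.

Builds a bent triatomic molecule in a uniform field, computes its FI-EAD
descriptor vectors, and shows the defining symmetry: rotating molecule and
field together changes nothing, rotating the field alone does.
"""

import numpy as np

from fieldpot import AtomicSystem, FeatureParams, compute_fiead, fiead_oracle
from fieldpot.synthetic import random_rotation, water_geometry

rng = np.random.default_rng(0)
feat = FeatureParams(r_c=3.0, L=2, n_rad=4, n_features=6, seed=1)

positions = water_geometry(0.96, 0.96, np.radians(104.5))
system = AtomicSystem(("O", "H", "H"), positions, field=[0.1, 0.0, 0.05])
coeffs = np.ones(3)

rho = compute_fiead(system, coeffs, 1.0, feat)
print("FI-EAD features, shape", rho.shape)
print(np.array_str(rho, precision=4))

oracle = fiead_oracle(system, coeffs, 1.0, feat)
print("\nmax |vectorized - brute-force expansion| =",
      f"{np.max(np.abs(rho - oracle)):.2e}",
      "(the two routes agree to numerical precision)")

R = random_rotation(rng)
joint = AtomicSystem(system.species, positions @ R.T, field=R @ system.field)
field_only = AtomicSystem(system.species, positions, field=R @ system.field)
print("\njoint rotation of molecule + field: max feature change =",
      f"{np.max(np.abs(compute_fiead(joint, coeffs, 1.0, feat) - rho)):.2e}")
print("rotation of the field alone:        max feature change =",
      f"{np.max(np.abs(compute_fiead(field_only, coeffs, 1.0, feat) - rho)):.2e}")
print("-> invariant under synchronous rotation, sensitive to the relative "
      "field direction, exactly as the field-system physics requires.")
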
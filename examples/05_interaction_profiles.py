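"""Distance-resolved hydrogen-bond, energy and orientation profiles.

A short classical NVT run of the hydroxyl-headed 4-site chain liquid
provides frames; the three analyses resolve, as a function of the
molecule–molecule center-of-mass distance (50 bins, 3.3–9 Å): hydrogen
bonds per volume, the mean pairwise nonbonded interaction energy, and the
mean cosine between the C–O bond vectors of each pair.
"""

import numpy as np

from nqeliq.interactions import (
    Frame,
    hbond_density_profile,
    interaction_energy_profile,
    orientation_profile,
)
from nqeliq.pimd import Integrator, IntegratorConfig, initialize_state
from nqeliq.forcefield import ForceField
from nqeliq.synthetic_data import ToyLiquidSpec, make_toy_liquid

top, pos, box = make_toy_liquid(
    ToyLiquidSpec(template="chain4", n_molecules=16, box=11.0), seed=5
)
ff = ForceField(top, cutoff=0.4 * box)
rng = np.random.default_rng(5)
state = initialize_state(top, pos, box, 1, 298.15, rng)
integ = Integrator(ff, state, IntegratorConfig(thermostat="langevin", T=298.15), rng)
frames = []
integ.run(2000)
for _ in range(20):
    integ.run(200)
    frames.append(Frame(state.positions[0].copy(), state.box))

hb = hbond_density_profile([frames], top)
en = interaction_energy_profile([frames], top)
ori = orientation_profile([frames], top, ("C", "O"))

print(f"{'r/A':>6} {'n_HB/V':>10} {'E_int kJ/mol':>13} {'<cos theta>':>12}")
for j in range(0, 50, 5):
    print(f"{hb.centers[j]:6.2f} {hb.values[j]:10.5f} "
          f"{np.nan_to_num(en.values[j]):13.3f} "
          f"{np.nan_to_num(ori.values[j]):12.3f}")
print(f"\ntotal H-bonds per frame: {hb.values.sum() * state.box**3:.2f}")
print("Short distances show bonded, attractive, orientationally "
      "correlated pairs; all three signals decay toward larger r_CM.")
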
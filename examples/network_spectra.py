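"""Why summation is unstable and averaging is not: the spectra.

Generates a connected random geometric graph, builds the two linear
update matrices — I + A for confidence summation, the Metropolis–Hastings
doubly stochastic F for averaging — and prints their dominant eigenpairs.
"""

import numpy as np

from cascade_consensus.networks import (
    generate_connected_rgg,
    metropolis_hastings_weights,
    spectral_radius,
)

topo, rejections = generate_connected_rgg(30, 0.3, seed=11)
print(f"RGG: n=30, delta=0.3, mean degree {topo.mean_degree:.1f} "
      f"({rejections} disconnected draws rejected)")

rho_sum, v_sum = spectral_radius(np.eye(30) + topo.adjacency())
f = metropolis_hastings_weights(topo)
rho_avg, v_avg = spectral_radius(f)
rho_destab, v_destab = spectral_radius(0.1 * np.eye(30) + f)

print(f"summation  I+A   : spectral radius {rho_sum:.3f}  (> 1: unstable)")
print(f"averaging  F     : spectral radius {rho_avg:.3f}  (= 1: stable)")
print(f"destabilized eps I+F (eps=0.1): {rho_destab:.3f}  (= 1+eps)")
cv = np.std(v_sum / np.mean(v_sum))
print(f"summation dominant eigenvector coefficient of variation: {cv:.2f}")
print(
    "\nThe summation mode grows fastest but is NOT the ones vector on an\n"
    "irregular graph (nonzero CV), so the runaway need not reflect the\n"
    "population average — the root of negative cascades.  The destabilized\n"
    "averaging matrix grows along exactly the ones vector instead."
)
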
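"""Asynchronous sequential sampling: emergent leaders and positive cascades.

Simulates 30 groups of 50 coupled drift-diffusion decision-makers on
sparse geometric networks (mean degree 10).  Agents broadcast one-shot
decisions; undecided neighbours integrate them as confidence-calibrated
evidence kicks.  Prints who triggers the decision cascades and whether
they tend to be correct.
"""

import numpy as np

from cascade_consensus.collective_sequential import (
    SeqConfig,
    influence_stats,
    run_asynchronous,
)
from cascade_consensus.ddm import CostSpec, DriftPrior, optimal_thresholds
from cascade_consensus.experiments import child_seed, make_topology

cost = CostSpec(omega_e=100.0, omega_t=1.0)
prior = DriftPrior(mu=0.2, sigma=0.5)  # heterogeneous drift magnitudes
z = optimal_thresholds(cost, prior, sigma=1.0)
print(f"Bayes-risk-optimal threshold: z = {z:.3f}")

config = SeqConfig(n=50, drift_prior=prior, cost=cost, dt=0.01)
runs = []
for s in range(30):
    topo = make_topology(50, 10.0, child_seed(3, 0, s))
    runs.append(run_asynchronous(config, topo, seed=child_seed(3, 1, s), threshold=z))

stats = influence_stats(runs, sigma=1.0)
rho, p = stats.spearman_rank_vs_triggers()
correct = np.mean([r.correct_fraction(1) for r in runs])
n_casc = sum(len(r.cascades) for r in runs)
trig_correct = sum(
    int(r.options[c.trigger] == 1) for r in runs for c in r.cascades
)

print(f"mean fraction of agents deciding correctly: {correct:.3f}")
print(f"cascades (>= 5 decisions) observed: {n_casc}")
print(f"cascade triggers that decided correctly: {trig_correct}/{n_casc}")
print(f"Spearman(drift rank, #triggered cascades): rho = {rho:.2f} (p = {p:.1g})")
print(
    "\nNegative rho: the best-informed agents (rank 1 = highest drift/noise)\n"
    "trigger most cascades — they decide early, early decisions carry big\n"
    "kicks, and those cascades are overwhelmingly correct."
)
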
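"""Synchronous opinion pooling: Weighted Bayes Consensus vs Belief Consensus.

Runs both update rules on identical topologies, accuracies and initial
opinions (50 agents, random geometric graph with mean degree 10) and
prints group accuracy and mean consensus time per heterogeneity level.
Expected pattern: the summation rule (WBC) reaches unanimity in fewer
iterations, but never beats the averaging rule (BC) on accuracy.
"""

from cascade_consensus.experiments import (
    ExperimentConfig,
    paired_comparison,
    summarize_signal_detection,
)

config = ExperimentConfig(
    scenario="signal-detection",
    n=50,
    kappa=10.0,
    sweep_values=(0.1, 0.3),
    replicates=50,
    master_seed=7,
)
runs = paired_comparison(config)
summary = summarize_signal_detection(runs, config.master_seed)

print(f"{'sigma_alpha':>11} {'algorithm':>9} {'accuracy':>9} {'mean time':>10}")
for _, row in summary.iterrows():
    print(
        f"{row.sweep_value:>11} {row.algorithm:>9} "
        f"{row.group_accuracy:>9.2f} {row.mean_consensus_time:>10.2f}"
    )
print(
    "\nAccuracy = fraction of runs unanimous for the true state; "
    "time = iterations to unanimity.\n"
    "WBC trades accuracy for speed: its unstable summation locks signs "
    "in quickly,\nwhile BC's averaging converges to the optimal pooled "
    "statistic but more slowly."
)
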
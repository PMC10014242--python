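"""Reproducible experiment drivers.

Binds the topology, synchronous and asynchronous modules into seeded
sweeps, mirroring the two headline experiment shapes:

* a speed/accuracy comparison of Weighted Bayes Consensus vs Belief
  Consensus across accuracy-heterogeneity levels (paired seeds, so the
  two algorithms see identical topologies, accuracies and initial
  opinions);
* an asynchronous leader/cascade sweep across drift-heterogeneity
  levels, with optional kick-disabled (asocial) paired baselines.

Every random draw descends from a master seed through
``numpy.random.SeedSequence`` spawn keys, so runs are deterministic and
independently re-derivable per (sweep value, replicate).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import collective_sequential as cs
from . import signal_detection as sd
from .ddm import CostSpec, DriftPrior, optimal_thresholds
from .networks import (
    Topology,
    generate_connected_rgg,
    radius_for_target_degree,
)

__all__ = [
    "ExperimentConfig",
    "child_seed",
    "wilson_interval",
    "bootstrap_mean_interval",
    "make_topology",
    "paired_comparison",
    "summarize_signal_detection",
    "sequential_sweep",
    "run_experiment",
]


def child_seed(master_seed: int, *key: int) -> np.random.SeedSequence:
    """Deterministic per-(sweep value, replicate) seed via spawn keys."""
    return np.random.SeedSequence(master_seed, spawn_key=tuple(key))


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    z = sstats.norm.ppf(0.5 + confidence / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def bootstrap_mean_interval(
    values, seed, n_boot: int = 1000, confidence: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap interval for a mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - confidence), 50 * (1 + confidence)])
    return (float(lo), float(hi))


_radius_cache: dict[tuple[int, float], float] = {}


def make_topology(n: int, kappa: float, seed) -> Topology:
    """Connected RGG with average degree calibrated to kappa.

    The delta-for-kappa calibration is cached per (n, kappa) — it is a
    property of the ensemble, not of one instance.
    """
    key = (n, round(kappa, 6))
    if key not in _radius_cache:
        _radius_cache[key] = radius_for_target_degree(n, kappa, seed=1234)
    topo, _ = generate_connected_rgg(n, _radius_cache[key], seed)
    return topo


@dataclass(frozen=True)
class ExperimentConfig:
    """A sweep over one parameter of one scenario."""

    scenario: str  # "signal-detection" | "sequential"
    n: int = 50
    kappa: float = 10.0
    sweep_parameter: str = "sigma_alpha"
    sweep_values: tuple = (0.1, 0.3, 0.5)
    replicates: int = 100
    master_seed: int = 0
    # signal-detection settings
    algorithms: tuple = ("WBC", "BC")
    p_plus: float = 0.5
    true_state: int = 1
    mu_alpha: float = 0.5
    max_iterations: int = 1000
    # sequential settings
    mu_drift: float = 0.2
    sigma: float = 1.0
    omega_e: float = 100.0
    omega_t: float = 1.0
    dt: float = 0.01
    include_asocial: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in ("signal-detection", "sequential"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def paired_comparison(config: ExperimentConfig) -> pd.DataFrame:
    """Synchronous algorithms on shared topologies/accuracies/initial opinions.

    Returns one row per (sweep value, replicate, algorithm) with columns
    (seed_key, algorithm, sigma_alpha, N, kappa, outcome, consensus_time),
    where every algorithm within a (sweep value, replicate) cell saw
    byte-identical inputs, so differences are attributable to the update
    rule alone.
    """
    if config.scenario != "signal-detection":
        raise ValueError("paired_comparison applies to the signal-detection scenario")
    if len(config.algorithms) < 1:
        raise ValueError("need at least one algorithm")
    rows = []
    for sv_idx, sigma_alpha in enumerate(config.sweep_values):
        for rep in range(config.replicates):
            ss = child_seed(config.master_seed, sv_idx, rep)
            topo_seed, acc_seed, init_seed = ss.spawn(3)
            topo = make_topology(config.n, config.kappa, topo_seed)
            accuracies = sd.sample_accuracies(
                config.mu_alpha, sigma_alpha, config.n, acc_seed
            )
            initial = sd.initialize_population(
                accuracies, config.true_state, init_seed
            )
            for algorithm in config.algorithms:
                run_cfg = sd.SDConfig(
                    n=config.n,
                    p_plus=config.p_plus,
                    true_state=config.true_state,
                    mu_alpha=config.mu_alpha,
                    sigma_alpha=sigma_alpha,
                    max_iterations=config.max_iterations,
                    algorithm=algorithm,
                )
                result = sd.run_synchronous(
                    run_cfg, topo, seed=0, accuracies=accuracies,
                    initial=sd.SDPopulation(
                        opinions=initial.opinions.copy(),
                        confidences=initial.confidences.copy(),
                    ),
                )
                rows.append(
                    {
                        "sweep_value": sigma_alpha,
                        "replicate": rep,
                        "algorithm": algorithm,
                        "sigma_alpha": sigma_alpha,
                        "N": config.n,
                        "kappa": config.kappa,
                        "outcome": result.outcome,
                        "consensus_time": result.consensus_time,
                    }
                )
    return pd.DataFrame(rows)


def summarize_signal_detection(runs: pd.DataFrame, master_seed: int = 0) -> pd.DataFrame:
    """Per (sweep value, algorithm): group accuracy and mean consensus time.

    Group accuracy is the proportion of runs unanimous for the true
    state (timeouts count as not unanimous); consensus time averages over
    unanimous runs only.  Wilson intervals for the proportion, percentile
    bootstrap for the time mean.
    """
    out = []
    for (sv, algo), grp in runs.groupby(["sweep_value", "algorithm"]):
        n = len(grp)
        k = int((grp["outcome"] == "unanimous-correct").sum())
        acc_lo, acc_hi = wilson_interval(k, n)
        ct = grp.loc[grp["consensus_time"].notna(), "consensus_time"].to_numpy(float)
        t_lo, t_hi = bootstrap_mean_interval(ct, seed=child_seed(master_seed, 9999))
        out.append(
            {
                "sweep_value": sv,
                "algorithm": algo,
                "n_runs": n,
                "group_accuracy": k / n,
                "accuracy_ci_low": acc_lo,
                "accuracy_ci_high": acc_hi,
                "mean_consensus_time": float(ct.mean()) if ct.size else float("nan"),
                "time_ci_low": t_lo,
                "time_ci_high": t_hi,
                "n_timeouts": int((grp["outcome"] == "timeout").sum()),
            }
        )
    return pd.DataFrame(out)


def sequential_sweep(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, dict[float, list[cs.SeqRunResult]]]:
    """Asynchronous runs across drift-heterogeneity values.

    Returns a per-run summary DataFrame and the full run results keyed by
    sweep value (needed for cascade/leader statistics).  When
    ``include_asocial`` is set, each replicate is also run with kicks
    disabled on the same topology, drifts and noise seed.
    """
    if config.scenario != "sequential":
        raise ValueError("sequential_sweep applies to the sequential scenario")
    cost = CostSpec(omega_e=config.omega_e, omega_t=config.omega_t, p_plus=config.p_plus)
    rows = []
    results: dict[float, list[cs.SeqRunResult]] = {}
    for sv_idx, sigma_drift in enumerate(config.sweep_values):
        prior = DriftPrior(config.mu_drift, sigma_drift)
        z = optimal_thresholds(cost, prior, config.sigma)
        run_cfg = cs.SeqConfig(
            n=config.n,
            drift_prior=prior,
            sigma=config.sigma,
            cost=cost,
            dt=config.dt,
            true_state=config.true_state,
        )
        results[sigma_drift] = []
        for rep in range(config.replicates):
            ss = child_seed(config.master_seed, sv_idx, rep)
            topo_seed, drift_seed, run_seed = ss.spawn(3)
            topo = make_topology(config.n, config.kappa, topo_seed)
            drifts = cs.sample_drifts(prior, config.true_state, config.n, drift_seed)
            variants = [("social", run_cfg)]
            if config.include_asocial:
                variants.append(("asocial", replace(run_cfg, kicks_enabled=False)))
            for label, cfg in variants:
                res = cs.run_asynchronous(
                    cfg, topo, seed=run_seed, drifts=drifts, threshold=z
                )
                if label == "social":
                    results[sigma_drift].append(res)
                rows.append(
                    {
                        "sweep_value": sigma_drift,
                        "replicate": rep,
                        "condition": label,
                        "N": config.n,
                        "kappa": config.kappa,
                        "threshold": z,
                        "correct_fraction": res.correct_fraction(config.true_state),
                        "n_undecided": int((res.options == 0).sum()),
                        "n_cascades": len(res.cascades),
                        "mean_cost": cs.bayes_risk_cost(res, cost, config.true_state),
                    }
                )
    return pd.DataFrame(rows), results


def run_experiment(config: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Run the configured sweep, write per-run and summary CSVs, return runs.

    The effective configuration is echoed to ``config.json`` in the output
    directory so every result is traceable to its parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, default=list))
    if config.scenario == "signal-detection":
        runs = paired_comparison(config)
        summary = summarize_signal_detection(runs, config.master_seed)
    else:
        runs, results = sequential_sweep(config)
        summary_rows = []
        for sv, res_list in results.items():
            stats = cs.influence_stats(res_list, sigma=config.sigma)
            rho, p = stats.spearman_rank_vs_triggers()
            top_q, bot_q = stats.quartile_mean_sizes()
            sub = runs[(runs["sweep_value"] == sv) & (runs["condition"] == "social")]
            summary_rows.append(
                {
                    "sweep_value": sv,
                    "n_runs": len(res_list),
                    "mean_correct_fraction": float(sub["correct_fraction"].mean()),
                    "mean_cost": float(sub["mean_cost"].mean()),
                    "spearman_rank_triggers": rho,
                    "spearman_p": p,
                    "top_quartile_mean_cascade_size": top_q,
                    "bottom_quartile_mean_cascade_size": bot_q,
                }
            )
        summary = pd.DataFrame(summary_rows)
    runs.to_csv(out / "runs.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    return runs
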
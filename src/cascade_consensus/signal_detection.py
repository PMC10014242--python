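"""Synchronous collective signal detection.

Every agent holds a binary opinion ``x_i ∈ {-1, +1}`` and a non-negative
log-odds confidence ``c_i``.  At initialization the confidence is derived
from the agent's accuracy ``alpha_i`` as ``c = ln(alpha / (1 - alpha))``,
the log-odds of being correct.  On each synchronous iteration agents pool
their neighbours' confidence-weighted votes.  Two update rules are
implemented:

* **Weighted Bayes Consensus (WBC)** — the locally Bayes-optimal rule
  under correlation neglect: signed evidence values ``y_i = x_i c_i`` are
  summed over the closed neighbourhood and a prior log-odds term is added.
  As a linear system ``y' = (I + A) y`` this is unstable: magnitudes grow
  without bound and, on irregular graphs, the dominant mode is not the
  population average, which is what makes runaway (negative-cascade)
  outcomes possible.
* **Belief Consensus (BC)** — distributed averaging
  ``y' = (I - eps L) y``; with ``I - eps L`` doubly stochastic it provably
  converges to the mean of the initial signed evidence, the globally
  optimal pooled statistic.  A destabilized variant ``y' = (eps_d I + F) y``
  keeps the averaging eigenstructure while letting the consensus mode grow,
  trading boundedness for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .networks import Topology, metropolis_hastings_weights, safe_epsilon

__all__ = [
    "SDPopulation",
    "SDConfig",
    "SDRunResult",
    "confidence_from_accuracy",
    "accuracy_from_confidence",
    "prior_log_odds",
    "sample_accuracies",
    "initialize_population",
    "wbc_step",
    "direct_bayes_posterior",
    "belief_consensus_step",
    "destabilized_consensus_step",
    "run_synchronous",
]

# Renormalize WBC magnitudes when the largest |y| exceeds this; the update
# is linear so a positive global rescale never changes any future sign.
RENORM_THRESHOLD = 1e100

_ACC_CLAMP = 1e-6  # keeps log-odds finite for accuracies sampled at ~1.0


def confidence_from_accuracy(alpha):
    """Log-odds confidence ``ln(alpha / (1 - alpha))``.

    Zero at chance level (alpha = 0.5), strictly increasing in alpha.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha <= 0.0) | (alpha >= 1.0)):
        raise ValueError("accuracy must lie strictly in (0, 1)")
    out = np.log(alpha / (1.0 - alpha))
    return float(out) if out.ndim == 0 else out


def accuracy_from_confidence(c):
    """Inverse map: logistic(c) = e^c / (1 + e^c), clamped against overflow."""
    c = np.clip(np.asarray(c, dtype=float), -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(-c))
    return float(out) if out.ndim == 0 else out


def prior_log_odds(p_plus: float, opinion: int) -> float:
    """Log prior ratio in favour of the given opinion.

    ``ln(P(S+)/P(S-))`` for opinion +1 and the reciprocal log argument for
    opinion -1.
    """
    if not 0.0 < p_plus < 1.0:
        raise ValueError(f"prior P(S+) must be in (0,1), got {p_plus}")
    if opinion not in (-1, 1):
        raise ValueError(f"opinion must be ±1, got {opinion}")
    return float(opinion * np.log(p_plus / (1.0 - p_plus)))


def sample_accuracies(mu_alpha: float, sigma_alpha: float, n: int, seed) -> np.ndarray:
    """Draw accuracies from Normal(mu, sigma), flipping values < 0.5 to 1 - value.

    The flip makes every agent weakly better than chance; increasing
    sigma_alpha therefore raises the mean individual accuracy (folded
    distribution).  Outputs are clamped into ``(0.5, 1 - 1e-6]`` so the
    log-odds confidence stays finite.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sigma_alpha < 0:
        raise ValueError(f"sigma_alpha must be >= 0, got {sigma_alpha}")
    rng = np.random.default_rng(seed)
    a = rng.normal(mu_alpha, sigma_alpha, size=n)
    a = np.where(a < 0.5, 1.0 - a, a)
    return np.clip(a, 0.5, 1.0 - _ACC_CLAMP)


@dataclass
class SDPopulation:
    """Opinions and confidences of the synchronous population at one iteration."""

    opinions: np.ndarray  # ±1 ints
    confidences: np.ndarray  # >= 0 floats
    t: int = 0
    renorm_log_scale: float = 0.0  # cumulative ln of scale divided out (WBC)

    def __post_init__(self) -> None:
        self.opinions = np.asarray(self.opinions, dtype=int)
        self.confidences = np.asarray(self.confidences, dtype=float)
        if self.opinions.shape != self.confidences.shape:
            raise ValueError("opinions and confidences must have the same length")
        if not np.all(np.abs(self.opinions) == 1):
            raise ValueError("opinions must be ±1")
        if np.any(self.confidences < 0):
            raise ValueError("confidences must be >= 0")

    @property
    def n(self) -> int:
        return self.opinions.size

    @property
    def signed_evidence(self) -> np.ndarray:
        """y_i = x_i * c_i."""
        return self.opinions * self.confidences

    def is_unanimous(self) -> bool:
        return bool(np.all(self.opinions == self.opinions[0]))


def initialize_population(
    accuracies: np.ndarray, true_state: int, seed
) -> SDPopulation:
    """Independent initial opinions and log-odds confidences.

    Each agent is correct (opinion = true state) with probability equal to
    its accuracy; its confidence is the log-odds of that accuracy.
    """
    if true_state not in (-1, 1):
        raise ValueError(f"true_state must be ±1, got {true_state}")
    accuracies = np.asarray(accuracies, dtype=float)
    rng = np.random.default_rng(seed)
    correct = rng.random(accuracies.size) < accuracies
    opinions = np.where(correct, true_state, -true_state)
    return SDPopulation(opinions=opinions, confidences=confidence_from_accuracy(accuracies))


def _sign_with_memory(values: np.ndarray, previous: np.ndarray) -> np.ndarray:
    """sign(values), with exact zeros resolved by keeping the previous opinion."""
    s = np.sign(values).astype(int)
    return np.where(s == 0, previous, s)


def wbc_step(pop: SDPopulation, topology: Topology, p_plus: float = 0.5) -> SDPopulation:
    """One synchronous Weighted Bayes Consensus update.

    For every agent simultaneously: ``s_i = x_i c_i + sum_{j in M_i} x_j c_j``;
    the new opinion is ``sign(s_i)`` (an exact zero retains the previous
    opinion) and the new confidence is ``|s_i + pi(new opinion)|`` where
    ``pi`` is the prior log-odds of the newly adopted opinion.
    """
    if pop.n != topology.n:
        raise ValueError(f"population size {pop.n} != topology size {topology.n}")
    if not np.all(np.isfinite(pop.confidences)):
        raise ValueError("non-finite confidence; renormalize before stepping")
    y = pop.signed_evidence
    a = topology.adjacency()
    s = y + a @ y
    new_op = _sign_with_memory(s, pop.opinions)
    pi = np.where(new_op == 1, prior_log_odds(p_plus, 1), prior_log_odds(p_plus, -1))
    new_conf = np.abs(s + pi)
    new = SDPopulation(
        opinions=new_op,
        confidences=new_conf,
        t=pop.t + 1,
        renorm_log_scale=pop.renorm_log_scale,
    )
    return _maybe_renormalize(new)


def _maybe_renormalize(pop: SDPopulation) -> SDPopulation:
    """Divide all magnitudes by max|y| once it exceeds RENORM_THRESHOLD.

    A uniform positive rescale commutes with the linear update, so every
    future sign decision is unchanged; the applied log-scale is accumulated
    for the record.
    """
    m = float(pop.confidences.max(initial=0.0))
    if m > RENORM_THRESHOLD:
        return replace(
            pop,
            confidences=pop.confidences / m,
            renorm_log_scale=pop.renorm_log_scale + float(np.log(m)),
        )
    return pop


def direct_bayes_posterior(votes, p_plus: float, candidate: int) -> float:
    """Exact naive-Bayes posterior P(S = candidate | votes).

    ``votes`` is a sequence of ``(opinion ±1, confidence >= 0)`` pairs.
    Each confidence is inverted to the voter's accuracy; the likelihood of
    the vote set under each world state is the product of per-vote terms
    (accuracy if the vote matches the state, error rate otherwise); Bayes'
    rule with the world prior then normalizes over the two candidates.

    This deliberately slow, literal computation is the reference for the
    linear-summation shortcut in :func:`wbc_step`.
    """
    if candidate not in (-1, 1):
        raise ValueError(f"candidate must be ±1, got {candidate}")
    if not 0.0 < p_plus < 1.0:
        raise ValueError(f"prior must be in (0,1), got {p_plus}")
    log_lik = {1: 0.0, -1: 0.0}
    for opinion, conf in votes:
        if conf < 0:
            raise ValueError("confidences must be >= 0")
        acc = accuracy_from_confidence(conf)
        for state in (1, -1):
            p = acc if opinion == state else 1.0 - acc
            log_lik[state] += np.log(p)
    log_post = {
        1: log_lik[1] + np.log(p_plus),
        -1: log_lik[-1] + np.log(1.0 - p_plus),
    }
    m = max(log_post.values())
    z = sum(np.exp(v - m) for v in log_post.values())
    return float(np.exp(log_post[candidate] - m) / z)


def belief_consensus_step(
    pop: SDPopulation, topology: Topology, epsilon: float
) -> SDPopulation:
    """One synchronous Belief Consensus (distributed averaging) update.

    ``y_i' = y_i + eps * sum_{j in M_i} (y_j - y_i)``, i.e. ``y' = (I - eps L) y``.
    With eps small enough that ``I - eps L`` is doubly stochastic the sum of
    y is conserved and the state converges to the initial mean on any
    connected graph.
    """
    if pop.n != topology.n:
        raise ValueError(f"population size {pop.n} != topology size {topology.n}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    d_max = int(topology.degrees().max(initial=0))
    if epsilon * d_max > 1.0 + 1e-12:
        raise ValueError(
            f"epsilon={epsilon} makes I - eps*L have a negative diagonal "
            f"(max degree {d_max}); use eps <= 1/max_degree"
        )
    y = pop.signed_evidence
    lap = topology.laplacian()
    y_new = y - epsilon * (lap @ y)
    new_op = _sign_with_memory(y_new, pop.opinions)
    return SDPopulation(
        opinions=new_op, confidences=np.abs(y_new), t=pop.t + 1,
        renorm_log_scale=pop.renorm_log_scale,
    )


def destabilized_consensus_step(
    pop: SDPopulation,
    topology: Topology,
    epsilon_destab: float,
    epsilon_avg: float | None = None,
    weight_matrix: np.ndarray | None = None,
) -> SDPopulation:
    """Destabilized averaging: ``y' = (eps_d I + F) y``.

    F is the doubly stochastic averaging matrix (``I - eps_avg L`` by
    default, or an explicit matrix such as the Metropolis–Hastings one).
    The dominant eigenvalue is ``1 + eps_d`` with the ones vector as
    eigenvector, so the growing mode carries the average of the initial
    conditions and signs converge to the sign of that average.
    ``eps_d = 0`` reduces exactly to :func:`belief_consensus_step`.
    """
    if epsilon_destab < 0:
        raise ValueError(f"epsilon_destab must be >= 0, got {epsilon_destab}")
    if weight_matrix is not None:
        f = np.asarray(weight_matrix, dtype=float)
        y_new = epsilon_destab * pop.signed_evidence + f @ pop.signed_evidence
        new_op = _sign_with_memory(y_new, pop.opinions)
        return SDPopulation(
            opinions=new_op, confidences=np.abs(y_new), t=pop.t + 1,
            renorm_log_scale=pop.renorm_log_scale,
        )
    if epsilon_avg is None:
        epsilon_avg = safe_epsilon(topology)
    base = belief_consensus_step(pop, topology, epsilon_avg)
    y_new = base.signed_evidence + epsilon_destab * pop.signed_evidence
    new_op = _sign_with_memory(y_new, pop.opinions)
    new = SDPopulation(
        opinions=new_op, confidences=np.abs(y_new), t=pop.t + 1,
        renorm_log_scale=pop.renorm_log_scale,
    )
    return _maybe_renormalize(new)


@dataclass(frozen=True)
class SDConfig:
    """Configuration for one synchronous run."""

    n: int = 50
    p_plus: float = 0.5
    true_state: int = 1
    mu_alpha: float = 0.5
    sigma_alpha: float = 0.3
    max_iterations: int = 1000
    algorithm: str = "WBC"  # WBC | BC | BC-destabilized
    epsilon: float | None = None  # BC step size; None -> 1/(1+max degree)
    epsilon_destab: float = 0.1  # gain for BC-destabilized

    def __post_init__(self) -> None:
        if not 0.0 < self.p_plus < 1.0:
            raise ValueError("prior P(S+) must be in (0,1)")
        if self.true_state not in (-1, 1):
            raise ValueError("true_state must be ±1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.algorithm not in ("WBC", "BC", "BC-destabilized"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class SDRunResult:
    """Outcome of one synchronous run."""

    outcome: str  # unanimous-correct | unanimous-wrong | timeout
    consensus_time: int | None  # iterations to unanimity; None on timeout
    opinion_counts: list[tuple[int, int]]  # per-iteration (#+1, #-1)
    final_signed_evidence: np.ndarray
    accuracies: np.ndarray

    @property
    def unanimous(self) -> bool:
        return self.outcome.startswith("unanimous")


def run_synchronous(
    config: SDConfig,
    topology: Topology,
    seed,
    accuracies: np.ndarray | None = None,
    initial: SDPopulation | None = None,
) -> SDRunResult:
    """Run the configured synchronous update rule to unanimity or timeout.

    Accuracies and initial opinions may be supplied explicitly (used by the
    paired-comparison driver to share them across algorithms); otherwise
    they are drawn from ``seed``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    acc_seed, init_seed = ss.spawn(2)
    if accuracies is None:
        accuracies = sample_accuracies(
            config.mu_alpha, config.sigma_alpha, config.n, acc_seed
        )
    if initial is None:
        pop = initialize_population(accuracies, config.true_state, init_seed)
    else:
        pop = initial
    if pop.n != topology.n:
        raise ValueError("population/topology size mismatch")

    eps = config.epsilon if config.epsilon is not None else safe_epsilon(topology)

    def step(p: SDPopulation) -> SDPopulation:
        if config.algorithm == "WBC":
            return wbc_step(p, topology, config.p_plus)
        if config.algorithm == "BC":
            return belief_consensus_step(p, topology, eps)
        return destabilized_consensus_step(
            p, topology, config.epsilon_destab, epsilon_avg=eps
        )

    counts = []

    def record(p: SDPopulation) -> None:
        plus = int(np.sum(p.opinions == 1))
        counts.append((plus, p.n - plus))

    record(pop)
    t = 0
    while not pop.is_unanimous() and t < config.max_iterations:
        pop = step(pop)
        t += 1
        record(pop)

    if pop.is_unanimous():
        outcome = (
            "unanimous-correct"
            if pop.opinions[0] == config.true_state
            else "unanimous-wrong"
        )
        consensus_time = t
    else:
        outcome, consensus_time = "timeout", None
    return SDRunResult(
        outcome=outcome,
        consensus_time=consensus_time,
        opinion_counts=counts,
        final_signed_evidence=pop.signed_evidence,
        accuracies=np.asarray(accuracies, dtype=float),
    )
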
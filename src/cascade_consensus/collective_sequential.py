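"""Asynchronous collective sequential sampling.

``N`` drift-diffusion accumulators integrate private evidence on a shared
communication topology.  When an agent's evidence first crosses a
threshold it broadcasts its decision once; each still-undecided neighbour
receives, one time step later, a signed evidence "kick" whose magnitude
is the Bayes-optimal log-odds implied by the sender's option and decision
time (see :func:`cascade_consensus.ddm.kick_size`).  Decisions are final:
decided agents stop integrating and never receive further input.

Because accurate agents (high drift-to-noise ratio) tend to decide early
and early decisions carry large kicks, chains of kick-caused decisions —
information cascades — are predominantly triggered by the best-informed
agents, which is the mechanism this module's statistics quantify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sstats

from .ddm import (
    CostSpec,
    DriftPrior,
    expected_decision_time,
    kick_size,
    optimal_thresholds,
    sample_drifts,
)
from .networks import Topology

__all__ = [
    "SeqConfig",
    "DecisionEvent",
    "CascadeRecord",
    "SeqRunResult",
    "run_asynchronous",
    "detect_cascades",
    "influence_stats",
    "bayes_risk_cost",
]


@dataclass(frozen=True)
class SeqConfig:
    """Configuration for one asynchronous run."""

    n: int = 50
    drift_prior: DriftPrior = field(default_factory=lambda: DriftPrior(0.2, 0.5))
    sigma: float = 1.0
    cost: CostSpec = field(default_factory=lambda: CostSpec(omega_e=100.0, omega_t=1.0))
    dt: float = 0.01
    true_state: int = 1
    max_time: float | None = None  # None -> 10x the asocial mean decision time
    kicks_enabled: bool = True
    marginalize_threshold: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.true_state not in (-1, 1):
            raise ValueError("true_state must be ±1")

    def horizon(self, z: float) -> float:
        """Simulation horizon: 10x the asocial mean decision time at mu_A."""
        if self.max_time is not None:
            return self.max_time
        mu = max(abs(self.drift_prior.mu), 1e-6)
        return 10.0 * expected_decision_time(mu, self.sigma, z)


@dataclass(frozen=True)
class DecisionEvent:
    """One agent's (final) decision."""

    agent: int
    time: float  # multiple of dt
    option: int  # ±1
    cause: str  # "spontaneous" | "kick"
    parent: int | None = None  # causing neighbour when cause == "kick"


@dataclass(frozen=True)
class CascadeRecord:
    """A causal chain of decisions rooted at a spontaneous trigger."""

    trigger: int
    members: tuple[int, ...]  # trigger first, then descendants in event order
    trigger_drift_rank: int | None = None  # 1 = highest |drift|/noise in group

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SeqRunResult:
    """Full record of one asynchronous run."""

    events: list[DecisionEvent]
    options: np.ndarray  # ±1 decided, 0 undecided at horizon
    times: np.ndarray  # decision times, nan if undecided
    drifts: np.ndarray  # signed drifts used
    threshold: float
    cascades: list[CascadeRecord]
    horizon: float

    @property
    def n(self) -> int:
        return self.options.size

    @property
    def decided(self) -> np.ndarray:
        return self.options != 0

    @property
    def undecided_set(self) -> set[int]:
        return set(np.nonzero(self.options == 0)[0].tolist())

    def correct_fraction(self, true_state: int) -> float:
        """Fraction of *all* agents that decided for the true state."""
        return float(np.mean(self.options == true_state))


class _KickCache:
    """Memoized kick magnitudes for one (prior, sigma, z, p_plus) setting.

    Decision times are multiples of dt, so repeated lookups are common;
    values are computed exactly on first use.
    """

    def __init__(self, prior: DriftPrior, sigma: float, z: float, p_plus: float):
        self.prior, self.sigma, self.z, self.p_plus = prior, sigma, z, p_plus
        self._compute = lru_cache(maxsize=None)(self._compute_uncached)

    def _compute_uncached(self, t: float, option: int) -> float:
        return kick_size(t, option, self.prior, self.sigma, self.z, self.p_plus)

    def __call__(self, t: float, option: int) -> float:
        return self._compute(round(t, 12), option)


def run_asynchronous(
    config: SeqConfig,
    topology: Topology,
    seed,
    drifts: np.ndarray | None = None,
    threshold: float | None = None,
    min_cascade_size: int | None = None,
) -> SeqRunResult:
    """Simulate N coupled accumulators to all-decided or the horizon.

    All agents start at zero evidence at t = 0 with signed drifts drawn
    from the population prior (sign = true state).  Time advances in steps
    of dt; undecided agents take an Euler–Maruyama step, then any kicks
    broadcast on the *previous* step are delivered, then threshold
    crossings are evaluated.  Agents crossing this step emit one
    :class:`DecisionEvent` (cause "kick" if the delivered kicks were
    necessary for the crossing) and broadcast once; decided agents are
    frozen.

    ``drifts`` and ``threshold`` may be supplied to share them across
    paired runs; otherwise drifts are sampled from ``seed`` and the
    threshold is set by Bayes-risk minimization.
    """
    if topology.n != config.n:
        raise ValueError(f"topology size {topology.n} != config n {config.n}")
    rng = np.random.default_rng(seed)
    if drifts is None:
        drifts = sample_drifts(config.drift_prior, config.true_state, config.n, rng)
    else:
        drifts = np.asarray(drifts, dtype=float)
    if threshold is None:
        threshold = optimal_thresholds(
            config.cost, config.drift_prior, config.sigma,
            marginalize=config.marginalize_threshold,
        )
    z = float(threshold)
    horizon = config.horizon(z)
    kick_of = _KickCache(config.drift_prior, config.sigma, z, config.cost.p_plus)
    neighbours = topology.neighbour_lists()

    n = config.n
    y = np.zeros(n)
    undecided = np.ones(n, dtype=bool)
    options = np.zeros(n, dtype=int)
    times = np.full(n, np.nan)
    events: list[DecisionEvent] = []
    event_time_of: dict[int, float] = {}
    # broadcasts emitted last step, to deliver this step: (sender, option, t_dec)
    outbox: list[tuple[int, int, float]] = []

    sq = config.sigma * math.sqrt(config.dt)
    n_steps = int(math.ceil(horizon / config.dt))
    t = 0.0
    for _ in range(n_steps):
        if not undecided.any():
            break
        t += config.dt
        idx = np.nonzero(undecided)[0]
        y[idx] += drifts[idx] * config.dt + sq * rng.standard_normal(idx.size)
        y_pre = y.copy()

        # deliver last step's broadcasts to still-undecided neighbours
        contributions: dict[int, list[tuple[int, float, float]]] = {}
        if config.kicks_enabled and outbox:
            for sender, option, t_dec in outbox:
                k = kick_of(t_dec, option)
                for nb in neighbours[sender]:
                    if undecided[nb]:
                        y[nb] += k
                        contributions.setdefault(nb, []).append((sender, k, t_dec))
        outbox = []

        crossed_up = undecided & (y >= z)
        crossed_dn = undecided & (y <= -z)
        crossed = np.nonzero(crossed_up | crossed_dn)[0]
        for i in crossed.tolist():
            option = 1 if crossed_up[i] else -1
            pre_crossed = y_pre[i] >= z or y_pre[i] <= -z
            if pre_crossed or i not in contributions:
                cause, parent = "spontaneous", None
            else:
                # attribute to the largest kick in the crossing direction;
                # ties: earliest sender decision, then lowest sender index
                best = max(
                    contributions[i],
                    key=lambda c: (c[1] * option, -c[2], -c[0]),
                )
                if best[1] * option > 0:
                    cause, parent = "kick", best[0]
                else:
                    cause, parent = "spontaneous", None
            undecided[i] = False
            options[i] = option
            times[i] = t
            events.append(
                DecisionEvent(agent=i, time=t, option=option, cause=cause, parent=parent)
            )
            event_time_of[i] = t
            outbox.append((i, option, t))

    if min_cascade_size is None:
        min_cascade_size = math.ceil(n / 10)
    result = SeqRunResult(
        events=events,
        options=options,
        times=times,
        drifts=drifts,
        threshold=z,
        cascades=[],
        horizon=horizon,
    )
    result.cascades = detect_cascades(events, topology, min_cascade_size)
    return result


def detect_cascades(
    events: list[DecisionEvent], topology: Topology, min_size: int
) -> list[CascadeRecord]:
    """Group decisions into causal trees and keep those of size >= min_size.

    Each kick-caused decision is a child of its causing neighbour's
    decision; spontaneous decisions are roots.  A cascade is a root plus
    all causal descendants; its size counts the trigger.
    """
    decided = {e.agent for e in events}
    time_of = {e.agent: e.time for e in events}
    neighbour_sets = [set(m) for m in topology.neighbour_lists()]
    children: dict[int, list[int]] = {}
    roots: list[DecisionEvent] = []
    for e in events:
        if e.cause == "kick":
            if e.parent is None or e.parent not in decided:
                raise ValueError(f"dangling cause reference in event {e}")
            if time_of[e.parent] >= e.time:
                raise ValueError(f"causal parent does not precede event {e}")
            if e.agent not in neighbour_sets[e.parent]:
                raise ValueError(f"causal parent is not a neighbour in event {e}")
            children.setdefault(e.parent, []).append(e.agent)
        else:
            roots.append(e)

    out = []
    for root in roots:
        members = [root.agent]
        stack = list(children.get(root.agent, []))
        while stack:
            a = stack.pop()
            members.append(a)
            stack.extend(children.get(a, []))
        members_sorted = [root.agent] + sorted(
            members[1:], key=lambda a: (time_of[a], a)
        )
        if len(members_sorted) >= min_size:
            out.append(CascadeRecord(trigger=root.agent, members=tuple(members_sorted)))
    return out


def drift_ranks(drifts: np.ndarray, sigma: float) -> np.ndarray:
    """Rank agents by decreasing |drift|/noise; rank 1 is the best agent.

    Returns an array where entry i is agent i's rank.  Ties broken by
    agent index for determinism.
    """
    ratio = np.abs(np.asarray(drifts, dtype=float)) / sigma
    order = np.lexsort((np.arange(ratio.size), -ratio))
    ranks = np.empty(ratio.size, dtype=int)
    ranks[order] = np.arange(1, ratio.size + 1)
    return ranks


@dataclass
class InfluenceStats:
    """Per-drift-rank cascade-trigger statistics aggregated over runs."""

    trigger_counts: np.ndarray  # per rank (1-based rank r at index r-1)
    cascade_sizes: list[list[int]]  # per rank, sizes of triggered cascades
    n_runs: int

    def spearman_rank_vs_triggers(self) -> tuple[float, float]:
        """Spearman correlation of rank index vs trigger count.

        Negative rho means better-informed agents (low rank index)
        trigger more cascades.
        """
        ranks = np.arange(1, self.trigger_counts.size + 1)
        rho, p = sstats.spearmanr(ranks, self.trigger_counts)
        return float(rho), float(p)

    def uniformity_chi2(self) -> tuple[float, float]:
        """Chi-square test of trigger counts against uniformity over ranks."""
        c = self.trigger_counts
        stat, p = sstats.chisquare(c)
        return float(stat), float(p)

    def quartile_mean_sizes(self) -> tuple[float, float]:
        """(mean cascade size of top drift quartile, of bottom quartile)."""
        nr = len(self.cascade_sizes)
        q = max(nr // 4, 1)
        top = [s for sizes in self.cascade_sizes[:q] for s in sizes]
        bot = [s for sizes in self.cascade_sizes[-q:] for s in sizes]
        mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
        return mean(top), mean(bot)


def influence_stats(
    runs: list[SeqRunResult],
    drifts: list[np.ndarray] | None = None,
    sigma: float = 1.0,
) -> InfluenceStats:
    """Aggregate cascade-trigger counts and sizes by within-run drift rank.

    Within each run agents are sorted by decreasing drift-to-noise ratio;
    the statistics answer "how often, and how large, are the cascades
    triggered by the r-th best agent?" across runs.
    """
    if drifts is None:
        drifts = [r.drifts for r in runs]
    if len(runs) != len(drifts):
        raise ValueError("runs and drift lists must be aligned")
    if not runs:
        raise ValueError("need at least one run")
    n = runs[0].n
    counts = np.zeros(n, dtype=int)
    sizes: list[list[int]] = [[] for _ in range(n)]
    for run, dr in zip(runs, drifts):
        dr = np.asarray(dr, dtype=float)
        if dr.size != run.n:
            raise ValueError("drift list does not match run size")
        ranks = drift_ranks(dr, sigma)
        for casc in run.cascades:
            r = int(ranks[casc.trigger])
            counts[r - 1] += 1
            sizes[r - 1].append(casc.size)
    return InfluenceStats(trigger_counts=counts, cascade_sizes=sizes, n_runs=len(runs))


def bayes_risk_cost(
    result: SeqRunResult,
    cost: CostSpec,
    true_state: int,
    charge_undecided: bool = True,
) -> float:
    """Mean realized per-agent cost: w_t * time + w_e per wrong decision.

    Undecided agents at the horizon are charged w_t * horizon when
    ``charge_undecided`` (no error cost, since no decision was made);
    otherwise they are excluded from the mean.
    """
    if true_state not in (-1, 1):
        raise ValueError("true_state must be ±1")
    costs = []
    for i in range(result.n):
        if result.options[i] != 0:
            c = cost.omega_t * result.times[i]
            if result.options[i] != true_state:
                c += cost.omega_e
            costs.append(c)
        elif charge_undecided:
            costs.append(cost.omega_t * result.horizon)
    if not costs:
        return float("nan")
    return float(np.mean(costs))
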
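"""Single-agent drift-diffusion machinery.

Decision evidence evolves as biased Brownian motion
``dy = A dt + sigma dW`` from ``y(0) = 0`` until it first reaches one of
two absorbing thresholds ``z+ > 0 > z-`` (free-response paradigm).  The
sign of the crossed threshold is the decision; the crossing time is the
decision time.

The analytic pieces assume *symmetric* thresholds ``z- = -z+`` (the
relevant case under equal world priors and a symmetric cost matrix):

* the first-passage-time density through the upper threshold,
  conditioned on that threshold being hit first, via the classical
  image-charge series ``theta(t, u, v)``;
* the probability of hitting ``z+`` before ``z-``,
  ``1 - 1/(exp(2 A z / sigma^2) + 1)``;
* the Bayes-risk-optimal threshold, minimizing
  ``w_t * E[T] + w_e * P(error)`` marginalized over the population's
  drift-magnitude prior;
* the evidence "kick" a neighbour's announced decision is worth: the
  log-odds of the world state implied by which threshold was hit and
  when, marginalized over the drift prior (the receiver knows the
  population's drift distribution but not the sender's drift).

Asymmetric thresholds are deliberately not given an analytic path; the
Monte Carlo simulator (:func:`simulate_ddm`) handles them and doubles as
the module's independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .signal_detection import prior_log_odds

__all__ = [
    "DDMSpec",
    "DriftPrior",
    "CostSpec",
    "theta_series",
    "fpt_density",
    "hit_probability",
    "expected_decision_time",
    "error_probability",
    "bayes_risk",
    "optimal_thresholds",
    "kick_log_ratio",
    "kick_size",
    "simulate_ddm",
    "simulate_ddm_batch",
    "sample_drifts",
    "folded_normal_mean",
]


@dataclass(frozen=True)
class DDMSpec:
    """Drift-diffusion parameters: drift A, noise sigma, thresholds z+ > 0 > z-."""

    drift: float
    sigma: float = 1.0
    z_plus: float = 1.0
    z_minus: float = -1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.z_minus < 0 < self.z_plus:
            raise ValueError(
                f"need z- < 0 < z+, got z-={self.z_minus}, z+={self.z_plus}"
            )

    @property
    def symmetric(self) -> bool:
        return math.isclose(self.z_plus, -self.z_minus, rel_tol=1e-12)

    def _require_symmetric(self, what: str) -> None:
        if not self.symmetric:
            raise ValueError(
                f"{what} is only available for symmetric thresholds "
                f"(z- = -z+); got z+={self.z_plus}, z-={self.z_minus}. "
                "Use simulate_ddm / simulate_ddm_batch for asymmetric cases."
            )


@dataclass(frozen=True)
class DriftPrior:
    """Population prior over drift *magnitudes*.

    Magnitudes are folded draws ``|Normal(mu, sigma)|`` supported on
    (0, inf); the sign of any realized drift equals the true world state,
    i.e. no agent is systematically misinformed.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma_A must be >= 0, got {self.sigma}")

    def pdf(self, a) -> np.ndarray:
        """Folded-normal density on (0, inf); requires sigma > 0."""
        if self.sigma == 0:
            raise ValueError("point-mass prior has no density")
        a = np.asarray(a, dtype=float)
        out = (
            stats.norm.pdf(a, loc=self.mu, scale=self.sigma)
            + stats.norm.pdf(a, loc=-self.mu, scale=self.sigma)
        )
        return np.where(a > 0, out, 0.0)

    def mean(self) -> float:
        return folded_normal_mean(self.mu, self.sigma)

    @property
    def upper_support(self) -> float:
        """Effective truncation point for quadrature."""
        return abs(self.mu) + 8.0 * self.sigma


@dataclass(frozen=True)
class CostSpec:
    """Linear decision costs: w_e per error, w_t per unit decision time."""

    omega_e: float
    omega_t: float
    p_plus: float = 0.5

    def __post_init__(self) -> None:
        if self.omega_e <= 0 or self.omega_t <= 0:
            raise ValueError("omega_e and omega_t must be > 0")
        if not 0.0 < self.p_plus < 1.0:
            raise ValueError("p_plus must be in (0,1)")


def folded_normal_mean(mu: float, sigma: float) -> float:
    """Mean of |Normal(mu, sigma)| (closed form)."""
    if sigma == 0:
        return abs(mu)
    return float(
        sigma * math.sqrt(2.0 / math.pi) * math.exp(-(mu**2) / (2 * sigma**2))
        + mu * (1.0 - 2.0 * stats.norm.cdf(-mu / sigma))
    )


def theta_series(t: float, u: float, v: float, tol: float = 1e-12) -> float:
    """Image-charge series for the zero-drift double-barrier FPT density.

    ``theta(t, u, v) = sum_k (v - u + 2 k v) / sqrt(2 pi t^3)
    * exp(-(v - u + 2 k v)^2 / (2 t))`` over all integers k; it is the
    density of the first passage through the upper barrier ``v`` of a
    driftless unit-noise Brownian motion started at ``u`` between
    absorbing barriers at 0 and ``v``.

    Terms are summed outward from k = 0 (alternating +k, -k) until two
    consecutive terms are below ``tol`` in absolute value; the tail decays
    super-exponentially so truncation is benign.
    """
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if v <= 0:
        raise ValueError(f"v must be > 0, got {v}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    pref = 1.0 / math.sqrt(2.0 * math.pi * t**3)
    total = 0.0
    small_streak = 0
    k = 0
    while True:
        for kk in ([0] if k == 0 else [k, -k]):
            w = v - u + 2.0 * kk * v
            term = pref * w * math.exp(-(w * w) / (2.0 * t))
            total += term
            if abs(term) < tol:
                small_streak += 1
            else:
                small_streak = 0
        if small_streak >= 2:
            return total
        k += 1
        if k > 100000:  # pragma: no cover - series always terminates sooner
            raise RuntimeError("theta series failed to converge")


def fpt_density(t, which: int, spec: DDMSpec, tol: float = 1e-12):
    """First-passage-time density through one threshold, conditioned on it.

    For ``which = +1`` (the upper threshold ``z+``) returns

    ``exp(-A^2 t / 2 sigma^2 - A z / sigma^2) (1 + exp(2 A z / sigma^2))
    * theta(t, z/sigma, 2 z/sigma)``

    evaluated in the numerically stable equivalent form
    ``exp(-A^2 t / 2 sigma^2) * 2 cosh(A z / sigma^2) * theta(...)``.
    ``which = -1`` is the reflection ``A -> -A``.  The result is the
    density of the decision time *given* that the requested threshold is
    hit first; it integrates to one over t.
    """
    if which not in (-1, 1):
        raise ValueError(f"which must be ±1, got {which}")
    spec._require_symmetric("the analytic first-passage density")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("t must be > 0")
    a = spec.drift if which == 1 else -spec.drift
    z = spec.z_plus
    s2 = spec.sigma**2
    u = z / spec.sigma
    v = 2.0 * z / spec.sigma
    th = np.vectorize(lambda tt: theta_series(tt, u, v, tol))(t_arr)
    azs = a * z / s2
    # guard cosh overflow for extreme drift/threshold combinations
    log_cosh = np.logaddexp(azs, -azs) - math.log(2.0)
    out = np.exp(-(a * a) * t_arr / (2.0 * s2) + math.log(2.0) + log_cosh) * th
    return float(out) if out.ndim == 0 else out


def hit_probability(spec: DDMSpec) -> float:
    """Probability of reaching z+ before z- (symmetric thresholds)."""
    spec._require_symmetric("the analytic hit probability")
    x = 2.0 * spec.drift * spec.z_plus / spec.sigma**2
    # 1 - 1/(e^x + 1) = logistic(x)
    return float(1.0 / (1.0 + np.exp(-np.clip(x, -700, 700))))


def expected_decision_time(a: float, sigma: float, z: float) -> float:
    """Unconditional mean decision time ``(z/A) tanh(A z / sigma^2)``.

    Decreasing in the drift magnitude at fixed z, sigma; limit ``z^2 /
    sigma^2`` as A -> 0.
    """
    if z <= 0 or sigma <= 0:
        raise ValueError("need z > 0 and sigma > 0")
    x = a * z / sigma**2
    if abs(x) < 1e-8:
        return z**2 / sigma**2
    return (z / a) * math.tanh(x)


def error_probability(a_mag: float, sigma: float, z: float) -> float:
    """P(hit the wrong threshold) for drift magnitude a_mag > 0 toward the truth."""
    return float(1.0 / (1.0 + math.exp(min(2.0 * a_mag * z / sigma**2, 700.0))))


def bayes_risk(
    z: float,
    cost: CostSpec,
    prior: DriftPrior,
    sigma: float,
    marginalize: bool = True,
) -> float:
    """Expected cost ``w_t E[T] + w_e P(error)`` at threshold magnitude z.

    With ``marginalize`` the expectation is over the folded drift prior
    (quadrature); otherwise the prior's mu is used as a point drift.
    """
    if z <= 0:
        raise ValueError(f"z must be > 0, got {z}")

    def risk_at(a_mag: float) -> float:
        return cost.omega_t * expected_decision_time(
            a_mag, sigma, z
        ) + cost.omega_e * error_probability(a_mag, sigma, z)

    if not marginalize or prior.sigma == 0:
        return risk_at(abs(prior.mu))
    val, _ = integrate.quad(
        lambda a: risk_at(a) * prior.pdf(a),
        0.0,
        prior.upper_support,
        epsrel=1e-8,
        limit=200,
    )
    return float(val)


def optimal_thresholds(
    cost: CostSpec,
    prior: DriftPrior,
    sigma: float,
    marginalize: bool = True,
    z_max: float | None = None,
) -> float:
    """Symmetric threshold magnitude minimizing the Bayes risk.

    A coarse grid locates the basin, then bounded 1-D minimization
    refines it.  Raises if no interior minimum can be bracketed (e.g. the
    risk is still decreasing at ``z_max``), reporting the grid profile.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if z_max is None:
        # error cost caps the useful threshold: beyond the point where
        # w_t * E[T] alone exceeds w_e the risk must be increasing
        z_max = max(5.0, 3.0 * sigma**2 / max(abs(prior.mu), 1e-3))
    grid = np.linspace(1e-3, z_max, 200)
    br = np.array([bayes_risk(z, cost, prior, sigma, marginalize) for z in grid])
    k = int(np.argmin(br))
    if k == len(grid) - 1:
        raise RuntimeError(
            "Bayes risk still decreasing at z_max; no interior minimum "
            f"bracketed. Grid tail: {list(zip(grid[-5:], br[-5:]))}"
        )
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda z: bayes_risk(z, cost, prior, sigma, marginalize),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def kick_log_ratio(
    t: float, prior: DriftPrior, sigma: float, z: float, tol: float = 1e-12
) -> float:
    """Core evidence log-ratio ``ln(I+ / I-)`` of a z+ hit at time t.

    ``I(s) = integral over drift magnitudes a of
    P(t | z+, s*a, sigma) * P(z+ | s*a, sigma) * p(a) da`` — the joint
    probability of the observed announcement (upper threshold, time t)
    under world state ``s`` in {+1, -1}, marginalized over the folded
    drift prior.  For a point-mass prior (sigma_A = 0) the integrals
    collapse to single evaluations at a = mu.
    """
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")

    def joint(a_signed: float) -> float:
        spec = DDMSpec(drift=a_signed, sigma=sigma, z_plus=z, z_minus=-z)
        return fpt_density(t, 1, spec, tol=tol) * hit_probability(spec)

    if prior.sigma == 0:
        num, den = joint(prior.mu), joint(-prior.mu)
    else:
        num, num_err = integrate.quad(
            lambda a: joint(a) * prior.pdf(a),
            0.0, prior.upper_support, epsrel=1e-8, limit=200,
        )
        den, den_err = integrate.quad(
            lambda a: joint(-a) * prior.pdf(a),
            0.0, prior.upper_support, epsrel=1e-8, limit=200,
        )
        if num <= 0 or den <= 0 or num_err > max(num, 1e-300) or den_err > max(den, 1e-300):
            raise RuntimeError(
                f"kick quadrature unreliable at t={t}: "
                f"num={num}±{num_err}, den={den}±{den_err}"
            )
    return float(np.log(num) - np.log(den))


def kick_size(
    t: float,
    option: int,
    prior: DriftPrior,
    sigma: float,
    z: float,
    p_plus: float = 0.5,
) -> float:
    """Signed evidence increment a neighbour's decision is worth.

    The neighbour announced ``option`` (±1, i.e. it hit z+ or z-) at
    decision time ``t``.  The returned value is the log-odds of the world
    state implied by that announcement, expressed in the receiver's signed
    evidence coordinates (positive = evidence toward S+), so it can be
    added directly to the receiver's accumulator:

    ``k = option * ln(I+ / I-) + ln(p+ / p-)``

    where the log-ratio marginalizes the unknown sender drift over the
    population prior.  Early decisions carry large |k| (fast crossings
    indicate high drift-to-noise ratio, hence reliable information); slow
    ones carry little.
    """
    if option not in (-1, 1):
        raise ValueError(f"option must be ±1, got {option}")
    r = kick_log_ratio(t, prior, sigma, z)
    return float(option * r + prior_log_odds(p_plus, 1))


def effective_threshold(z: float, sigma: float, dt: float) -> float:
    """Continuity-corrected threshold for Euler–Maruyama comparisons.

    A discretely observed diffusion overshoots an absorbing boundary by
    ``0.5826 * sigma * sqrt(dt)`` on average (the constant is
    ``-zeta(1/2)/sqrt(2*pi)``), so first-passage statistics of the
    discretized process match the *continuous* process with the boundary
    moved outward by that amount.  Used when validating the simulator
    against the analytic formulas.
    """
    return z + 0.5826 * sigma * math.sqrt(dt)


def simulate_ddm(
    spec: DDMSpec,
    dt: float,
    seed,
    kicks: list[tuple[float, float]] | None = None,
    max_time: float = 1e4,
) -> tuple[int, float]:
    """Euler–Maruyama path to first threshold crossing.

    ``y <- y + A dt + sigma sqrt(dt) xi`` each step; any scheduled
    ``(time, increment)`` kicks are added at the first step boundary at or
    after their time.  Crossing is evaluated only at step boundaries after
    drift, noise and kicks are summed.  Returns ``(decision ±1, time)``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    rng = np.random.default_rng(seed)
    pending = sorted(kicks or [], key=lambda p: p[0])
    y = 0.0
    t = 0.0
    sq = spec.sigma * math.sqrt(dt)
    ki = 0
    n_steps = int(math.ceil(max_time / dt))
    for _ in range(n_steps):
        t += dt
        y += spec.drift * dt + sq * rng.standard_normal()
        while ki < len(pending) and pending[ki][0] <= t:
            y += pending[ki][1]
            ki += 1
        if y >= spec.z_plus:
            return 1, t
        if y <= spec.z_minus:
            return -1, t
    raise TimeoutError(f"no threshold crossing before max_time={max_time}")


def simulate_ddm_batch(
    spec: DDMSpec,
    dt: float,
    n_paths: int,
    seed,
    max_time: float = 1e4,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Monte Carlo: decisions (±1) and decision times of n_paths paths.

    Paths that have not crossed by ``max_time`` get decision 0 and time nan.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    rng = np.random.default_rng(seed)
    y = np.zeros(n_paths)
    decided = np.zeros(n_paths, dtype=int)
    times = np.full(n_paths, np.nan)
    sq = spec.sigma * math.sqrt(dt)
    n_steps = int(math.ceil(max_time / dt))
    active = np.arange(n_paths)
    t = 0.0
    for _ in range(n_steps):
        t += dt
        y[active] += spec.drift * dt + sq * rng.standard_normal(active.size)
        ya = y[active]
        hit_up = ya >= spec.z_plus
        hit_dn = ya <= spec.z_minus
        hit = hit_up | hit_dn
        if hit.any():
            idx = active[hit]
            decided[idx] = np.where(hit_up[hit], 1, -1)
            times[idx] = t
            active = active[~hit]
            if active.size == 0:
                break
    return decided, times


def sample_drifts(prior: DriftPrior, true_state: int, n: int, seed) -> np.ndarray:
    """Signed drifts: |Normal(mu_A, sigma_A)| times the true state."""
    if true_state not in (-1, 1):
        raise ValueError(f"true_state must be ±1, got {true_state}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return true_state * np.abs(rng.normal(prior.mu, prior.sigma, size=n))
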
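# Methods

## Scope and assumptions

The package models a one-shot binary collective decision about a hidden
world state `S ∈ {S⁺ = +1, S⁻ = −1}` with symmetric classification
costs.  Agents are *naive Bayesian*: they apply the statistically
optimal update to the information they receive while neglecting the
correlations that network propagation induces (each received signal is
treated as independent, as if its sender were the first decider).  Two
interaction regimes are implemented, sharing the network layer but
differing in what agents integrate and when they communicate.

Communication graphs are static, undirected and unweighted.  The default
generator is the random geometric graph: `n` nodes uniform in the unit
square, an edge below Euclidean distance `δ`.  Experiments parameterize
connectivity by the mean degree `κ` instead of `δ`; the `δ(κ)` map is
found by bisection on the *empirical* mean degree (200 sampled
instances, tolerance ±0.5) because the boundary of the finite square
biases the `nπδ²` estimate.  Instances are rejection-sampled until
connected, with the rejection count reported.  Erdős–Rényi and
`k`-regular ring generators are provided behind the same interface for
robustness checks.

## Synchronous scenario

Opinions are initialized independently: agent `i` is correct with
probability `α_i`, with `α_i` drawn from `Normal(μ_α, σ_α)` flipped
about 0.5 (so heterogeneity raises mean accuracy — a folded
distribution) and clamped to `1 − 1e−6` to keep the log-odds confidence
`c_i = ln(α_i/(1−α_i))` finite.  The clamp matters only on a
measure-zero event of the sampler.

**Weighted Bayes Consensus** sums the closed neighbourhood's signed
evidence and adds the prior log-odds of the newly adopted opinion.  The
module carries an exact oracle, `direct_bayes_posterior`, that computes
the same posterior the long way (invert confidences to accuracies,
multiply per-vote likelihood terms, apply Bayes' rule) — the linear
shortcut is tested against it to 1e−10.  Numerical choices:

* `sign(0)` is undefined; an agent with exactly zero pooled evidence
  keeps its previous opinion (deterministic, minimal change).
* The prior term is re-added at every iteration, exactly as the update
  rule is defined; default experiments use a flat prior, which makes the
  double counting moot.
* Magnitudes grow exponentially (the update matrix `I + A` has spectral
  radius > 1 whenever an edge exists).  When `max_i |y_i|` exceeds 1e100
  all magnitudes are divided by it.  A uniform positive rescale commutes
  with the linear update, so every future sign — hence every opinion —
  is unchanged; the accumulated log-scale is recorded.  The test suite
  verifies sign-exactness against an arbitrary-precision rational
  replay of the recursion.

**Belief Consensus** is `y' = (I − εL) y`.  `ε` defaults to the uniform
safe value `1/(1 + max degree)`, which every agent can compute locally
and which keeps `I − εL` doubly stochastic; the full Metropolis–Hastings
matrix (`w_ij = 1/(1 + max(d_i, d_j))`) is available for the
destabilized variant `y' = (ε_d I + F) y`, whose dominant eigenpair
`(1 + ε_d, 1)` makes the growing mode carry the initial average.

A run iterates the configured rule to unanimity or `max_iterations`
(default 1000).  Timeouts are excluded from consensus-time statistics
and counted as non-unanimous for group accuracy, which is the
proportion of runs unanimous for the true state.  Both conventions are
exposed as flags since the choice is not forced by the problem.

## Asynchronous scenario

All agents start integrating at `t = 0` with signed drifts
`A_i = S · |Normal(μ_A, σ_A)|` — the folded draw is the population's
drift-magnitude prior, and no agent is systematically misinformed.
Thresholds are symmetric (`z⁻ = −z⁺`), equal across agents, and set by
minimizing the Bayes risk `ω_t E[T] + ω_e P(error)` using the closed
forms `E[T] = (z/Ã) tanh(Ãz/σ²)` and `P(error) = 1/(1 + e^{2Ãz/σ²})`,
marginalized over the drift prior by adaptive quadrature on
`(0, μ_A + 8σ_A]` (a point-drift mode is available behind a flag, since
whether the threshold-setting construction marginalizes is a genuinely
open choice).  The minimizer is a coarse grid followed by bounded 1-D
refinement; a minimum still descending at the search bound raises an
error with the grid profile.

The first-passage density through `z⁺` conditioned on hitting it first
is the image-charge series `θ(t, u, v)` (terms summed outward from
`k = 0` until two consecutive terms fall below 1e−12; the tail decays
super-exponentially), combined with the Girsanov drift tilt — evaluated
as `exp(−A²t/2σ²)·2cosh(Az/σ²)·θ`, which is the algebraically identical,
overflow-safe form of the conditional density.  Hit probability is the
logistic `1 − 1/(e^{2Az/σ²} + 1)`.  Asymmetric thresholds deliberately
have no analytic path (the printed formulas presume symmetry and all
experiments use equal world priors); requesting them raises an error
directing to the Monte Carlo simulator.

The kick integrals marginalize the joint announcement probability
(conditional FPT density × hit probability) over the folded drift prior
by adaptive quadrature (relative tolerance 1e−8, support truncated at
`μ_A + 8σ_A`); with `σ_A = 0` they collapse to the exact two-term
log-ratio, which the quadrature path reproduces to 1e−8.  The returned
kick is expressed in the receiver's signed-evidence coordinates
(`option · log-ratio + prior log-odds`), so mirrored options have equal
magnitude under a flat world prior.

The collective simulator advances in steps of `dt` (default 0.01; the
step size is an exposed parameter, and the single-agent validation runs
at `dt = 1e−3`): undecided agents take an Euler–Maruyama step, kicks
broadcast on the previous step are delivered to still-undecided
neighbours, and crossings are then evaluated — so kick delivery has a
one-step latency, avoiding order dependence within a step, and decided
agents are frozen and receive nothing.  A decision is attributed to a
kick when the pre-kick evidence had not crossed; among several same-step
kicks the largest contribution in the crossing direction wins (ties:
earlier sender decision, then lower index).  Cascades are the causal
trees rooted at spontaneous decisions; a cascade's size includes its
trigger, and the reporting threshold defaults to `⌈N/10⌉`.  The horizon
defaults to 10× the asocial mean decision time at `μ_A`; agents
undecided at the horizon are recorded, and charged `ω_t ×` horizon in
the realized-cost statistic (flag-controlled, as the convention is not
forced).

## Monte Carlo validation and the continuity correction

The Euler–Maruyama simulator doubles as the module's independent
oracle.  A discretely observed diffusion systematically overshoots an
absorbing boundary; to first order the discrete process behaves like the
continuous one with the boundary moved outward by `0.5826·σ·√dt`
(the constant is `−ζ(1/2)/√(2π)`).  At `dt = 1e−3` this shifts mean
decision times by more than the Monte Carlo error of 10⁴ paths, so all
simulator-vs-analytic comparisons evaluate the analytic formulas at the
corrected threshold (`effective_threshold`).  Hit *probabilities* are
insensitive to the correction at these parameters and pass either way.

## Synthetic data and what the tests show

Every input is generated in-package: topologies, accuracies, drifts and
noise paths, under the stated defaults (`N = 50`, `κ = 10`,
`μ_α = 0.5`, `μ_A = 0.2`, `σ = 1`, `ω_e = 100`, `ω_t = 1`, flat world
prior).  The generators emulate idealized study conditions — static
connected graphs, exactly known accuracy/drift distributions, perfectly
synchronized clocks and loss-free one-shot communication.  They do not
emulate sensory correlations between nearby agents, communication noise
or delay heterogeneity, time-varying topologies, or individuals whose
drift sign opposes the true state.  Passing tests therefore establish
the internal consistency of the algorithms and the direction of the
qualitative effects under these conditions, not quantitative predictions
for any real animal group.

End-to-end checks run at reduced replication (100 runs or paired seeds
per condition versus 500–1000 in a full study); the effect sizes
involved (paired accuracy differences, rank correlations near −0.6)
are large enough that 3-standard-error margins remain decisive at that
scale.  One caveat is intrinsic: bottom-quartile agents trigger very
few cascades in heterogeneous groups — that scarcity *is* the
leadership effect — so the top-vs-bottom quartile comparison of mean
cascade sizes is checked directionally with a 3-SE noise allowance
rather than as a significance claim.

## Known limitations

* Analytic first-passage machinery covers symmetric thresholds only;
  asymmetric setups fall back to simulation.
* The kick quadrature is memoized per decision time but still the
  costliest inner operation for large heterogeneous groups.
* Belief Consensus consensus *time* depends on the spectral gap of the
  instance graph; on barely connected geometric graphs convergence to
  the mean can be slow, and sign-unanimity (the stopping rule) can occur
  well before numerical convergence.
* The experiments layer sweeps one parameter at a time; factorial
  designs are composed by the caller.
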
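# cascade-consensus

Simulation and analysis of collective two-choice decisions on
communication networks, for researchers in collective animal behaviour,
decision neuroscience and distributed decision-making.  The package asks
when information cascades help or hurt a group of naive-Bayesian
decision-makers, and shows that the answer hinges on *timing*:
synchronous confidence pooling is an unstable linear system prone to
erroneous runaways, while asynchronous decision-making lets the
best-informed individuals decide early and pull the group toward the
correct answer.

## The models

**Synchronous signal detection.** `N` agents hold opinions
`x_i ∈ {−1, +1}` about a hidden binary world state `S` and log-odds
confidences `c_i = ln(α_i / (1 − α_i))` derived from their accuracies
`α_i`.  Each iteration every agent pools its neighbourhood's
confidence-weighted votes.  The locally Bayes-optimal rule under
correlation neglect (**Weighted Bayes Consensus, WBC**) is linear in the
signed evidence `y_i = x_i c_i`:

    x_i' = sign( y_i + Σ_{j∈M_i} y_j )
    c_i' = | y_i + Σ_{j∈M_i} y_j + π(x_i') |,    π = log prior ratio

i.e. `y' = (I + A) y` with `A` the adjacency matrix — spectral radius
above 1 on any graph with an edge, and a dominant eigenvector that is
*not* the ones vector on irregular graphs, so the runaway mode need not
carry the population average.  The baseline (**Belief Consensus, BC**)
replaces summation by distributed averaging, `y' = (I − εL) y` with
`I − εL` doubly stochastic (Metropolis–Hastings weights or the uniform
safe `ε = 1/(1 + max degree)`), which provably converges to the mean of
the initial signed evidence — the globally optimal pooled statistic.

**Asynchronous sequential sampling.** Each agent is a drift-diffusion
accumulator `dy_i = A_i dt + σ dW` that decides when `y_i` first reaches
`±z`; the threshold minimizes the Bayes risk
`ω_t E[T] + ω_e P(error)` marginalized over the population's drift prior
`|Normal(μ_A, σ_A)|`.  A decision is broadcast once; an undecided
neighbour receiving it at time `t` adds the evidence "kick"

    k = ln [ ∫ P(t|z⁺,+Ã) P(z⁺|+Ã) p(Ã) dÃ / ∫ P(t|z⁺,−Ã) P(z⁺|−Ã) p(Ã) dÃ ] + log prior ratio

— the exact log-odds the announcement is worth given that fast
crossings indicate high drift-to-noise ratio.  First-passage densities
use the classical image-charge series; hit probabilities the logistic
closed form.  Chains of kick-caused decisions are detected as cascades
and attributed to their triggering agent.

## Worked example

`python examples/asynchronous_cascades.py` simulates 30 groups of 50
coupled accumulators on sparse geometric networks (mean degree 10,
drift magnitudes `|N(0.2, 0.5)|`, noise 1, costs `ω_e = 100`,
`ω_t = 1`) and prints:

```
Bayes-risk-optimal threshold: z = 3.348
mean fraction of agents deciding correctly: 0.967
cascades (>= 5 decisions) observed: 32
cascade triggers that decided correctly: 31/32
Spearman(drift rank, #triggered cascades): rho = -0.49 (p = 0.0003)
```

The threshold is the Bayes-risk minimizer for these costs; 96.7% of all
agents choose the true state; nearly every cascade is triggered by a
*correct* early decider; and the negative Spearman correlation says the
cascade triggers are predominantly the highest-drift (best informed)
agents — early decisions rescue the group rather than mislead it.  The
other examples show the synchronous speed/accuracy trade-off
(`synchronous_consensus.py`), the kick-size calibration curve
(`kick_calibration.py`) and the stability spectra
(`network_spectra.py`).

A thin CLI wraps the sweep drivers:

```
cascade-consensus signal-detection --sigma-alpha 0.1 --sigma-alpha 0.3 \
    --replicates 100 --seed 1 --out results/sd
cascade-consensus sequential --sigma-drift 0.5 --replicates 50 --seed 1 \
    --out results/seq
```

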
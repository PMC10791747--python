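# triguild

Simulator for **adaptive three-guild ecological networks**: plants coupled
to pollinators by a mutualistic bipartite sub-network and to herbivores by
an antagonistic one, with within-guild competition, where animals
adaptively rewire their plant partners to increase their own equilibrium
biomass. The package is aimed at theoretical/community ecologists studying
how adaptive foraging shapes the structure (nestedness, modularity,
degree-centrality correlations) and stability (resilience) of multiplex
networks.

## The model in brief

Species niches are Gaussian profiles of breadth σ centred at positions
s̄ ∈ [0, 1]; the interaction coefficient of a pair is the overlap ratio
α_ij = exp(−(s̄_i − s̄_j)² / 4σ²). Competition, mutualism and herbivory
rates are β_ij = Ω_c α_ij (β_ii = 1), γ_ij = Ω_m θ_ij α_ij and
τ_ij = Ω_p θ_ij α_ij, with θ the random binary incidences at connectance
C. Biomasses follow a Lotka–Volterra system with type II functional
responses (half-saturation h, conversion efficiency ε):

dP_i/dt = P_i ( r − Σ_j β_ij P_j + Σ_j γ_ij M_j / (1 + h Σ_{k∈mut(P_i)} M_k)
                − Σ_j τ_ij H_j / (1 + h Σ_{k∈ant(H_j)} P_k) )

and analogously for pollinators M and herbivores H. At equilibrium,
resilience is |max Re λ| of the analytic Jacobian (defined only when
locally stable). Rewiring: a random animal abandons plant j with
probability 1 − ψ_j⁻¹ (ψ_j = j's partner count in the animal's guild),
attaches to a random unlinked plant, and the switch is kept only if the
animal's equilibrium biomass strictly increases. Structure is quantified
by NODF nestedness and Barber bipartite modularity, standardised against
equiprobable or degree-probabilistic null ensembles with one-tailed
z-tests (threshold 1.645).

See `docs/methods.md` for the full equations, parameter table, and
numerical choices.

## Worked example

```python
import numpy as np
from triguild import (ModelParams, generate_community, CommunityState,
                      integrate_to_equilibrium, run_rewiring,
                      plant_stats, correlation_suite)

params = ModelParams(omega_c=0.02, omega_p=0.175, omega_m=0.175)
mats = generate_community(params, S_P=30, S_M=30, S_H=30, seed=1)
eq = integrate_to_equilibrium(CommunityState.uniform(mats), mats, params)
print(eq.locally_stable, round(eq.resilience, 3))
corr = correlation_suite(plant_stats(mats, eq, params))
print(round(corr["spearman_dd"], 3), round(corr["r2_db"], 3))

traj = run_rewiring(mats, params, n_attempts=2000, seed=2)
corr_ad = correlation_suite(
    plant_stats(traj.final_mats, traj.final_eq, params))
print(traj.n_accepted, round(corr_ad["spearman_dd"], 3))
```

prints

```
True 0.494
0.034 0.323
325 0.175
```

The random (pre-rewiring) network is locally stable with resilience 0.494
(recovery rate after a small perturbation); across its plants the
Spearman correlation between mutualistic and antagonistic degree
centrality is ≈ 0.03 — plants popular with pollinators are not
particularly popular with herbivores — and the energy-budget difference
is moderately predicted by the degree difference (r² ≈ 0.32). After 2000
rewiring attempts (325 accepted, each strictly raising the focal animal's
equilibrium biomass) the degree-centrality correlation has risen to
≈ 0.18, and it keeps rising as rewiring continues — adaptive rewiring
makes plant generalism coherent across the two sub-networks.

A command-line interface mirrors the library
(`triguild generate|equilibrate|rewire|metrics|sweep|lhs`, each with
`--seed`, `--out-dir` and `--config`).

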
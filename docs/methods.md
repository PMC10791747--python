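# Methods

## The model

`triguild` simulates a three-guild ecological network: `S_P` plant species
linked to `S_M` pollinators through a mutualistic bipartite sub-network and
to `S_H` herbivores through an antagonistic one, with the plant guild
shared between the two. Species within a guild also compete.

**Niche-based interaction strengths.** Every species has a Gaussian niche
profile of breadth `sigma` centred at a position drawn uniformly on the
axis `[0, 1]`. The interaction coefficient between species *i* and *j* is
the interspecific-to-conspecific overlap ratio

    alpha_ij = exp(-(s_i - s_j)^2 / (4 sigma^2)),

symmetric, in `(0, 1]`, strictly decreasing in niche distance and
increasing in breadth. Three scalars convert overlap into per-capita
rates: within-guild competition `beta_ij = Omega_c * alpha_ij` (off the
diagonal; `beta_ii = 1` exactly), mutualism `gamma_ij = Omega_m * theta_ij
* alpha_ij`, herbivory `tau_ij = Omega_p * theta_ij * alpha_ij`. The
binary incidences `theta` are independent Bernoulli draws at connectance
`C_mut` / `C_ant`. The Gaussian profile formally extends beyond `[0, 1]`;
we use the closed-form `alpha` over the whole real line and do not
truncate at the boundaries, so `alpha` near the axis ends is exactly the
closed form, not a renormalised version.

**Dynamics.** Biomasses follow a Lotka-Volterra system with type II
(saturating) cross-guild functional responses sharing one half-saturation
constant `h` (see the `dynamics` module docstring for the exact
equations). One asymmetry deserves emphasis: the herbivory loss of plant
*i* sums over herbivores *j* terms saturating in the plant partners *of
herbivore j* — each herbivore divides its intake among its own plants —
whereas the mutualistic gain saturates in plant *i*'s own pollinator set.
The literal form is implemented; the alternative reading (saturation over
the plant's own herbivore set) is deliberately not.

**Stability.** At an equilibrium the community Jacobian is evaluated
analytically (including the quotient-rule cross terms the type II
denominators induce between plants sharing a herbivore). The system is
locally stable when all eigenvalues have negative real part; resilience —
the asymptotic recovery rate from a small perturbation — is
`|max Re(lambda)|`, and is reported only for locally stable equilibria.

**Adaptive rewiring.** After the community settles into equilibrium, an
animal drawn uniformly from the pooled pollinators and herbivores
considers dropping one of its plant partners *j*, drawn uniformly; the
detachment fires with probability `1 - 1/psi_j`, where `psi_j` is plant
*j*'s partner count within the focal animal's guild (specialist plants
are never abandoned). A replacement plant is drawn uniformly from the
unlinked ones, the new link strength follows from niche overlap, and the
system is re-equilibrated from the previous equilibrium (warm start) in
chunks of 50 time units. The switch is kept only if the focal animal's
equilibrium biomass strictly increased; otherwise every matrix entry and
the biomass state are restored bit-exactly. Link counts of both
sub-networks and species richness are therefore invariant over a run.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `Omega_c` | competition strength at perfect overlap | 0.1 (sweep: 0.01-0.1) |
| `Omega_m` | mutualism strength at perfect overlap | 0.1 (sweep: 0.035-0.35) |
| `Omega_p` | herbivory strength at perfect overlap | 0.1 (sweep: 0.035-0.35) |
| `r_P, r_M, r_H` | per-capita intrinsic growth rates (1/time) | 1 |
| `h` | half-saturation constant of the type II responses | 0.1 |
| `eps` | predation conversion efficiency | 0.8 |
| `C_mut, C_ant` | sub-network connectances | 0.15 |
| `sigma` | niche breadth (niche-axis units) | 0.1 |
| `S_P, S_M, S_H` | guild sizes | 30 |

The reference experiment runs 1e5 rewiring attempts per community,
samples structure metrics over the last 1e4 attempts, replicates each
interaction-strength combination 60 times, and spans a ternary simplex of
55 `(Omega_c, Omega_p, Omega_m)` combinations (integer compositions
a+b+c=9 mapped through the two step sizes — the unique grid consistent
with the stated per-parameter ranges and steps and a 55-point layout).

## Numerical choices

- **Integrator**: LSODA (stiff-capable, via `scipy.integrate.odeint`) with
  the analytic Jacobian supplied; relative/absolute tolerances 1e-8/1e-10.
  Strong mutualism at high connectance makes the system stiff.
- **Equilibrium criterion**: integration proceeds in chunks of 50 time
  units until `|dX_i/dt| < tol (1 + |X_i|)` for every species, with
  `tol = 1e-8`, capped at 5000 time units (20 chunks of 50 inside the
  rewiring loop). Initial conditions are all-ones for the first
  equilibration; subsequent equilibrations warm-start.
- **Biomass floor**: 1e-9, applied after each chunk to species that
  entered the call positive; exact zeros are absorbing. Species are
  clamped, never removed, so community dimensions stay fixed; floored
  species are counted as near-extinctions. The Jacobian is evaluated at
  the floored state with all rows retained.
- **Acceptance rule**: strict `>` on the focal biomass, no tolerance band
  (a configurable epsilon exists for noise-robustness studies, default 0).
  A proposal whose re-equilibration fails or does not converge within the
  chunk cap is rejected and the previous state restored; such events are
  counted separately from ordinary rejections.
- **Attempt accounting**: every proposal draw counts as an attempt,
  including untriggered detachments and animals with no free plant, giving
  a well-defined denominator; acceptance rates are reported against both
  attempts and actionable proposals.
- **Modularity optimiser**: Barber's bipartite Q maximised by alternating
  one-sided optimal label updates (BRIM) from random restarts (default
  20), with greedy module merging between rounds; the single-module
  baseline Q=0 bounds the result from below. On all matrices up to 3x3
  and sampled 4x4s the heuristic attains the exhaustive-search optimum.
- **NODF**: strict decreasing-fill convention (equal marginal totals
  contribute zero), 0-100 scale, computed on the binary incidences only.
- **Null models**: equiprobable (Bernoulli at realised connectance,
  the default, chosen for determinism of its expectations) and
  degree-probabilistic (cell probability `(k_i/n_cols + d_j/n_rows)/2`);
  1000 replicates by default; all-zero draws are redrawn and counted.
  One-tailed z-test, significant strictly above 1.645.
- **RNG discipline**: one root `SeedSequence` per run spawns documented
  child streams (positions x3, incidences x2, rewiring, null models);
  sweep replicates are seeded by `(base_seed, design index, replicate
  index)`, so parallel and serial execution give byte-identical results.

## Design choices where the procedure was open

- **Incidence draws** are per-cell Bernoulli rather than exact-fill (an
  exact-fill mode exists); rewiring conserves whatever link count was
  realised. Every animal row is redrawn into having at least one link,
  because a partnerless animal could never rewire and would stay
  disconnected forever.
- **Detachment partner** is drawn uniformly among the animal's current
  partners before the Bernoulli trigger; scanning all partners instead is
  a plausible alternative that is not implemented.
- **A rejected attempt advances no model time**; the pre-proposal
  equilibrium is restored as-is.
- **Stationarity** of biomass and structure over a rewiring run is
  assessed from fixed-length runs (snapshots and structure samples over
  the trailing window); no automatic stationarity stop rule is applied —
  `n_attempts` is always honoured exactly.
- **Fixed-strength line scans** accept arbitrary `Omega` values off the
  0.035 grid (the three antagonism levels used in the scan experiments,
  0.05/0.15/0.25, are themselves off-grid).
- **Complexity covariates** `log(S C)` use the natural logarithm.
- **Latin hypercube sensitivity** spans ±30% boxes around the baseline in
  6 dimensions (guild size applied to all guilds, connectance to both
  sub-networks, growth rate to all guilds, `h`, `eps`, `sigma`), 10
  samples, each stratum used exactly once per dimension; guild sizes are
  rounded to integers ≥ 2 and `eps` is capped at 1.

## What the generator emulates — and what it does not

Synthetic communities capture the niche structure (distance-decaying
interaction strengths), random partner assignment at fixed connectance,
and the guild architecture of real plant-pollinator-herbivore systems.
They do not capture phylogenetic signal in niches, trait evolution,
spatial structure, empirically observed degree distributions, or
environmental stochasticity — dynamics are fully deterministic. Passing
tests therefore certify the model's internal behaviour (convergence,
conservation laws, metric correctness, direction of the
strength-stability trends), not quantitative agreement with any empirical
community.

## Problem sizes used by the test suite

The reference experiments (30 species per guild, 1e5 attempts, 60
replicates, 1000-replicate nulls) are long runs. The test suite exercises
the identical code paths at desk scale: strength-stability trend checks
use 10 species per guild at connectance 0.3 with 2000 rewiring attempts
and 6 replicates per strength combination (20 in the focal cell used for
the degree-correlation and biomass-gain checks); the random-network
correlation statistics use 30 replicate communities at full 30/30/30
size (equilibration only); the structural z-score check runs two
replicates at full network dimensions (30/30/30, connectance 0.15) with
6000 rewiring attempts and 100-replicate null ensembles.
`scripts/acceptance.py` runs the full-size random-network statistics
over 30 seeded replicates.

## Known limitations

- Resilience is undefined (reported as missing) at unstable equilibria;
  replicates whose *initial* random network is unstable are redrawn with
  the next child seed and counted.
- The equilibrium reached can depend on initial conditions in principle;
  the all-ones start plus warm-started rewiring defines one reproducible
  trajectory through state space, not a global attractor analysis.
- The modularity heuristic is exact on small matrices but carries no
  optimality guarantee at 30x30; restarts trade time for quality.
- Structure metrics are computed on binary incidences; weighted
  nestedness/modularity variants are out of scope.
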
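# Methods

## Model

`popsplit` embeds population divergence into the structured coalescent as
a per-lineage event process. The state of a lineage (backward in time) is
its population label. Three event types compete on every time interval:

* **Coalescence** within population *i*: total rate kᵢ(kᵢ−1)/Θᵢ, the
  Kingman rate in mutation-scaled units (Θ = 4Nₑμ for diploids; one unit
  of time = one expected substitution per site).
* **Immigration** (label switch along a declared migration edge j→i):
  rate Mⱼᵢ = mⱼᵢ/μ per lineage currently labelled *i*.
* **Divergence** (irreversible switch from a derived label to its
  ancestral label): per-lineage hazard of a normal distribution with mean
  τ, standard deviation σ, truncated to [0, b₁],

      λ_d(t) = φ((t−τ)/σ) / (σ · S(t)),      S(t) = P[t ≤ X ≤ b₁],

  so the risk of having "already joined the ancestor" grows with depth.
  The lower truncation bound cancels from the hazard; only b₁ appears.
  b₁ defaults to +∞; when a prior with an upper bound is placed on τ that
  bound is a natural choice for b₁.

τ and σ are parameters of the inference, giving the split a mean time
*and* a width. σ → 0 recovers the classic sharp-boundary
isolation(-with-migration) model. The connection structure is an
adjacency matrix, not a species tree: any population may be
ancestral-and-present, and several derived populations may share an
ancestor without an ordering constraint.

### Genealogy density

A genealogy G is an ultrametric binary tree augmented with time-stamped
migration and divergence events on branches. Its density f(G|ρ) is a
product over the time slices bounded by every tip, event and coalescence:
each slice contributes

    exp( −u·(Σᵢ kᵢ(kᵢ−1)/Θᵢ + Σᵢⱼ kᵢMⱼᵢ) − Σ_edges k_der·Λ_d(t₀,t₀+u) )

(Λ_d the cumulative hazard, evaluated in closed form) times the rate of
the event ending the slice: 2/Θᵢ for the observed coalescing pair, Mⱼᵢ
for a migration, and the switching lineage's own hazard λ_d(t) for a
divergence. Because the genealogy records *which* lineage switched, the
event factor is the per-lineage hazard while the number of at-risk
lineages multiplies the exponent; this is the labelled-genealogy
normalisation, verified by the density-integrates-to-one and
sampler-vs-direct-simulation tests. All accumulation is in log space —
thousand-locus products would underflow otherwise.

### Event-ordering probabilities

The probability that a divergence precedes all coalescence and migration
in an interval is ξ_d = ∫ e^(−u·λ_c+m) λ_d(t₀+u) e^(−Λ_d(t₀,t₀+u)) du
(the survival factor is the decaying exponential of the cumulative
hazard). It has no closed form; the package evaluates it by adaptive
quadrature (absolute tolerance 1e−10, integration window to
min(b₁, τ+10σ) plus an analytic exponential tail bound) and by the
midpoint approximation ξ_d ≈ λ_d(t₀+ε)/(λ_c+m + λ_d(t₀+ε)), where all
clocks are frozen at a representative point t₀+ε. For interval
evaluation on a fixed genealogy, ε is the interval length itself; for
prospective comparisons the package uses the one-step estimate
ε = 1/(λ_c+m + λ_d(t₀)). Across sweeps of Θ, M and τ the two forms agree
to ≤0.15 absolute and are co-monotone (tolerance frozen from the
quadrature oracle).

Neither quantity is needed for simulation or MCMC: both use **competing
draws** — a waiting time proposed independently for each possible event
(exponential inversion for the constant rates, survival inversion
u: exp(−Λ_d(t₀,t₀+u)) = 1−r for the hazard), with the earliest event
applied. This produces events at exactly the ξ frequencies (verified by a
χ² test against the quadrature values).

## Inference

The posterior p(ρ|D) ∝ p(ρ) Π_loci ∫ f(G|ρ) p(D|G) dG is sampled by
Metropolis–Hastings over the joint space of parameters and per-locus
genealogies. p(D|G) is Felsenstein pruning under F84 (stationary
frequencies + transition boost κ; rate matrix normalised to one expected
substitution per unit time; ambiguity codes and gaps become uniform
partials; site patterns compressed once per locus). Loci are independent
and combine by summing logs.

Move classes, chosen at random each iteration:

1. **Path re-simulation** (the main topology move): the branch above one
   random non-root node is detached and its event path re-simulated
   against the fixed remainder by competing draws until it re-coalesces.
   Above the background root the remaining root lineage becomes active
   too and the pair is simulated jointly to a new root. The Hastings
   ratio uses the exact forward/reverse path densities against the same
   background; the state never stores events above the current root, and
   the sibling's former root-adjacent events are part of the resampled
   object, which keeps the move exactly reversible.
2. **Node slide / event slide**: one coalescence time or one event time
   is redrawn uniformly within its local window (symmetric). Event
   slides skip the pruning recomputation entirely, since label switches
   do not touch the substitution process.
3. **Parameter moves**: sliding windows reflected at the prior bounds,
   widths tuned during burn-in toward 20–40% acceptance. For the
   divergence mean, half of the proposals are **joint translations** that
   shift τ together with every switch time of that edge (unit Jacobian):
   with a tight σ the switch times are rigidly coupled to τ, and without
   this move the τ chain is essentially frozen.

Single chain, single temperature. Correctness was established by (a)
prior recovery: with the data term removed, the sampled marginals of all
parameters reproduce their priors, which exercises the full Hastings
machinery including the genealogy integration; (b) fixed-parameter
genealogy sampling matching direct simulation from the model
(Kolmogorov–Smirnov on TMRCA); (c) a two-tip posterior matching 1-D grid
quadrature.

Starting state: parameters drawn from their priors; per-locus genealogies
from UPGMA on Jukes–Cantor distances, followed by a label-repair pass
that inserts the divergence (or migration) events needed to make every
coalescence join identically labelled lineages.

### Priors and summaries

Priors are uniform or upper-bounded exponential per parameter. Defaults:
uniform(1e−6, 0.1) for Θ, uniform(0, 1000) for M, an exponential for τ
bounded ~3× beyond the oldest divergence under consideration (mean a
third of the bound), and a deliberately small uniform range for σ — a
wide σ prior lets the spread absorb the divergence signal and, with
migration, interacts with the immigration-rate estimate.

Posteriors are summarised by histograms over the prior support (1,500
bins by default); the point estimate is the midpoint of the highest bin
after a 3-bin moving average, percentiles are empirical, and spread is
reported as the **standardized credibility width** (p97.5 − p2.5)/mode.
Note this statistic diverges as the mode approaches zero, so comparisons
across designs should use truths whose posterior mode is well away from
zero. An autocorrelation-based effective sample size accompanies every
summary; non-convergence shows up as a small ESS rather than failing
silently.

## Units

Internally every time and rate is mutation-scaled. Figure conventions in
the divergence literature vary; the helpers in `popsplit.units` convert:
x Nₑ generations ↔ x·Θ/4, and x coalescent units of 4Nₑ generations ↔
x·Θ, with the reference Θ (per-deme or combined) stated explicitly by the
caller. For the lineage-survival experiment the package reads the
published time axis in units of 4N_deme generations (τ_mut = x·Θ_deme);
this is the only reading consistent with the reported <20% survival at
the "4Nₑ generations" grid point (cross-checked against msprime), and
both conventions remain available.

## Synthetic data

The simulator is the generative counterpart of the inference model:
backward-in-time competing draws with either **per-lineage hazard**
switching (the inference model; default) or a **shared epoch** — one
zero-truncated normal draw per dataset and a hard split, the convention
of classic divergence simulators. The two differ subtly: with a large σ
the shared-epoch mode redraws negative epochs, so about Φ(−1) ≈ 15.8% of
raw draws fall below τ−σ and accepted epochs are biased old. Sequences
evolve under F84 from stationary root states; defaults are equal base
frequencies and κ = 1.5 (transition/transversion ratio 2), values the
simulations do not otherwise pin down. One integer seed spawns
independent per-locus streams.

What the generator does *not* emulate: recombination within loci,
rate variation across sites, indels/sequencing error, serially sampled
(ancient) tips, and selection. Passing tests therefore demonstrate
correctness of the method under its own assumptions, not robustness of
divergence-time estimation to their violation.

## Study conditions and problem sizes

The packaged experiments run at desk scale, chosen to finish in about a
minute each on one CPU: parameter recovery uses 20+20 samples, 10 loci ×
1,000 bp (2 loci for the width comparison), τ ∈ {0.125, 0.5, 1.0} Nₑ
generations with combined Θ = 0.02, simulation σ = τ/100, and chains of
60,000 steps (burn-in 15,000, thinning 20). The lineage-survival
experiment uses 1,000 replicates per time point. Larger designs (hundreds
of replicate datasets, 1,000-locus runs) are straightforward scale-ups of
the same calls.

## Numerical choices

* Hazard, cumulative hazard and survival inversion work through
  log-space complementary normal tails (`log_ndtr`, `ndtri_exp`): naive
  erf differences cancel catastrophically for t ≫ τ, while the log-space
  forms stay finite to τ + 8σ and beyond.
* The cumulative hazard's closed form (a log-ratio of upper-tail masses)
  agrees with direct quadrature of the hazard to ≤1e−8 relative error
  (property-tested over a parameter grid); hazard inversion round-trips
  to ≤1e−8.
* Degenerate inputs: σ → 0 concentrates switching at τ (the sampler and
  density both handle σ ~ 1e−7·τ); u = 0 intervals contribute only their
  event factor; a migration event with M = 0, or any event illegal in its
  interval state, scores −∞.
* The quadrature for ξ reports non-convergence with the achieved
  tolerance instead of returning a silent value.

## Limitations

* Marginal likelihoods / Bayes factors for comparing population-model
  hypotheses are out of scope; alternative connection matrices must be
  run as separate analyses.
* Single-temperature MCMC: multimodal posteriors (very wide σ priors
  with migration) may need longer chains than the defaults.
* F84 only; no site-rate heterogeneity, no tip dating, no VCF ingestion.
* The survival experiment's count-based fast path assumes migration and
  coalescence only below the split (exact for that design; verified
  against the full event simulator).
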
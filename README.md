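# popsplit

Bayesian estimation of population divergence times by **lineage label
switching** in the structured coalescent.

## The problem

Dating the split of two populations from multi-locus sequence data is
usually done by treating the divergence time τ as a hard boundary: below
τ, a structured coalescent with migration; above it, one panmictic
ancestral population. `popsplit` instead treats the split as a *random
variable carried by individual lineages*: looking backward in time, every
sampled lineage in a derived population is at risk of irreversibly
switching its label to the ancestral population, with switching times
drawn from the hazard of a zero-truncated normal distribution with mean τ
and standard deviation σ. Divergence becomes a third event type alongside
coalescence and migration, and τ and σ are estimated like any other
coalescent parameter — no guide tree, and several derived populations may
share one ancestor.

## The model

All rates are mutation-scaled (Θ = 4Nₑμ; times in expected substitutions
per site). Over a genealogy interval with kᵢ lineages in population i:

* coalescence in i at rate kᵢ(kᵢ−1)/Θᵢ,
* immigration into i from j at rate kᵢ·Mⱼᵢ (M = m/μ),
* a label switch on each derived lineage at the truncated-normal hazard
  λ_d(t) = φ((t−τ)/σ) / (σ·S(t)), S(t) the upper-tail mass on [t, b₁].

The genealogy density f(G|ρ) is a product over time slices of the
survival of all three risks times the terminating event's rate; the
sequence likelihood p(D|G) is Felsenstein pruning under the F84 mutation
model; posteriors for Θ, M, τ, σ come from Metropolis–Hastings sampling
that alternates parameter moves with genealogy moves (detach one lineage,
re-simulate its path by competing draws — inverse-transform sampling for
the divergence hazard — and re-attach). The probability that a divergence
is the first event in an interval, ξ_d, is available both as an exact
integral and as the fast rate-ratio approximation
λ_d(t₀+ε)/(λ_c+m + λ_d(t₀+ε)).

## Worked example

`examples/05_infer_divergence_time.py` simulates 4 loci × 1000 bp for two
populations of Θ = 0.01 each, with pop2 splitting off pop1 at τ = 0.002,
and infers the parameters back (≈20 s):

```
parameter             mode      2.5%     97.5%  std width
theta_pop1         0.01110   0.00852   0.01785      0.840
theta_pop2         0.00863   0.00591   0.01551      1.112
tau_pop2_pop1      0.00214   0.00160   0.00330      0.797
sigma_pop2_pop1    0.00010   0.00008   0.00050      4.153

simulated truth: theta = 0.01, tau = 0.002
```

The posterior mode of τ (0.00214) and both Θ's bracket the simulated
truth; `std width` is the standardized credibility width
(p97.5 − p2.5)/mode used to summarise posterior spread — it shrinks as
loci are added. The other examples cover the hazard math (`01`), dataset
simulation (`02`), the genealogy density (`03`), and the loss of signal
about old splits under migration (`04`).

A thin command-line interface wraps the same calls:

```bash
popsplit simulate -c run.cfg -o data/       # write PHYLIP + event-newick
popsplit infer    -c run.cfg -d data/ -o out/   # posterior TSVs + log
popsplit survival --fournm 1.0 --tau-grid 1,2,4,8
popsplit selftest                           # fast invariant checks
```

The config format (populations, sample counts, a migration/divergence
adjacency matrix, priors, chain settings) is described in
`popsplit/io.py`; population indices are 1-based in files.

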
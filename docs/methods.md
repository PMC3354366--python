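# Methods

## The model

`phenonet` implements causal-structure search among quantitative traits in
pedigreed populations. Phenotypes of animal *i* on *t* traits follow a
recursive structural equation model (SEM) embedded in the quantitative-
genetics mixed model:

```
y_i = Λ y_i + β[season_i] + u_i + e_i,
u ~ N(0, G0 ⊗ A),      e_i ~ iid N(0, Ψ0),  Ψ0 diagonal
```

`Λ` is a t×t matrix of structural coefficients (row = affected trait),
zero except where the causal structure puts an edge; `A` is the numerator
relationship matrix built from the pedigree; `G0` the additive genetic
covariance; `Ψ0` the structural residual variances. The diagonal `Ψ0`
encodes causal sufficiency: traits share no residual covariance except
through `Λ` and genetics. Solving for `y_i` gives the reduced model with

```
R0* = (I−Λ)⁻¹ Ψ0 (I−Λ)⁻ᵀ,      G0* = (I−Λ)⁻¹ G0 (I−Λ)⁻ᵀ
```

`R0*` is the residual covariance of the phenotypes *conditional on the
genetic effects* — the multiple-trait animal model (MTAM) residual
covariance. Because every positive-definite `R0` LDL-factorizes under a
fixed trait order, a *fully recursive* SEM (all lower-triangular `Λ`
entries free) is likelihood-equivalent to the MTAM; fitting it yields
posterior draws of `R0*`.

## Why condition on genetic effects

Genetic covariances between traits confound phenotype-level independence
queries: two causally unconnected traits look dependent whenever their
genetic effects are correlated. d-separations in the trait causal graph
are mirrored as null partial correlations only in the distribution of
`y | u`, i.e. in `R0*`. The search therefore operates on posterior
samples of `R0*`, never on raw phenotypic covariances.

## The search

For each trait pair (j, j′) and each conditioning set S (all subsets,
exhaustive — at t = 5 there are at most 8 per pair), the residual partial
correlation ρ_{j,j′|S} is computed per posterior draw of `R0*` through
precision-submatrix inversion, giving a posterior sample of the partial
correlation. The highest-posterior-density (HPD) interval at a chosen
content is the shortest contiguous window over the sorted draws (ties go
to the lowest start); the correlation is declared null iff the interval
contains zero (endpoints count; an absolute 1e-12 guard absorbs floating-
point residue in degenerate cases). Skeleton, unshielded-collider
discovery and Meek-rule propagation (R1–R4) then follow the Inductive
Causation scheme; a Dor–Tarsi sink-elimination check reports whether a
partially oriented result admits any consistent DAG extension.

When the search runs at several HPD contents (default 70–95%), the
partial-correlation samples are shared and the intervals for the content
list are *nested by construction* — each higher-content interval is the
shortest window containing the lower one. The raw shortest-window
estimator does not guarantee nesting for multimodal samples, and nesting
is what makes the null verdict monotone in the content (edges can only be
pruned, never gained, as the content rises). Edges present at every
content are flagged most stable.

Temporal knowledge (hatch → 35-day weight → first egg → laying window)
may orient edges the data leave undirected, overriding the algorithm;
newly created unshielded colliders are reported, never hidden, and traits
tied in time (egg weight and egg number) are never auto-oriented between
each other — a run whose selected graph retains such an edge skips that
SEM refit with a warning instead of guessing a direction.

## Bayesian fitting

All conditionals are conjugate. Per trait, (β_j, λ_j·) is drawn jointly
from its multivariate-normal conditional under flat priors (the trait-j
equation is a linear model on season dummies and parents' phenotypes with
offset u_j); the genetic effects are updated in per-animal t-dimensional
blocks sweeping the pedigree using the sparse `A⁻¹` (assembled by the
inbreeding-aware per-individual rules; inbreeding coefficients come from
memoized kinship recursion); `G0` is inverse-Wishart; each ψ_j is scaled
inverse-χ². Default hyperparameters are weakly informative values on the
quail traits' scales: s² = (0.6, 400, 70, 0.7, 40) with ν_ψ = 3,
`G0•` = diag(0.3, 200, 30, 0.3, 10) with ν_G = 7. Default chain settings
are a single chain of 300,000 iterations with 100,000 burn-in; the test
profile (5,000 / 2,000) is used on synthetic data throughout the suite.
Per-draw deviance −2 log p(y | Λ, β, u, Ψ0) is accumulated during
sampling on the structural scale (the transform I−Λ has unit Jacobian),
and the running posterior mean of u is kept so full u chains are never
stored.

The per-animal u sweep is JIT-compiled (numba) with a pure-Python
fallback of identical arithmetic; chains are bit-reproducible given the
seed either way.

Sampler validation is layered: the u-sweep's stationary distribution is
checked against the exact joint Gaussian conditional on a structured
pedigree; a successive-conditional (Geweke-style) simulation confirms the
u/G0/ψ cycle preserves prior moments (β and Λ stay fixed there — their
flat priors cannot be sampled); and a univariate marginal-likelihood
profile with u integrated out analytically agrees with the Gibbs
posterior.

## Model comparison

The deviance conditions on u, and θ̄ includes the posterior mean of u:
DIC = 2·D̄ − D(θ̄), pD = D̄ − D(θ̄). This conditional reading is the
standard choice in this model family; the marginalized alternative (u
integrated out of the deviance) is out of scope. Models fitted to the
same dataset (enforced via a data fingerprint) are ranked with deltas to
the best; deltas under a configurable margin (default 2) are flagged as
practical ties.

## The synthetic-data generator

The generator emulates a quail layer study: five traits — birth weight
(BW, g), 35-day weight (W35, g), age at first egg (AFE, d), average egg
weight (AEW, g), number of eggs (NE) — six hatch seasons assigned
uniformly at random, and the selected causal structure BW→AEW,
W35→AFE→NE with structural coefficients (−0.408 g/g, −0.052 day/g,
−0.113 egg/day) and the reported Model-C dispersion values. Genetic
effects are drawn by sequential Mendelian sampling (founders N(0, G0);
offspring get the parental mean plus a deviation scaled by
0.5 − 0.25(F_s + F_d)), which is exactly N(0, G0 ⊗ A) at O(q·t²) cost.
Season effects are evenly spaced on the reduced scale at 0.3·√ψ_j per
step around the traits' reported means — estimable but not dominant; no
effect sizes are reported for them, so this is the package's choice.

The default breeding design is 150 founders and five generations of 60
random matings × 4 offspring: a 1,350-animal pedigree with the most
recent 840 animals phenotyped (the study analyzed 849 hens within a
10,680-animal pedigree — the generator keeps the phenotyped count and the
presence of unphenotyped ancestors, at desk scale). The family breadth
matters: designs funneling each generation through few matings (Ne ≈ 70)
leave relatedness so uniform that season effects absorb the shared
genetic mean and the genetic/residual decomposition of low-heritability
traits becomes unidentifiable — heritability posteriors then sit
systematically low. At Ne ≈ 120 with 60 families per generation the
posterior is calibrated (checked by z-scores of reduced-scale
heritabilities across probe replicates).

What the generator does not emulate: selection and non-random mating,
maternal effects, environmental trends across seasons, genotype data,
missing records (the study had none), and the full 10,680-animal pedigree
depth. Passing tests therefore demonstrate correctness of the machinery
and behavior of the method under its own assumptions, not robustness to
violations of them.

## Problem sizes and numerical choices

The suite runs everything at synthetic desk scale: the replicate study
uses 20 datasets at the default design with 4,000-iteration chains
(2,500 retained); parameter recovery uses one dataset with a 30,000 /
10,000 chain — the smallest heritability mixes too slowly for the 5,000-
iteration smoke profile to give a stable posterior mean; and the
graph-algorithm oracles enumerate DAGs and orientations exhaustively at
≤ 6 nodes. Tie-breaks are fixed everywhere
(lowest HPD window start; subsets in increasing size then lexicographic
order; stable topological sorts), singular per-draw submatrices are
skipped and counted (a query errors if more than 1% of draws drop), and
collider conflicts are surfaced as bidirected-flagged edges rather than
silently resolved.

## Known limitations

- Conditional DIC is biased toward the saturated fully recursive model in
  exact-truth simulations at this scale: the extra structural
  coefficients soak up genetic signal that imperfectly estimated u leaves
  in the residuals, dropping D̄ by far more than pD rises. Across
  replicates the DIC difference (true structure − MTAM) is roughly
  +40 ± 90, so a mild preference for the sparse structure in any single
  dataset — as in the real study — is entirely compatible with this
  spread, but the sparse structure does not win in the majority of
  replicates. A marginalized deviance would penalize the saturated model
  more honestly and is the natural extension.
- The 95%-content search has limited power for the weak edges (true
  partial correlations ≈ −0.12): single edges drop out of individual
  replicates regularly, exactly the instability the multi-content
  stability report is designed to expose.
- Heritability posteriors condition on one realized founder sample;
  at pedigree sizes far below the real study's, founder-sampling noise is
  a visible part of the error budget.
- Cyclic structures, latent-variable (FCI-style) search, maternal
  effects, and genomic relationship matrices are out of scope.
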
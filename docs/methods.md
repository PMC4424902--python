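# Methods

## Model

`hiervar` estimates per-variant disease risk in a single sequenced
gene by combining two evidence sources in a two-level hierarchical
regression.

The first level is one joint logistic regression of case status on
carrier indicators (dominant coding: any alternate allele) for all m
variants, an intercept, and optional individual-level confounders. It
returns the vector of per-variant log odds ratios β̂ and the covariance
V, taken as the corresponding block of the inverse (penalized) observed
information. Carrier coding rather than additive dosage is used
because at minor-allele frequencies ≤ 1% homozygous carriers are
vanishingly rare and the phenotype mechanism is carrier-based.

The second level models the true log relative risks as linear in the
standardized functional score, β = Zγ + δ with δ ~ N(0, τ²I) and
Z = [1, (s − s̄)/sd(s)]. γ is estimated by GLS with weights
(V + τ²I)⁻¹; the semi-Bayes shrinkage estimate is
β̃ = Zγ̂ + B(β̂ − Zγ̂) with B = τ²(τ²I + V)⁻¹, its variance
BVBᵀ + (I−B)ZΓZᵀ(I−B)ᵀ with Γ the GLS covariance of γ̂, and variants
are ranked by z = β̃/se(β̃), ties broken by variant id.

## First-stage penalization and convergence

Rare carrier indicators regularly produce complete separation, so the
default first stage is Firth's Jeffreys-prior penalized likelihood;
ridge (λ on variant coefficients only, default λ = 1, intercept and
confounders unpenalized) and an unpenalized mode exist for speed and
for closed-form checks. The IRLS solver treats the Jeffreys-modified
score U = Xᵀ(y − μ + h(1/2 − μ)) as the exact gradient it is, but uses
X'WX as an approximate Hessian; near the optimum this map can enter a
2-cycle, so steps are damped by 0.5 whenever the gradient has stopped
shrinking below max|U| < 10⁻², with step-halving keeping the penalized
likelihood non-decreasing throughout. Convergence requires
max|U| < 10⁻⁶ within 250 iterations (the damped iteration at m = 166
occasionally needs ~110–180). Exactly duplicated carrier columns are
rank-deficient under Firth; the first occurrence is kept, the
duplicates are aliased to it and share its estimate, and the aliasing
is reported.

## Second-level variance τ²

τ² controls how far estimates may deviate from the functional-score
prediction and is the single most consequential tuning parameter. The
default fixes τ² = 1 a priori — the semi-Bayes convention: residual
log relative risks within ±2 of the score prediction (roughly a
7-fold relative-risk band) with 95% probability, a deliberately
permissive prior for rare variants whose effects can be large.

A DerSimonian–Laird-style moment estimator is provided
(`tau2="moment"`): with M = I − Z(ZᵀZ)⁻¹Zᵀ and r = Mβ̂,
τ̂² = max(0, (rᵀr − tr(MVM))/tr(M)). It is not the default because it
is degenerate in precisely the regime this package targets: penalized
estimates of very rare variants have empirical spread smaller than
their nominal inverse-information variance, the moment difference goes
negative, and the floored τ̂² = 0 removes all genetic information from
the ranking (β̃ collapses to Zγ̂). The estimator remains exact and
tested for the moderate-frequency settings where it behaves.

When τ² = 0 and V is singular (aliased duplicate columns), the GLS
solve falls back to the Moore–Penrose pseudo-inverse.

## Synthetic cohort generator

The generator emulates a single-gene case-control resequencing study:
861 individuals and 166 observed variants by default, matching the
scale of the exome cohort the method was originally benchmarked
against. Because that cohort is not public, two distributional
surrogates are used, both configurable:

- **Allele counts**: P(k) ∝ k⁻¹ on k ∈ {1, …, ⌊2n·max_maf⌋}
  (default max MAF 1%, so k ≤ 17), the neutral site-frequency
  expectation; exactly k alternate alleles are placed uniformly among
  the 2n chromosomes, so every variant is observed and column sums are
  exact. This yields the singleton/doubleton-heavy spectrum in which
  genetic evidence alone is weakest.
- **C-scores**: i.i.d. Gamma(shape 2, scale 5) truncated to [0, 50]
  via the inverse CDF (PHRED-like range, mean ≈ 9.9). A degenerate
  constant mode (`score_shape=inf`) supports edge-case tests.

Causal status is assigned with probability increasing in the score:
w_j = RR^{z_j} with z_j the within-replicate standardized score,
p_j = min(1, f·m·w_j/Σw), independent Bernoulli draws. This reduces
to uniform p = f at RR = 1, induces an exactly monotone score–risk
relationship for RR > 1, and keeps the expected causal fraction at
f = 10% up to probability capping (capping costs ≈ 0.2 percentage
points at RR = 2 under the default score distribution). Carriers of at
least one causal variant draw phenotype N(0.5, 0.2²), non-carriers
N(0, 1) — a standardized effect size of 0.5 — and individuals strictly
above the sample median become cases (ties to controls), giving
430 cases / 431 controls at n = 861.

What the generator does *not* emulate: linkage disequilibrium,
population structure, genotyping error, multi-gene context, and any
real relationship between allele frequency and functional score.
Passing benchmarks on these data show the estimator exploits exactly
the structure the mechanism encodes; they do not certify performance
on real cohorts where the score–pathogenicity correlation is unknown.

## Evaluation protocol

Per replicate, both rankings are scored against the replicate's latent
causal status: the hierarchical z, and the C-score baseline in which a
variant keeps its score only if carried by at least one case and
otherwise receives a sentinel below the minimum score (rank-last).
Sentinel-last rather than exclusion keeps the truth denominator
identical across methods. AUC is the tie-aware Mann–Whitney statistic
(equal to the trapezoidal area under the full step curve; verified to
10⁻¹² in tests); curves are averaged vertically on a fixed 101-point
FPR grid with right-continuous step interpolation; the Monte-Carlo
standard error of the mean AUC is sd/√R. Replicate failures are
skipped and counted; more than 10% skipped in a configuration aborts.

Child random streams are derived from the master seed by
`SeedSequence(master_seed, spawn_key=(round(1000·RR), replicate))`, so
adding an association-strength configuration never perturbs another
configuration's draws, and the default keeps one fixed cohort
(genotypes and scores) across replicates while redrawing causal status
and phenotypes, mirroring a real sequenced cohort.

## Problem sizes

The shipped benchmark configuration runs the full cohort size
(861 × 166) with 50 replicates per association strength
(RR ∈ {1.1, 2, 4}), about half a minute of compute with the Firth
first stage; the same machinery scales to the 400-replicate average
by raising `replicates`. At 50 replicates the qualitative conclusions
are stable: the hierarchical z dominates the baseline in every
configuration (largest margin at RR = 1.1), both methods improve with
RR, and a no-signal configuration (RR = 1, μ = 0) returns both methods
to AUC ≈ 0.5.

## Known limitations

- The second stage assumes a single linear score effect; Z accepts
  more columns but no model selection is performed.
- Fixed τ² is a prior judgment; results for borderline variants can be
  sensitive to it. The moment estimator is unreliable for rare
  variants (above).
- The first-stage covariance from the inverse penalized information is
  approximate for ridge (no bias correction).
- Multiallelic VCF records are skipped, not decomposed; missing
  genotypes default to reference (a strict mode errors instead) — with
  rare variants, missing-as-reference is the conservative choice.
- No MCMC/full-Bayes fitting; uncertainty in τ² is not propagated.
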
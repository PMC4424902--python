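# hiervar

Hierarchical-model prioritization of rare variants: integrating
case-control sequencing data with aggregate functional scores.

## The problem

In a sequenced gene, most rare single-nucleotide variants are neutral,
a few are causal, and the causal ones are often singletons or
doubletons — far too rare for case/control frequencies alone to rank
them. Aggregate functional scores such as the CADD PHRED-scaled
C-score help, but they ignore the genetic evidence entirely. `hiervar`
implements a two-level hierarchical (semi-Bayes) regression that
combines both sources, for statistical geneticists who want a
per-variant ranking of likely causal variants in a gene.

## The model

**Level 1 (genetic evidence).** One multivariable logistic regression
of case status on carrier indicators for all m variants (plus
intercept and optional confounders) gives per-variant log relative
risks β̂ with covariance V. Because rare carrier indicators routinely
separate, the first stage uses Firth's Jeffreys-prior penalized
likelihood by default (ridge on the variant block is available).

**Level 2 (functional evidence).** The true log relative risks are
modeled as linear in the functional score:

    β = Zγ + δ,   δ ~ N(0, τ²I),   Z = [1, standardized C-score]

γ is estimated by generalized least squares with weights (V + τ²I)⁻¹.
The second-level residual variance τ² is fixed a priori at 1.0 by
default (the semi-Bayes convention: residual relative risks within a
~7-fold band of the score prediction at 95%); a DerSimonian–Laird-style
moment estimator is available via `tau2="moment"`.

**Shrinkage and ranking.** With B = τ²(τ²I + V)⁻¹, the compromise
estimate

    β̃ = Zγ̂ + B(β̂ − Zγ̂)

pulls each noisy genetic estimate toward its functional prediction,
with variance BVBᵀ + (I−B)ZΓZᵀ(I−B)ᵀ. Variants are ranked by the
Wald-type z = β̃ / se(β̃).

The package also ships the full simulation/evaluation protocol used to
benchmark the method: a synthetic single-gene cohort generator
(861 individuals × 166 observed variants by default, neutral-like 1/k
allele-frequency spectrum, truncated-Gamma C-scores), a generative
causal/phenotype mechanism (10% causal variants with probability
increasing in the score at relative risk 1.1/2/4 per score SD, carrier
phenotype N(0.5, 0.2²) vs non-carrier N(0,1), median-split labels),
and replicate-averaged ROC comparison of the hierarchical z-ranking
against ranking by the C-scores of variants carried by at least one
case.

## Worked example

```python
import hiervar as hv

geno, scores, truth, phen = hv.run_replicate(
    hv.CohortParams(), hv.CausalModelParams(score_rr=2.0), replicate_seed=42
)
model = hv.HierarchicalShrinkageRanker(penalty="firth", tau2=1.0)
model.fit(geno.dosages, phen.case_status,
          scores=scores.scores, variant_ids=list(geno.variant_ids))
print(f"second-stage slope (per SD of C-score): {model.gamma_[1]:.3f}")
for vid, z in model.rank()[:3]:
    print(vid, round(z, 2))
```

prints

```
second-stage slope (per SD of C-score): 0.065
1:1161:A:G 1.94
1:1034:A:G 1.91
1:1126:A:G 1.77
```

All three top-ranked variants are truly causal in this replicate; the
z-ranking recovers the causal set with AUC 0.924 against 0.691 for the
raw C-scores. The positive slope γ̂₁ = 0.065 says higher-scoring
variants carry higher estimated risk in this cohort, and the shrunken
z blends each variant's own case/control evidence with that trend.

The same fit is available from the shell for real data:

```sh
hiervar fit --vcf cohort.vcf --annotations scores.tsv \
            --phenotypes labels.tsv --out results/
```

and the full benchmark (three association strengths, replicate-averaged
ROC curves, summary TSVs and optional plot) via

```sh
hiervar evaluate --replicates 50 --seed 20260920 --out results/figure --plot
```

which writes `summary.tsv` with, per method and association strength,
the replicate-averaged AUC and its Monte-Carlo standard error. At 50
replicates and the defaults above the hierarchical ranking dominates
the C-score-only baseline in every configuration (e.g. mean AUC 0.886
vs 0.626 at relative risk 1.1), with the largest margin when the score
is only weakly informative.

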
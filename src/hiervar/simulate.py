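"""Synthetic cohort generation and the causal/phenotype mechanism.

The generator emulates the study setting the method was evaluated in: a
single gene sequenced in a case-control cohort (861 individuals, 166
observed single-nucleotide variants by default), rare-skewed allele
frequencies, a per-variant functional score, causal status assigned
with probability increasing in the score (relative risk per score
standard deviation of 1.1, 2 or 4), a Gaussian phenotype shifted to
mean 0.5 with SD 0.2 for carriers of causal variants versus standard
normal for non-carriers, and case/control labels from a median split.

The allele-frequency spectrum (neutral-like ``P(k) ~ 1/k``) and the
score distribution (Gamma truncated to the PHRED-like range [0, 50])
are surrogates for the non-deposited source data and are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AnnotationTable, GenotypeMatrix, PhenotypeTable

#: Upper truncation bound for synthetic functional scores (PHRED-like scale).
SCORE_MAX = 50.0


@dataclass
class CohortParams:
    """Generative parameters for the genotype/score cohort.

    ``sfs_exponent`` a controls the site-frequency spectrum
    ``P(allele count k) ~ k**(-a)`` on ``k in {1, ..., floor(2 n max_maf)}``;
    a = 1 is the neutral expectation. ``score_shape``/``score_scale``
    parameterize the Gamma score distribution (defaults give mean 10 on
    the PHRED-like scale); ``score_shape = inf`` is a degenerate
    constant mode where every score equals ``score_scale``.
    """

    n_individuals: int = 861
    n_variants: int = 166
    max_maf: float = 0.01
    sfs_exponent: float = 1.0
    score_shape: float = 2.0
    score_scale: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0 < self.max_maf <= 0.5:
            raise ValueError("max_maf must be in (0, 0.5]")
        if not (self.score_scale > 0 and self.score_shape > 0):
            raise ValueError("score_shape and score_scale must be positive")


@dataclass
class CausalModelParams:
    """Parameters of the causal-assignment and phenotype mechanism.

    ``score_rr`` is the relative risk of being causal per standard
    deviation of functional score; ``mu``/``sd_carrier`` give the
    carrier phenotype distribution N(mu, sd_carrier^2) against the
    non-carrier standard normal.
    """

    causal_fraction: float = 0.10
    score_rr: float = 2.0
    mu: float = 0.5
    sd_carrier: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.causal_fraction < 1:
            raise ValueError("causal_fraction must be in (0, 1)")
        if self.score_rr < 1:
            raise ValueError("score_rr must be >= 1")
        if self.sd_carrier <= 0:
            raise ValueError("sd_carrier must be positive")


@dataclass
class TruthTable:
    """Latent causal status per variant, with the assignment probabilities."""

    variant_ids: list[str]
    is_causal: np.ndarray
    assignment_probs: np.ndarray

    def __post_init__(self) -> None:
        self.is_causal = np.asarray(self.is_causal, dtype=np.int64)
        self.assignment_probs = np.asarray(self.assignment_probs, dtype=float)
        if not (len(self.variant_ids) == len(self.is_causal) == len(self.assignment_probs)):
            raise ValueError("truth table length mismatch")
        if np.any((self.assignment_probs < 0) | (self.assignment_probs > 1)):
            raise ValueError("assignment probabilities must be in [0, 1]")


def allele_count_pmf(params: CohortParams) -> tuple[np.ndarray, np.ndarray]:
    """Support and normalized probabilities of the truncated frequency spectrum."""
    k_max = math.floor(2 * params.n_individuals * params.max_maf)
    if k_max < 1:
        raise ValueError(
            f"floor(2 * n * max_maf) = {k_max} < 1: no admissible allele count"
        )
    k = np.arange(1, k_max + 1)
    w = k.astype(float) ** (-params.sfs_exponent)
    return k, w / w.sum()


def generate_genotypes(
    params: CohortParams, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw a genotype matrix with exact per-variant allele counts.

    For each variant an allele count k is drawn from the truncated
    spectrum and exactly k alternate alleles are placed uniformly at
    random among the 2n chromosomes, so every variant is observed and
    each column's dosage sum equals its drawn k.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, m = params.n_individuals, params.n_variants
    k_support, k_probs = allele_count_pmf(params)
    ks = rng.choice(k_support, size=m, p=k_probs)
    dosages = np.zeros((n, m), dtype=np.int64)
    for j, k in enumerate(ks):
        chrom = rng.choice(2 * n, size=k, replace=False)
        np.add.at(dosages[:, j], chrom // 2, 1)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    variant_ids = [f"1:{1000 + j}:A:G" for j in range(m)]
    return GenotypeMatrix(dosages, sample_ids, variant_ids)


def generate_cscores(
    n_variants: int,
    score_shape: float = 2.0,
    score_scale: float = 5.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    variant_ids: list[str] | None = None,
) -> AnnotationTable:
    """Draw i.i.d. functional scores from Gamma(shape, scale) truncated to [0, 50].

    Truncation uses the inverse-CDF transform, so draws are exact and
    deterministic given the seed. ``score_shape = inf`` yields the
    constant mode (all scores equal ``score_scale``).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if variant_ids is None:
        variant_ids = [f"1:{1000 + j}:A:G" for j in range(n_variants)]
    if math.isinf(score_shape):
        if not 0 <= score_scale <= SCORE_MAX:
            raise ValueError("constant-mode score must lie in [0, 50]")
        return AnnotationTable(variant_ids, np.full(n_variants, float(score_scale)))
    if score_shape <= 0 or score_scale <= 0:
        raise ValueError("score_shape and score_scale must be positive")
    dist = stats.gamma(a=score_shape, scale=score_scale)
    u = rng.random(n_variants) * dist.cdf(SCORE_MAX)
    scores = dist.ppf(u)
    return AnnotationTable(variant_ids, np.clip(scores, 0.0, SCORE_MAX))


def assign_causal(
    scores: AnnotationTable,
    params: CausalModelParams,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Assign latent causal status with probability increasing in the score.

    Per-variant weight ``w_j = RR ** z_j`` with ``z_j`` the
    within-replicate standardized score; assignment probability
    ``p_j = min(1, f * m * w_j / sum(w))`` so that the expected causal
    fraction is f up to probability capping; status is drawn as
    independent Bernoulli(p_j).
    """
    params.validate()
    if len(scores.variant_ids) == 0:
        raise ValueError("need at least one variant")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    s = scores.scores
    m = len(s)
    f = params.causal_fraction
    sd = s.std()
    if params.score_rr == 1.0 or sd == 0.0:
        if sd == 0.0 and params.score_rr > 1.0:
            warnings.warn(
                "all scores identical: score standardization degenerate, "
                "falling back to uniform causal probability",
                RuntimeWarning,
            )
        probs = np.full(m, f)
    else:
        z = (s - s.mean()) / sd
        w = params.score_rr ** z
        probs = np.minimum(1.0, f * m * w / w.sum())
    is_causal = (rng.random(m) < probs).astype(np.int64)
    return TruthTable(list(scores.variant_ids), is_causal, probs)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    truth: TruthTable,
    params: CausalModelParams,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Gaussian mixture phenotype: carriers of causal variants are shifted.

    An individual is a carrier iff it has dosage > 0 for at least one
    causal variant (no dose term). Carriers draw
    y ~ N(mu, sd_carrier^2); non-carriers draw y ~ N(0, 1).
    """
    params.validate()
    if list(truth.variant_ids) != list(genotypes.variant_ids):
        raise ValueError("truth table not aligned with genotype variants")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    causal_cols = truth.is_causal.astype(bool)
    carrier = (genotypes.dosages[:, causal_cols] > 0).any(axis=1)
    n = genotypes.n_individuals
    y = rng.standard_normal(n)
    y[carrier] = params.mu + params.sd_carrier * y[carrier]
    return PhenotypeTable(list(genotypes.sample_ids), y_continuous=y)


def dichotomize(y: np.ndarray) -> np.ndarray:
    """Median split: case iff strictly above the sample median.

    With continuous draws this yields floor(n/2) cases; ties go to
    controls. All-identical values leave zero cases and are an error.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two individuals to dichotomize")
    case = (y > np.median(y)).astype(np.int64)
    if case.sum() == 0:
        raise ValueError("degenerate labels: no phenotype exceeds the median")
    return case


def run_replicate(
    cohort_params: CohortParams,
    causal_params: CausalModelParams,
    replicate_seed: int,
    genotypes: GenotypeMatrix | None = None,
    annotations: AnnotationTable | None = None,
) -> tuple[GenotypeMatrix, AnnotationTable, TruthTable, PhenotypeTable]:
    """One draw of the full generative mechanism.

    Child streams for genotypes, scores, causal assignment and
    phenotype are derived deterministically from ``replicate_seed``.
    Pass ``genotypes``/``annotations`` to hold the cohort fixed across
    replicates (as with a real sequenced cohort) while redrawing causal
    status and phenotype.
    """
    ss = np.random.SeedSequence(replicate_seed)
    rng_geno, rng_score, rng_causal, rng_pheno = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    if genotypes is None:
        genotypes = generate_genotypes(cohort_params, rng=rng_geno)
    if annotations is None:
        annotations = generate_cscores(
            cohort_params.n_variants,
            cohort_params.score_shape,
            cohort_params.score_scale,
            rng=rng_score,
            variant_ids=list(genotypes.variant_ids),
        )
    truth = assign_causal(annotations, causal_params, rng=rng_causal)
    phen = simulate_phenotype(genotypes, truth, causal_params, rng=rng_pheno)
    phen.case_status = dichotomize(phen.y_continuous)
    return genotypes, annotations, truth, phen
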
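import numpy as np
import pytest

import hiervar as hv


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial synthetic cohort (fast to fit)."""
    params = hv.CohortParams(n_individuals=200, n_variants=30, max_maf=0.02, seed=11)
    ss = np.random.SeedSequence(11)
    rg, rs = (np.random.default_rng(c) for c in ss.spawn(2))
    geno = hv.generate_genotypes(params, rng=rg)
    ann = hv.generate_cscores(
        params.n_variants, rng=rs, variant_ids=list(geno.variant_ids)
    )
    return geno, ann


@pytest.fixture(scope="session")
def small_replicate(small_cohort):
    """One full generative draw on the small cohort."""
    geno, ann = small_cohort
    causal = hv.CausalModelParams(score_rr=2.0, seed=5)
    geno, ann, truth, phen = hv.run_replicate(
        hv.CohortParams(n_individuals=200, n_variants=30, max_maf=0.02),
        causal, 99, genotypes=geno, annotations=ann,
    )
    return geno, ann, truth, phen
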
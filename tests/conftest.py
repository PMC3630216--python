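import numpy as np
import pytest

from gistsig.simulate import (
    CohortSpec,
    GeneSpec,
    Stratum,
    make_study_fixture,
    simulate_cohort,
)


def null_cohort_spec(seed, n=300, n_genes=4, p=5, rho=0.4, maf_lo=0.1, maf_hi=0.45,
                     missing_rate=0.0):
    """Small cohort spec with no planted effects (outcome independent of genotype)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    nv = n_genes * p
    maf_w = rng.uniform(maf_lo, maf_hi, nv)
    maf_o = np.clip(maf_w + rng.normal(0, 0.08, nv), 0.05, 0.45)
    return CohortSpec(
        n_subjects=n,
        strata=[Stratum("white", 0.82, maf_w), Stratum("other", 0.18, maf_o)],
        genes=[GeneSpec(f"G{i}", p, rho) for i in range(n_genes)],
        missing_rate=missing_rate,
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_fixture():
    """Engineered 333-subject / 225-variant pre-QC cohort (seed fixed)."""
    return make_study_fixture(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A clean 300-subject null cohort used by several module tests."""
    return simulate_cohort(null_cohort_spec(seed=11, missing_rate=0.01))
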
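import numpy as np
import pytest

from inote.core_data import Cohort, GeneBlock
from inote.null_model import fit_null


def make_cohort(n=60, r=2, seed=0):
    """Random balanced-ish cohort with intercept + (r-1) covariates."""
    rng = np.random.default_rng(seed)
    x = np.column_stack([np.ones(n), rng.standard_normal((n, r - 1))]) \
        if r > 1 else np.ones((n, 1))
    y = np.zeros(n)
    y[rng.choice(n, n // 2, replace=False)] = 1.0
    return Cohort(y=y, x=x)


def make_block(n=60, p=4, seed=0, gene_id="g", with_g=True, with_m=True):
    rng = np.random.default_rng(seed + 1000)
    m = rng.uniform(0.1, 0.9, size=(n, p)) if with_m else None
    g = rng.standard_normal(n) if with_g else None
    return GeneBlock(gene_id, m=m, g=g)


@pytest.fixture(scope="session")
def cohort60():
    return make_cohort(60, 2, seed=3)


@pytest.fixture(scope="session")
def null60(cohort60):
    return fit_null(cohort60)


@pytest.fixture(scope="session")
def blocks3(cohort60):
    return [make_block(cohort60.n, p, seed=s, gene_id=f"g{s}")
            for s, p in zip((1, 2, 3), (3, 5, 2))]
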
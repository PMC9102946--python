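import numpy as np
import pandas as pd
import pytest

from hepident.synthcohort import (
    generate_annotation,
    generate_cohort_counts,
    generate_methylation,
)


@pytest.fixture(scope="session")
def small_annotation():
    """300 coding + 60 lncRNA genes with promoter-covered CpGs (seed 1)."""
    return generate_annotation(300, 60, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_annotation):
    """20 normals / 80 tumors with 10 planted downregulated lncRNAs."""
    genes, cpgs = small_annotation
    counts, cond, truth = generate_cohort_counts(
        genes, n_normal=20, n_tumor=80, n_planted_down=10, seed=1
    )
    return genes, cpgs, counts, cond, truth


@pytest.fixture(scope="session")
def small_methylation(small_cohort):
    genes, cpgs, counts, cond, truth = small_cohort
    beta, pairing, truth = generate_methylation(genes, cpgs, truth, n_pairs=30, seed=1)
    return genes, cpgs, beta, pairing, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
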
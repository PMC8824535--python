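import numpy as np
import pytest

from mirrank import gene_sets as gs
from mirrank import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_config():
    """Small-but-complete generator configuration for fast end-to-end runs."""
    return sd.GeneratorConfig(
        seed=7,
        n_mirnas=6,
        n_genes=300,
        n_databases=3,
        prediction_density=0.05,
        planted_category_sizes={c: 20 for c in gs.DEFAULT_CATEGORY_KEYWORDS},
    )


def null_cohort_config(seed: int, cohort_n: int = 23) -> sd.GeneratorConfig:
    """One-miRNA cohort with no planted effect (fold change 1, no copula)."""
    return sd.GeneratorConfig(
        seed=seed,
        cohort_n=cohort_n,
        cohort_mirnas=["hsa-miR-126"],
        undetectable_mirnas=[],
        planted_fold_changes={},
        planted_spearman={},
    )
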
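import numpy as np
import pytest

from snpsib.genio import GenotypeMatrix, impute_missing
from snpsib.simdata import SimConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_study():
    """A small two-cohort study with two planted causal SNPs (imputed)."""
    cfg = SimConfig(
        n_snps=40,
        n_cases_train=120,
        n_controls_train=90,
        n_cases_test=60,
        n_controls_test=90,
        causal_indices=(3, 17),
        causal_log_odds=(1.3, 1.3),
        seed=11,
    )
    (G_tr, y_tr), (G_te, y_te), truth = simulate_cohorts(cfg)
    G_te = impute_missing(G_te, reference=G_tr)
    G_tr = impute_missing(G_tr)
    return G_tr, y_tr, G_te, y_te, truth


@pytest.fixture()
def toy_matrix():
    """Four samples, one SNP: cases are minor homozygotes, controls major."""
    G = GenotypeMatrix(
        codes=np.array([[0], [0], [2], [2]], dtype=np.int8),
        sample_ids=["a", "b", "c", "d"],
        snp_ids=["rs1"],
    )
    y = np.array([1, 1, 0, 0], dtype=np.int8)
    return G, y
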
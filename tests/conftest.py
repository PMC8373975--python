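import numpy as np
import pandas as pd
import pytest

import cmsshift as cs

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def small_cohort():
    """A modest labeled two-platform cohort with planted DE genes."""
    cfg = cs.CohortConfig(
        n_genes=500, n_samples_per_platform=(30, 30), n_cms2=30, n_cms4=30,
        n_de_genes=40, de_log2fc_magnitude=2.0, seed=7,
    )
    matrix, annotation, truth = cs.simulate_reference_cohort(cfg)
    return cfg, matrix, annotation, truth


@pytest.fixture(scope="session")
def adjusted_cohort(small_cohort):
    cfg, matrix, annotation, truth = small_cohort
    log2 = cs.rpm_log2(matrix)
    adjusted, _ = cs.batch_adjust(log2, annotation["platform"])
    return cfg, adjusted, annotation, truth


def make_matrix(values, genes=None, samples=None, layer="log2rpm"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return cs.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), layer=layer)
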
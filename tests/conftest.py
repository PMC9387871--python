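import numpy as np
import pandas as pd
import pytest

import nmfomics as nm
from nmfomics.simulate import SimulationDesign, simulate_cohort


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(n_genes=120, n_cpgs=400, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    """One small simulated cohort shared across read-only tests."""
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Preprocessed matrix + rank-5 fit of the small cohort."""
    expr, beta, sheet, annot, truth = small_cohort
    expr_f, _ = nm.mean_variance_filter(nm.normalize_expression(expr), 1.25, 0.1)
    beta_f, _ = nm.mean_variance_filter(beta, 0.05, 0.005)
    A = nm.concatenate_and_scale(expr_f, beta_f)
    model = nm.nmf_fit(A, 5, n_runs=5, max_iter=600, seed=11)
    return A, model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_omics(rng, n_features=20, n_samples=8, modality=nm.GENE, low=0.0, high=10.0):
    data = pd.DataFrame(
        rng.uniform(low, high, size=(n_features, n_samples)),
        index=[f"{modality[0]}{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return nm.OmicsMatrix(data, modality)
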
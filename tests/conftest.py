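import warnings

import numpy as np
import pytest

from neuropathnet.models import MultiTaskNeuralRegressor
from neuropathnet.preprocess import (
    apply_pca,
    fit_pca,
    harmonize_batches,
    minmax_normalize,
)
from neuropathnet.simulate import SimulationConfig, generate

warnings.filterwarnings("ignore", message="Mean of empty slice")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small multi-cohort dataset shared across unit tests."""
    cfg = SimulationConfig(
        n_cohorts=2,
        samples_per_cohort=60,
        n_genes=150,
        n_signal_genes=15,
        n_sex_interacting_genes=6,
        n_sex_marker_genes=4,
        seed=5,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def tiny_processed(tiny_dataset):
    expr, pheno, covs, truth = tiny_dataset
    norm, scaler = minmax_normalize(expr)
    harm = harmonize_batches(norm, norm.cohort)
    pca = fit_pca(harm.values, k=25)
    X_pc = apply_pca(pca, harm.values)
    return {
        "expr": harm,
        "pheno": pheno,
        "covs": covs,
        "truth": truth,
        "pca": pca,
        "X_pc": X_pc,
        "scaler": scaler,
    }


@pytest.fixture(scope="session")
def tiny_model(tiny_processed):
    est = MultiTaskNeuralRegressor(
        shared_widths=(24, 12),
        branch_widths=(6,),
        epochs=20,
        random_state=0,
    )
    est.fit(tiny_processed["X_pc"], tiny_processed["pheno"].masked_array())
    return est
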
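import numpy as np
import pytest

import cmskit as ck
from cmskit.io import ExpressionMatrix, LabelVector


@pytest.fixture(scope="session")
def small_cohort():
    """100-sample, 20-gene cohort with 2 markers per subtype; moderately noisy
    so the classes overlap and CV has signal to work with."""
    cfg = ck.SimulationConfig(
        n_per_class=(25, 25, 25, 25),
        n_genes=20,
        n_informative_per_class=2,
        effect_size=2.0,
        noise_sd=1.0,
        seed=3,
    )
    return ck.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_reference(small_cohort):
    matrix, _, _ = small_cohort
    panel = ck.GenePanel(matrix.gene_ids, "FF")
    return ck.build_reference(matrix, panel, "FF")


@pytest.fixture(scope="session")
def small_training_set(small_cohort, small_reference):
    matrix, labels, _ = small_cohort
    tags = ("nanostring",) * matrix.n_samples
    return ck.TrainingSet(
        X=ck.align_cotraining(matrix, small_reference),
        y=labels,
        weights=ck.default_weights(tags),
        source=tags,
    )


@pytest.fixture(scope="session")
def small_model(small_training_set, small_reference):
    """One trained model shared across tests (CV over a short lambda grid)."""
    return ck.fit(
        small_training_set, small_reference, alpha=0.7, cv_folds=5, seed=3, n_lambda=15
    )


def make_matrix(values, scale="log2", gene_prefix="G", sample_prefix="S"):
    values = np.asarray(values, dtype=float)
    genes = tuple(f"{gene_prefix}{i + 1}" for i in range(values.shape[0]))
    samples = tuple(f"{sample_prefix}{j + 1}" for j in range(values.shape[1]))
    return ExpressionMatrix(genes, samples, values, scale)
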
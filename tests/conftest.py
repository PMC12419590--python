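"""Shared fixtures: small synthetic cohorts, an integrated set, a trained model.

Session scope keeps the expensive pieces (training) to a single fit.
"""

import numpy as np
import pandas as pd
import pytest

from stmir import datafusion, regression, synthdata
from stmir.types import ExprMatrix

SEED = 11


def make_expr(values, features, samples, modality="mRNA", cohort="c", stage="raw"):
    return ExprMatrix(
        values=pd.DataFrame(values, index=features, columns=samples, dtype=float),
        modality=modality,
        cohort=cohort,
        stage=stage,
    )


@pytest.fixture(scope="session")
def truth():
    return synthdata.make_truth(n_genes=120, n_mirnas=12, n_celltypes=4, seed=SEED)


@pytest.fixture(scope="session")
def bulk_pair(truth):
    mrna_a, mirna_a, _ = synthdata.generate_bulk_cohort(
        n_samples=150, cohort_label="A", seed=SEED, truth=truth
    )
    mrna_b, mirna_b, _ = synthdata.generate_bulk_cohort(
        n_samples=120, cohort_label="B", seed=SEED, truth=truth,
        batch_distortion="scale-power",
    )
    return mrna_a, mirna_a, mrna_b, mirna_b


@pytest.fixture(scope="session")
def training_set(bulk_pair):
    return datafusion.integrate_pair(*bulk_pair)


@pytest.fixture(scope="session")
def small_hp():
    return regression.Hyperparams(learning_rate=0.1, max_depth=4, n_estimators=100)


@pytest.fixture(scope="session")
def bundle(training_set, small_hp):
    return regression.train(training_set, small_hp, seed=SEED)


@pytest.fixture(scope="session")
def tissue(truth):
    return synthdata.generate_spatial_tissue(
        truth, n_spots=240, dominant_fraction=0.75, purity_range=(0.55, 0.95),
        depth_mean=8000, seed=SEED,
    )
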
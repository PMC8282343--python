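"""Shared fixtures: small simulated cohorts, preprocessed expression."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sigqtl import preprocess, simdata


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return simdata.SimConfig(
        n_samples=80,
        n_genes=200,
        n_variants=600,
        n_phenotypes=10,
        category_blocks={"ses": 3, "asthma": 3, "blood_composition": 4},
        missing_fraction=0.25,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> simdata.CohortBundle:
    return simdata.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_expr(small_cohort) -> preprocess.ExpressionMatrix:
    expr = preprocess.ExpressionMatrix(
        counts=small_cohort.counts,
        gene_meta=small_cohort.annotation,
    )
    expr = preprocess.filter_genes(expr)
    expr = preprocess.normalize_logcpm(expr)
    cov = pd.DataFrame(
        small_cohort.truth.confounders,
        index=small_cohort.counts.columns,
        columns=["C1", "C2", "C3"],
    )
    return preprocess.residualize(expr, cov)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
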
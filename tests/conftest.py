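"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pytest

from npxrisk.preprocess import preprocess_study
from npxrisk.simulate import CohortSpec, SimConfig, TruthTable, generate_study


def make_study(
    n_sets_per_cohort=60,
    cohorts=("A", "B"),
    n_proteins=6,
    beta0=None,
    seed=0,
    duplicate_fraction=0.0,
    lod_quantile=0.0,
    **kwargs,
):
    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    truth = TruthTable.with_effects(proteins, beta0=beta0) if beta0 else TruthTable.null(proteins)
    cfg = SimConfig(
        cohorts=[CohortSpec(c, n_sets_per_cohort, ("panel1", "panel2")) for c in cohorts],
        n_proteins=n_proteins,
        duplicate_fraction=duplicate_fraction,
        lod_quantile=lod_quantile,
        truth=truth,
        seed=seed,
        **kwargs,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_study():
    """Two-cohort null study with duplicates and LOD censoring."""
    return make_study(
        n_sets_per_cohort=50, n_proteins=10, duplicate_fraction=0.2, lod_quantile=0.05, seed=11
    )


@pytest.fixture(scope="session")
def planted_study():
    """Four-cohort study with one strong planted protein (OR_sd = 2)."""
    return make_study(
        n_sets_per_cohort=120,
        cohorts=("A", "B", "C", "D"),
        n_proteins=8,
        beta0={"P0001": np.log(2.0)},
        seed=21,
    )


@pytest.fixture(scope="session")
def planted_pre(planted_study):
    return preprocess_study(
        planted_study.matrix, planted_study.lod_mask, planted_study.annotations, planted_study.subjects
    )
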
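"""Shared fixtures: one synthetic study data set, fitted once per session."""

from __future__ import annotations

import numpy as np
import pytest

from fieldqsar import (
    ProbeSpec,
    SyntheticSpec,
    build_grid,
    filter_columns,
    generate_ligand_set,
    plant_activities,
    select_n_components,
    table1_fixture,
)
from fieldqsar.synthetic import default_planted_coefficients

CV_SEED = 7


@pytest.fixture(scope="session")
def synthetic_study():
    """40 aligned synthetic ligands, noise sd = 5% of planted signal sd."""
    spec = SyntheticSpec(n_ligands=40, noise_sd=0.05, noise_relative=True, seed=0)
    ligs = generate_ligand_set(spec)
    grid = build_grid(ligs.molecules, spacing=1.5, margin=4.0)
    spec.planted_coefficients = default_planted_coefficients(grid)
    ligs, dm_full = plant_activities(ligs, grid, ProbeSpec(), spec)
    dm = filter_columns(dm_full, min_sd=0.05)
    return {
        "spec": spec,
        "ligs": ligs,
        "grid": grid,
        "dm_full": dm_full,
        "dm": dm,
        "y": ligs.pic50,
    }


@pytest.fixture(scope="session")
def fitted_model(synthetic_study):
    """Component count chosen by 5-fold CV on the synthetic study set."""
    dm = synthetic_study["dm"]
    return select_n_components(
        dm.values, synthetic_study["y"], folds=5, seed=CV_SEED, max_A=8
    )


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_test_pairs(table1):
    """(observed, predicted) pIC50 for the 8 external test compounds."""
    test = table1[table1["set_label"] == "test"]
    return test["pic50_exp"].to_numpy(), test["pic50_pred"].to_numpy()
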
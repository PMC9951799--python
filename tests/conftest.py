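"""Shared fixtures: a small synthetic dataset and fitted models.

Everything is generated programmatically with fixed seeds; the fitted-model
fixtures use short chains sized for test speed, which is enough for the
structural and directional checks they back.
"""

import warnings

import pytest

from allelometa.effects import effect_table
from allelometa.impute import add_dose_categories, impute_dose
from allelometa.model import ModelSpec, build_design, fit
from allelometa.simulate import SyntheticConfig, simulate_dataset, simulate_tree

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study set (~200 effects) plus its tree and truth."""
    cfg = SyntheticConfig(seed=3, n_grass=10, n_recipient=16,
                          target_effects=200)
    tree = simulate_tree(cfg.n_grass + cfg.n_recipient, seed=3)
    records, truth = simulate_dataset(cfg, tree)
    return cfg, tree, records, truth


@pytest.fixture(scope="session")
def completed_table(small_world):
    _, tree, records, _ = small_world
    table = effect_table(records)
    kept = table.loc[table["keep"]].reset_index(drop=True)
    imp = impute_dose(kept, seed=1)
    return add_dose_categories(kept, imp)


@pytest.fixture(scope="session")
def fitted_full(small_world, completed_table):
    _, tree, _, _ = small_world
    spec = ModelSpec(kind="full", chains=2, iterations=800, warmup=400, seed=5)
    design = build_design(completed_table, tree, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(design, spec)
    return draws, design


@pytest.fixture(scope="session")
def fitted_intercept(small_world, completed_table):
    _, tree, _, _ = small_world
    spec = ModelSpec(kind="intercept_only", chains=2, iterations=800,
                     warmup=400, seed=6)
    design = build_design(completed_table, tree, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(design, spec)
    return draws, design
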
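"""Shared fixtures: all test inputs are generated, none are shipped."""

from __future__ import annotations

import numpy as np
import pytest

from gemble import build_from_models
from gemble.fixtures import (
    FixtureSpec,
    degrade_model,
    make_phenotype_table,
    make_synthetic_ensemble,
    make_toy_model,
    make_two_pathway_gapfill_fixture,
)


@pytest.fixture
def toy_model():
    """Single-carbon linear chain, FBA optimum 10."""
    return make_toy_model(FixtureSpec(n_carbon_sources=1))


@pytest.fixture
def toy_model_2src():
    """Two independent carbon chains, FBA optimum 20."""
    return make_toy_model(FixtureSpec(n_carbon_sources=2))


@pytest.fixture
def two_member_ensemble(toy_model_2src):
    """Members m1 (complete, optimum 20) and m2 (lacking CONV_C1, optimum 10)."""
    m1 = toy_model_2src.copy()
    m1.id = "m1"
    m2 = toy_model_2src.copy()
    m2.id = "m2"
    m2.remove_reactions([m2.reactions.get_by_id("CONV_C1")], remove_orphans=False)
    return build_from_models([m1, m2])


def build_seeded_toy_ensemble(n_members: int = 20, seed: int = 7):
    """Ensemble of toy variants differing in uptake bounds and reaction presence."""
    rng = np.random.default_rng(seed)
    base = make_toy_model(FixtureSpec(n_carbon_sources=2))
    variants = []
    for i in range(n_members):
        variant = base.copy()
        variant.id = f"v{i:02d}"
        variant.reactions.get_by_id("EX_C1").lower_bound = float(
            -rng.choice([10.0, 5.0, 2.0])
        )
        if rng.random() < 0.4:
            variant.remove_reactions(
                [variant.reactions.get_by_id("CONV_C2")], remove_orphans=False
            )
        if rng.random() < 0.3:
            variant.reactions.get_by_id("T_C2").upper_bound = 3.0
        variants.append(variant)
    return build_from_models(variants, ensemble_id="seeded_toy")


@pytest.fixture(scope="session")
def seeded_toy_ensemble():
    return build_seeded_toy_ensemble()


@pytest.fixture
def degraded_fixture(toy_model_2src):
    """(complete, draft, universal) with CONV_C1 removed and 3 decoys."""
    draft, universal = degrade_model(toy_model_2src, ["CONV_C1"])
    return toy_model_2src, draft, universal


@pytest.fixture
def two_pathway_fixture():
    return make_two_pathway_gapfill_fixture()


@pytest.fixture(scope="session")
def synthetic_ensemble():
    """(ensemble, causal feature id) with one planted causal feature."""
    return make_synthetic_ensemble(FixtureSpec(seed=3))
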
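"""Shared fixtures: reference geometries and small synthetic reaction sets."""

import numpy as np
import pytest

from qtst.dataset_builder import scaffold_split
from qtst.featurization import FeatureConfig
from qtst.synthetic_fixtures import FixtureSpec, make_reaction_set, planted_q_dataset, reference_geometries


@pytest.fixture(scope="session")
def geoms():
    return reference_geometries()


@pytest.fixture(scope="session")
def small_reactions():
    """50 synthetic reactions with 5 temperatures each."""
    return make_reaction_set(FixtureSpec(n_reactions=50, n_temps=5, seed=11))


@pytest.fixture(scope="session")
def small_split(small_reactions):
    return scaffold_split(small_reactions, seed=11)


@pytest.fixture(scope="session")
def feature_config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def planted_setup():
    """200 reactions x 10 temperatures with a planted feature->ln Q map.

    Session-scoped because generation plus featurization is the expensive
    part shared by the estimator-recovery checks.
    """
    spec = FixtureSpec(n_reactions=200, n_temps=10, seed=7)
    reactions = make_reaction_set(spec)
    fcfg = FeatureConfig()
    rows = planted_q_dataset(reactions, fcfg, seed=7)
    split = scaffold_split(reactions, seed=7)
    structures = {s.id: s for r in reactions for s in r.structures}
    return {
        "reactions": reactions,
        "rows": rows,
        "split": split,
        "structures": structures,
        "fcfg": fcfg,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
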
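import numpy as np
import pandas as pd
import pytest

from divmeta import effect_sizes as es
from divmeta import synthetic_data as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.SyntheticConfig(seed=20221127, n_studies=40,
                               obs_per_study=(2, 4))


@pytest.fixture(scope="session")
def small_corpus(small_config):
    """A small synthetic observation table with its tree and ground truth."""
    tree = syn.simulate_tree(small_config)
    obs, truth = syn.simulate_observations(small_config, tree=tree)
    return obs, tree, truth


@pytest.fixture(scope="session")
def small_effects(small_corpus):
    obs, _, _ = small_corpus
    return es.add_effect_sizes(obs)


@pytest.fixture(scope="session")
def toy_meta_table():
    """Tiny effect-size table with 2 studies for closed-form checks."""
    rng = np.random.default_rng(7)
    study = ["s1"] * 4 + ["s2"] * 4
    v = rng.uniform(0.05, 0.3, 8)
    y = 0.3 + np.repeat(rng.normal(0, 0.3, 2), 4) + rng.normal(0, np.sqrt(v))
    return pd.DataFrame({"g": y, "v": v, "study_id": study})
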
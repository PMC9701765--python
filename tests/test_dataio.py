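"""Observation schema, validation, round-trip I/O, and SEM subsets."""

import numpy as np
import pandas as pd
import pytest

from divmeta import dataio, effect_sizes as es
from divmeta import synthetic_data as syn


def rows(n=3, **overrides):
    base = dict(obs_id="o", study_id="s1", plant_species="sp_1",
                trophic_group="plant", response_category="plant_growth",
                mean_treat=6.0, mean_ctrl=5.0, sd_treat=1.0, sd_ctrl=1.0,
                n_treat=10, n_ctrl=10, n_genotypes_added=2,
                ecosystem="agroecosystem", life_form="herbaceous",
                experiment_type="plot", climate_zone="temperate",
                site_id=None, plot_id=None, latitude=None, longitude=None)
    out = []
    for i in range(n):
        r = dict(base, obs_id=f"o{i}")
        for k, val in overrides.items():
            r[k] = val[i] if isinstance(val, list) else val
        out.append(r)
    return pd.DataFrame(out)


def test_read_well_formed(tmp_path):
    path = tmp_path / "obs.csv"
    rows(3).to_csv(path, index=False)
    records, rejects = dataio.read_observations(path)
    assert len(records) == 3 and len(rejects) == 0


def test_reject_insufficient_df(tmp_path):
    path = tmp_path / "obs.csv"
    rows(2, n_treat=[1, 10]).to_csv(path, index=False)
    records, rejects = dataio.read_observations(path)
    assert len(records) == 1 and len(rejects) == 1
    assert "insufficient df" in rejects["reason"].iloc[0]


def test_reject_inconsistent_group_mapping(tmp_path):
    path = tmp_path / "obs.csv"
    rows(1, response_category="herbivore_damage").to_csv(path, index=False)
    _, rejects = dataio.read_observations(path)
    assert "inconsistent" in rejects["reason"].iloc[0]


def test_reject_non_numeric(tmp_path):
    path = tmp_path / "obs.csv"
    df = rows(2)
    df["sd_treat"] = df["sd_treat"].astype(object)
    df.loc[0, "sd_treat"] = "NA?"
    df.to_csv(path, index=False)
    records, rejects = dataio.read_observations(path)
    assert len(records) == 1
    assert "non-numeric" in rejects["reason"].iloc[0]


def test_missing_column_is_schema_error(tmp_path):
    path = tmp_path / "obs.csv"
    rows(2).drop(columns=["sd_ctrl"]).to_csv(path, index=False)
    with pytest.raises(dataio.SchemaError):
        dataio.read_observations(path)


def test_schema_map_renames_columns(tmp_path):
    path = tmp_path / "obs.csv"
    rows(2).rename(columns={"mean_treat": "Mt"}).to_csv(path, index=False)
    records, _ = dataio.read_observations(path, schema={"Mt": "mean_treat"})
    assert len(records) == 2


def test_round_trip_lossless(tmp_path, small_corpus):
    obs, _, _ = small_corpus
    recs = dataio.frame_to_records(obs)
    path = tmp_path / "out.csv"
    dataio.write_observations(recs, path)
    back, rejects = dataio.read_observations(path)
    assert len(rejects) == 0
    assert back == recs


@pytest.mark.parametrize("category, group, antagonist", [
    ("disease_spread", "disease", True),
    ("plant_growth", "plant", False),
    ("predator_abundance", "natural_enemy", False),
    ("weed_diversity", "weed", True),
    ("nematode_abundance", "nematode", True),
    ("herbivore_damage", "herbivore", True),
])
def test_response_group_mapping(category, group, antagonist):
    assert dataio.map_response_to_group(category) == (group, antagonist)


def test_unknown_category_raises():
    with pytest.raises(dataio.MappingError):
        dataio.map_response_to_group("plankton_abundance")


def test_every_category_maps_to_exactly_one_group():
    seen = {}
    for cat in dataio.RESPONSE_CATEGORIES:
        grp, flag = dataio.map_response_to_group(cat)
        assert grp in dataio.TROPHIC_GROUPS
        seen.setdefault(grp, []).append(cat)
    antag_union = {c for g in dataio.ANTAGONIST_GROUPS for c in seen.get(g, [])}
    other = {c for g, cs in seen.items()
             if g not in dataio.ANTAGONIST_GROUPS for c in cs}
    assert not antag_union & other  # no category double-counted


def _paired_effects():
    df = pd.concat([
        rows(2, study_id="sA", trophic_group=["disease", "plant"],
             response_category=["disease_spread", "plant_growth"]),
        rows(2, study_id="sB", trophic_group="plant",
             response_category="plant_growth"),
    ], ignore_index=True)
    df["obs_id"] = [f"o{i}" for i in range(len(df))]
    return es.add_effect_sizes(df)


def test_build_pairs_definition():
    eff = _paired_effects()
    pairs = dataio.build_pairs(eff, "disease", "plant")
    assert len(pairs) == 1  # only study sA measured both
    assert pairs["study_id"].iloc[0] == "sA"
    assert pairs.attrs["n_studies"] == 1


def test_build_pairs_role_swap_symmetry():
    eff = _paired_effects()
    ab = dataio.build_pairs(eff, "disease", "plant")
    ba = dataio.build_pairs(eff, "plant", "disease")
    assert len(ab) == len(ba)
    assert np.allclose(ab["g_lower"].to_numpy(), ba["g_upper"].to_numpy())
    assert np.allclose(ab["g_upper"].to_numpy(), ba["g_lower"].to_numpy())


def test_build_triples_definition():
    df = rows(3, study_id="sC",
              trophic_group=["natural_enemy", "herbivore", "plant"],
              response_category=["predator_abundance", "herbivore_abundance",
                                 "plant_growth"])
    eff = es.add_effect_sizes(df)
    triples = dataio.build_triples(eff)
    assert len(triples) == 1
    two = es.add_effect_sizes(df.iloc[:2].copy())
    assert len(dataio.build_triples(two)) == 0


def test_pair_and_triple_counts_match_generator_bookkeeping(small_config):
    obs, truth = syn.simulate_trophic_links(small_config, n_studies=25)
    eff = es.add_effect_sizes(obs)
    planted = truth["planted"]
    triples = dataio.build_triples(eff)
    assert len(triples) == len(planted)
    pairs = dataio.build_pairs(eff, "herbivore", "plant")
    assert len(pairs) == len(planted)
    assert pairs.attrs["n_studies"] == planted["study_id"].nunique()


def test_generated_data_validates_with_zero_rejects(tmp_path, small_corpus):
    obs, _, _ = small_corpus
    path = tmp_path / "gen.csv"
    obs.to_csv(path, index=False)
    records, rejects = dataio.read_observations(path)
    assert len(records) == len(obs) and len(rejects) == 0
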
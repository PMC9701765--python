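"""Observation data model, CSV I/O with validation, and analysis subsets.

The unit of analysis is one *observation*: a diverse-vs-monoculture contrast
for one response measure in one study.  Each row carries the two-group summary
statistics (means, SDs, sample sizes), the moderators (ecosystem, life form,
experiment type, climatic zone, number of added genotypes) and identifiers
(study, optional site/plot, plant species).  Validation never drops rows
silently: rejects are returned with reasons.

Subset builders assemble the structural-equation-model inputs: bi-trophic
pairs (e.g. plant antagonist performance vs. plant performance) and
tri-trophic triples (natural enemy, herbivore, plant) of effect sizes that
were co-measured within the same study and diversity contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TROPHIC_GROUPS = (
    "plant",
    "herbivore",
    "natural_enemy",
    "weed",
    "nematode",
    "disease",
)

#: Groups whose performance harms plants; aggregated as "plant antagonists".
ANTAGONIST_GROUPS = frozenset({"herbivore", "weed", "nematode", "disease"})

#: Fixed response-category -> trophic-group mapping.  Categories are concrete
#: measures; aggregate panels (plant antagonist, natural-enemy aggregate) are
#: derived from groups, never stored per record.
RESPONSE_TO_GROUP: Mapping[str, str] = {
    "plant_growth": "plant",
    "plant_reproduction": "plant",
    "plant_quality": "plant",
    "herbivore_abundance": "herbivore",
    "herbivore_damage": "herbivore",
    "herbivore_diversity": "herbivore",
    "predator_abundance": "natural_enemy",
    "predator_diversity": "natural_enemy",
    "parasitoid_abundance": "natural_enemy",
    "parasitoid_diversity": "natural_enemy",
    "parasitism": "natural_enemy",
    "weed_growth": "weed",
    "weed_diversity": "weed",
    "nematode_abundance": "nematode",
    "disease_spread": "disease",
    "disease_damage": "disease",
}

RESPONSE_CATEGORIES = tuple(RESPONSE_TO_GROUP)

ECOSYSTEMS = (
    "agroecosystem",
    "grassland",
    "forest",
    "old_field",
    "marine",
    "wetland",
    "shrubland",
)
LIFE_FORMS = ("herbaceous", "woody")
EXPERIMENT_TYPES = ("plot", "pot", "indoor")
CLIMATE_ZONES = ("temperate", "tropical", "indoor")


class SchemaError(ValueError):
    """A mandatory column is missing or the file layout is unusable."""


class MappingError(KeyError):
    """A response category outside the fixed category enum."""


@dataclass
class ObservationRecord:
    """One effect-size observation (a diverse-vs-mono contrast)."""

    obs_id: str
    study_id: str
    plant_species: str
    trophic_group: str
    response_category: str
    mean_treat: float
    mean_ctrl: float
    sd_treat: float
    sd_ctrl: float
    n_treat: int
    n_ctrl: int
    n_genotypes_added: int
    ecosystem: str
    life_form: str
    experiment_type: str
    climate_zone: str
    site_id: str | None = None
    plot_id: str | None = None
    latitude: float | None = None
    longitude: float | None = None


_COLUMNS = [f.name for f in fields(ObservationRecord)]
_NUMERIC = {
    "mean_treat": float,
    "mean_ctrl": float,
    "sd_treat": float,
    "sd_ctrl": float,
    "n_treat": int,
    "n_ctrl": int,
    "n_genotypes_added": int,
}
_MANDATORY = [c for c in _COLUMNS if c not in
              ("site_id", "plot_id", "latitude", "longitude")]


def map_response_to_group(response_category: str) -> tuple[str, bool]:
    """Map a response category to (trophic_group, antagonist_flag).

    The antagonist flag is True iff the group belongs to the plant-antagonist
    aggregate (herbivores, weeds, plant-feeding nematodes, plant diseases).
    """
    try:
        group = RESPONSE_TO_GROUP[response_category]
    except KeyError:
        raise MappingError(
            f"unknown response category: {response_category!r}"
        ) from None
    return group, group in ANTAGONIST_GROUPS


def validate_record(rec: ObservationRecord) -> list[str]:
    """Return the list of invariant violations for one record (empty = valid)."""
    problems: list[str] = []
    if rec.sd_treat < 0 or rec.sd_ctrl < 0:
        problems.append("negative SD")
    if rec.sd_treat == 0 and rec.sd_ctrl == 0:
        problems.append("both SDs zero (effect size undefined)")
    if rec.n_treat < 2 or rec.n_ctrl < 2:
        problems.append("insufficient df")
    elif rec.n_treat + rec.n_ctrl < 5:
        problems.append("insufficient df")
    if rec.n_genotypes_added < 1:
        problems.append("n_genotypes_added < 1")
    if rec.trophic_group not in TROPHIC_GROUPS:
        problems.append(f"unknown trophic group {rec.trophic_group!r}")
    if rec.response_category not in RESPONSE_TO_GROUP:
        problems.append(f"unknown response category {rec.response_category!r}")
    elif RESPONSE_TO_GROUP[rec.response_category] != rec.trophic_group:
        problems.append("response category inconsistent with trophic group")
    if rec.ecosystem not in ECOSYSTEMS:
        problems.append(f"unknown ecosystem {rec.ecosystem!r}")
    if rec.life_form not in LIFE_FORMS:
        problems.append(f"unknown life form {rec.life_form!r}")
    if rec.experiment_type not in EXPERIMENT_TYPES:
        problems.append(f"unknown experiment type {rec.experiment_type!r}")
    if rec.climate_zone not in CLIMATE_ZONES:
        problems.append(f"unknown climate zone {rec.climate_zone!r}")
    return problems


def _coerce_row(row: Mapping[str, object]) -> ObservationRecord | str:
    kwargs: dict[str, object] = {}
    for name in _COLUMNS:
        val = row.get(name)
        missing = val is None or (isinstance(val, float) and math.isnan(val)) \
            or (isinstance(val, str) and val == "")
        if name in _NUMERIC:
            if missing:
                return f"missing value in {name}"
            try:
                fval = float(val)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                return f"non-numeric value in {name}: {val!r}"
            if _NUMERIC[name] is int:
                if fval != int(fval):
                    return f"non-integer value in {name}: {val!r}"
                kwargs[name] = int(fval)
            else:
                kwargs[name] = fval
        elif name in ("latitude", "longitude"):
            kwargs[name] = None if missing else float(val)  # type: ignore[arg-type]
        elif name in ("site_id", "plot_id"):
            kwargs[name] = None if missing else str(val)
        else:
            if missing:
                return f"missing value in {name}"
            kwargs[name] = str(val)
    return ObservationRecord(**kwargs)  # type: ignore[arg-type]


def read_observations(
    path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[ObservationRecord], pd.DataFrame]:
    """Read and validate an observations CSV.

    Parameters
    ----------
    path
        CSV file (comma-separated, UTF-8, header row, "." decimal).
    schema
        Optional map from file column names to canonical names, for files
        with renamed columns.

    Returns
    -------
    records, rejects
        Valid records, and a DataFrame of rejected rows with a ``reason``
        column.  Rows are never silently dropped.
    """
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    records: list[ObservationRecord] = []
    rejects: list[dict] = []
    for _, row in df.iterrows():
        out = _coerce_row(row)
        if isinstance(out, str):
            rejects.append({**row.to_dict(), "reason": out})
            continue
        problems = validate_record(out)
        if problems:
            rejects.append({**row.to_dict(), "reason": "; ".join(problems)})
        else:
            records.append(out)
    return records, pd.DataFrame(rejects)


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Tabulate records with a stable column order."""
    return pd.DataFrame([vars(r) for r in records], columns=_COLUMNS)


def write_observations(records: Iterable[ObservationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def frame_to_records(df: pd.DataFrame) -> list[ObservationRecord]:
    recs = []
    for _, row in df.iterrows():
        out = _coerce_row(row)
        if isinstance(out, str):
            raise ValueError(out)
        recs.append(out)
    return recs


# ---------------------------------------------------------------------------
# SEM subsets: pairs and triples of co-measured effect sizes
# ---------------------------------------------------------------------------

#: Join key for "the same diversity contrast": finest key present in all
#: subsets.  Observations of the same group within a cell are combined by
#: inverse-variance weighting before pairing.
CONTRAST_KEY = ["study_id", "site_id", "n_genotypes_added"]


@dataclass
class PairedInteractionRecord:
    """Two co-measured effect sizes from the same study and contrast."""

    study_id: str
    lower_group: str
    upper_group: str
    g_lower: float
    v_lower: float
    g_upper: float
    v_upper: float
    n_genotypes_added: int
    log2_genotypes: float
    diversity_indicator: int = 1
    site_id: str | None = None


def _cell_table(effects: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    """Inverse-variance combine effect sizes per (contrast cell, group)."""
    sub = effects[effects["trophic_group"].isin(groups)].copy()
    if sub.empty:
        return pd.DataFrame(
            columns=[*CONTRAST_KEY, "trophic_group", "g", "v"])
    sub["site_id"] = sub["site_id"].fillna("")
    sub["_w"] = 1.0 / sub["v"]
    sub["_wg"] = sub["_w"] * sub["g"]
    agg = sub.groupby([*CONTRAST_KEY, "trophic_group"], as_index=False).agg(
        _w=("_w", "sum"), _wg=("_wg", "sum"))
    agg["g"] = agg["_wg"] / agg["_w"]
    agg["v"] = 1.0 / agg["_w"]
    return agg.drop(columns=["_w", "_wg"])


def build_pairs(
    effects: pd.DataFrame,
    lower_group: str | Sequence[str],
    upper_group: str | Sequence[str],
) -> pd.DataFrame:
    """Build the bi-trophic SEM subset.

    Parameters
    ----------
    effects
        Observation table augmented with effect-size columns ``g`` and ``v``
        (see :mod:`divmeta.effect_sizes`).
    lower_group, upper_group
        Trophic group (or groups to aggregate, e.g. the four antagonist
        groups) at each end of the interaction.

    Returns
    -------
    DataFrame with one row per (study, site, contrast) cell in which both
    groups were measured, columns ``g_lower, v_lower, g_upper, v_upper``,
    the contrast descriptors and ``log2_genotypes``.
    """
    lowers = [lower_group] if isinstance(lower_group, str) else list(lower_group)
    uppers = [upper_group] if isinstance(upper_group, str) else list(upper_group)
    lo = _cell_table(effects, lowers).drop(columns="trophic_group") \
        if len(lowers) > 1 else _cell_table(effects, lowers)
    up = _cell_table(effects, uppers).drop(columns="trophic_group") \
        if len(uppers) > 1 else _cell_table(effects, uppers)
    if len(lowers) == 1:
        lo = lo.drop(columns="trophic_group")
    if len(uppers) == 1:
        up = up.drop(columns="trophic_group")
    merged = lo.merge(up, on=CONTRAST_KEY, suffixes=("_lower", "_upper"))
    merged["log2_genotypes"] = np.log2(merged["n_genotypes_added"].astype(float))
    merged["diversity_indicator"] = (merged["n_genotypes_added"] >= 1).astype(int)
    merged = merged.sort_values(CONTRAST_KEY, kind="stable").reset_index(drop=True)
    merged.attrs["n_pairs"] = len(merged)
    merged.attrs["n_studies"] = merged["study_id"].nunique()
    return merged


def build_triples(effects: pd.DataFrame) -> pd.DataFrame:
    """Build the tri-trophic (natural enemy, herbivore, plant) SEM subset.

    One row per contrast cell where all three trophic levels were measured;
    the number of contributing studies is recorded in ``.attrs["n_studies"]``
    for audit against the source corpus.
    """
    parts = {}
    for name, group in [("enemy", "natural_enemy"),
                        ("herbivore", "herbivore"),
                        ("plant", "plant")]:
        t = _cell_table(effects, [group]).drop(columns="trophic_group")
        parts[name] = t.rename(columns={"g": f"g_{name}", "v": f"v_{name}"})
    merged = parts["enemy"].merge(parts["herbivore"], on=CONTRAST_KEY)
    merged = merged.merge(parts["plant"], on=CONTRAST_KEY)
    merged["log2_genotypes"] = np.log2(merged["n_genotypes_added"].astype(float))
    merged["diversity_indicator"] = 1
    merged = merged.sort_values(CONTRAST_KEY, kind="stable").reset_index(drop=True)
    merged.attrs["n_triples"] = len(merged)
    merged.attrs["n_studies"] = merged["study_id"].nunique()
    return merged
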
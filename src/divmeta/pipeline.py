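"""Stage orchestration: one engine, config-driven subsets, reproducible outputs.

``run_all`` executes validation -> effect sizes -> meta-regression (base
model, moderator models with LRTs, category estimates) -> genotype-number
trends -> piecewise SEM -> publication bias, writing CSV report tables plus
a JSON manifest (input hashes, config hash, package version) so a run can be
reproduced byte-identically.  Floating-point output is fixed at 6
significant digits.  Subgroup analyses are config filters over the same
engine, not bespoke code paths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, dataio, effect_sizes, publication_bias, trend_gls
from . import meta_regression as mr
from . import piecewise_sem as sem

_FLOAT_FMT = "%.6g"

AGGREGATE_LABELS = {"plant": "plant", "natural_enemy": "natural_enemy",
                    **{g: "antagonist" for g in dataio.ANTAGONIST_GROUPS}}


@dataclass
class PipelineConfig:
    observations: str
    tree: str | None = None
    out_dir: str = "divmeta_out"
    filters: Mapping[str, str] = field(default_factory=dict)
    moderators: Sequence[str] = ("ecosystem", "life_form",
                                 "experiment_type", "climate_zone")
    use_tree: bool = True
    alpha: float = 0.05
    seed: int = 20221127

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _components(cfg: PipelineConfig, phylo) -> list[str]:
    comps = ["tau2_study", "tau2_obs", "tau2_species_iid"]
    if phylo is not None:
        comps.insert(0, "tau2_species_phylo")
    return comps


def estimates_table(ests: Sequence[mr.CategoryEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "label": e.label, "effect": e.effect, "ci_low": e.ci_low,
        "ci_high": e.ci_high, "t": e.t, "p": e.p,
        "k_obs": e.k_obs, "k_studies": e.k_studies} for e in ests])


def group_estimates(effects: pd.DataFrame,
                    phylo=None,
                    components: Sequence[str] = ("tau2_study", "tau2_obs"),
                    alpha: float = 0.05,
                    seed: int = 20221127,
                    **fit_kwargs) -> tuple[pd.DataFrame, mr.MetaFit]:
    """Cell-means meta-regression per trophic group plus the antagonist,
    plant and natural-enemy aggregates (a second fit on the aggregated
    grouping, mirroring the integrated trophic-group variable)."""
    fit = mr.fit_meta(effects, moderators=("trophic_group",), intercept=False,
                      components=components, phylo=phylo, seed=seed,
                      **fit_kwargs)
    rows = estimates_table(mr.category_estimates(fit, alpha=alpha))
    agg = effects.copy()
    agg["trophic_group"] = agg["trophic_group"].map(AGGREGATE_LABELS)
    fit_agg = mr.fit_meta(agg, moderators=("trophic_group",), intercept=False,
                          components=components, phylo=phylo, seed=seed,
                          **fit_kwargs)
    agg_rows = estimates_table(mr.category_estimates(fit_agg, alpha=alpha))
    agg_rows = agg_rows[agg_rows["label"] == "trophic_group[antagonist]"]
    table = pd.concat([rows, agg_rows], ignore_index=True)
    table["label"] = table["label"].str.replace(
        r"trophic_group\[(.*)\]", r"\1", regex=True)
    return table, fit


def run_all(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- validate ----------------------------------------------------------
    records, rejects = dataio.read_observations(config.observations)
    frame = dataio.records_to_frame(records)
    for col, val in config.filters.items():
        frame = frame[frame[col] == val]
    frame = frame.reset_index(drop=True)
    _write(frame, out / "validated.csv")
    _write(rejects, out / "rejects.csv")

    # --- effect sizes ------------------------------------------------------
    effects = effect_sizes.add_effect_sizes(frame)
    _write(effects, out / "effects.csv")

    phylo = None
    if config.use_tree and config.tree:
        phylo = mr.phylo_correlation(config.tree)
    comps = [c for c in _components(config, phylo)
             if not c.startswith("tau2_species")
             or effects["plant_species"].nunique() > 1]

    # --- meta-regression ---------------------------------------------------
    cat_table, base_fit = group_estimates(
        effects, phylo=phylo, components=comps,
        alpha=config.alpha, seed=config.seed)
    _write(cat_table, out / "category_estimates.csv")
    _write(pd.DataFrame({
        "coef": base_fit.beta.index, "estimate": base_fit.beta.to_numpy(),
        "se": base_fit.se.to_numpy()}), out / "coefficients.csv")
    _write(pd.DataFrame(
        [{"component": k, "tau2": v}
         for k, v in base_fit.variance_components.items()]),
        out / "variance_components.csv")

    lrt_rows = []
    for moderator in config.moderators:
        sub = effects
        if moderator == "climate_zone":
            sub = effects[effects["climate_zone"] != "indoor"].reset_index(drop=True)
        if sub[moderator].nunique() < 2:
            continue
        red = mr.fit_meta(sub, moderators=("trophic_group",),
                          components=comps, phylo=phylo,
                          method="ml", seed=config.seed)
        full = mr.fit_meta(sub, moderators=("trophic_group", moderator),
                           intercept=False, components=comps, phylo=phylo,
                           method="ml", seed=config.seed)
        stat, df, p = mr.lrt(full, red)
        lrt_rows.append({"term": moderator, "lrt": stat, "df": df, "p": p,
                         "n_obs": full.n_obs})
    _write(pd.DataFrame(lrt_rows), out / "model_comparison.csv")

    # --- genotype-number trends -------------------------------------------
    antag = effects[effects["trophic_group"].isin(dataio.ANTAGONIST_GROUPS)]
    trend_fits = trend_gls.fit_trends(effects)
    if len(antag) >= 4 and antag["n_genotypes_added"].nunique() > 1:
        trend_fits["antagonist"] = trend_gls.fit_gls_varexp(
            trend_gls.log_genotypes(antag["n_genotypes_added"].to_numpy()),
            antag["g"].to_numpy(), group="antagonist")
    trend_table = pd.DataFrame([{
        "group": name, "slope": f.slope, "intercept": float(f.beta[0]),
        "delta": f.delta, "t": f.t_slope, "df": f.df_resid, "p": f.p_slope}
        for name, f in trend_fits.items()])
    _write(trend_table, out / "trend.csv")
    pooled = trend_fits["pooled"]
    grid = np.linspace(pooled.x.min(), pooled.x.max(), 25)
    _write(trend_gls.predict_with_band(pooled, grid, alpha=config.alpha),
           out / "trend_predictions.csv")

    # --- piecewise SEM -----------------------------------------------------
    pairs = dataio.build_pairs(effects, sorted(dataio.ANTAGONIST_GROUPS), "plant")
    sem_tables = {"paths": [], "dsep": [], "global": []}
    results = {}
    if len(pairs) >= 10 and pairs["log2_genotypes"].nunique() > 1:
        results["bi_trophic"] = sem.run_sem(sem.BI_TROPHIC, pairs)
    triples = dataio.build_triples(effects)
    if len(triples) >= 10 and triples["log2_genotypes"].nunique() > 1:
        results["tri_trophic"] = sem.run_sem(sem.TRI_TROPHIC, triples)
    for name, res in results.items():
        for pth in res.paths:
            sem_tables["paths"].append({
                "model": name, "source": pth.source, "target": pth.target,
                "estimate": pth.estimate, "se": pth.se, "t": pth.t, "p": pth.p})
        for cl in res.dsep_claims:
            sem_tables["dsep"].append({
                "model": name, "first": cl.first, "second": cl.second,
                "conditioning": "+".join(cl.conditioning), "p": cl.p})
        sem_tables["global"].append({
            "model": name, "fisher_c": res.fisher_c, "df": res.fisher_df,
            "p": res.fisher_p})
    _write(pd.DataFrame(sem_tables["paths"]), out / "sem_paths.csv")
    _write(pd.DataFrame(sem_tables["dsep"]), out / "sem_dsep.csv")
    _write(pd.DataFrame(sem_tables["global"]), out / "sem_global.csv")
    _write(pairs, out / "pairs.csv")
    _write(triples, out / "triples.csv")

    # --- publication bias --------------------------------------------------
    report = publication_bias.bias_report(
        effects, moderators=("trophic_group",), components=comps,
        phylo=phylo, seed=config.seed,
        alpha_one_tailed=config.alpha)
    _write(pd.DataFrame([vars(report)]), out / "bias.csv")

    # --- manifest ----------------------------------------------------------
    cfg_dict = {**vars(config), "filters": dict(config.filters),
                "moderators": list(config.moderators)}
    manifest = {
        "version": __version__,
        "inputs": {"observations": _sha256(Path(config.observations)),
                   **({"tree": _sha256(Path(config.tree))}
                      if config.tree else {})},
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "n_obs": int(len(effects)),
        "n_studies": int(effects["study_id"].nunique()),
        "tables": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    summary = {
        "category_estimates": cat_table.to_dict("records"),
        "trend": trend_table.to_dict("records"),
        "sem_paths": sem_tables["paths"],
        "bias": vars(report),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    return manifest
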
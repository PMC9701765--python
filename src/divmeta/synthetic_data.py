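"""Synthetic data with the exact statistical structure the analysis assumes.

The generator emulates a curated effect-size corpus: hundreds of studies
each contributing a handful of diverse-vs-monoculture contrasts across six
trophic groups, group-specific true mean effects, between-study /
between-species / within-study heterogeneity, phylogenetic correlation of
species effects on a simulated pure-birth tree, heteroscedastic sampling
variances driven by group sizes, co-measured trophic pairs/triples generated
from a linear DAG with known path coefficients, and optional
publication-bias censoring.

Each observation's true standardized difference is

.. math::

    \\theta = \\mu_{group} + b\\,\\log_2 G + u_{species} + u_{study} + u_{obs}

and two normal arms with that standardized difference are actually sampled,
so the effect-size formulas downstream face realistic noise.  A fast mode
draws the (g, v) pair directly from the sampling distribution for large
calibration runs.  One global random stream is forked per study, so adding
studies never perturbs earlier ones.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import effect_sizes as es
from .dataio import RESPONSE_TO_GROUP, TROPHIC_GROUPS
from .meta_regression import PhyloCorrelation, phylo_correlation

__all__ = ["SyntheticConfig", "CensorConfig", "simulate_tree",
           "simulate_observations", "simulate_trophic_links"]

_CATEGORIES_BY_GROUP: dict[str, list[str]] = {}
for cat, grp in RESPONSE_TO_GROUP.items():
    _CATEGORIES_BY_GROUP.setdefault(grp, []).append(cat)

_ECOSYSTEM_PROBS = {
    "agroecosystem": 0.55, "grassland": 0.12, "forest": 0.10,
    "old_field": 0.08, "marine": 0.05, "wetland": 0.05, "shrubland": 0.05,
}


@dataclass(frozen=True)
class CensorConfig:
    """Suppress nonsignificant results to emulate publication bias.

    An observation whose one-tailed z in ``direction`` misses the critical
    value is dropped with probability ``prob``.
    """

    prob: float = 0.8
    direction: str = "positive"   # or "negative"
    z_crit: float = 1.645


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth settings for the generator.

    Default true means echo the magnitudes of the real corpus (plants +0.35,
    natural enemies +0.75, herbivores -0.60; the other antagonist groups
    negative), with moderate between-study (0.10) and within-study (0.05)
    heterogeneity.
    """

    seed: int = 20221127
    n_studies: int = 150
    obs_per_study: tuple[int, int] = (2, 6)
    group_probs: Mapping[str, float] = field(default_factory=lambda: {
        "plant": 0.40, "herbivore": 0.25, "natural_enemy": 0.10,
        "weed": 0.06, "nematode": 0.04, "disease": 0.15})
    true_means: Mapping[str, float] = field(default_factory=lambda: {
        "plant": 0.35, "herbivore": -0.60, "natural_enemy": 0.75,
        "weed": -0.10, "nematode": -2.00, "disease": -1.10})
    genotype_slope: float = 0.0
    tau2_study: float = 0.10
    tau2_obs: float = 0.05
    tau2_species: float = 0.05
    phylo_signal: float = 0.5
    n_species: int = 40
    birth_rate: float = 1.0
    arm_n: tuple[int, int] = (5, 30)
    sd_range: tuple[float, float] = (0.5, 2.0)
    genotype_levels: tuple[int, ...] = (2, 3, 4, 6, 8)
    paths: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        ("diversity", "enemy"): 0.709,
        ("diversity", "herbivore"): -0.865,
        ("diversity", "plant"): 0.884,
        ("enemy", "herbivore"): -0.011,
        ("herbivore", "plant"): -0.025})
    link_noise_sd: float = 1.0
    censor: CensorConfig | None = None

    def __post_init__(self):
        probs = np.array([self.group_probs[g] for g in TROPHIC_GROUPS])
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("group probabilities must sum to 1")
        for name in ("tau2_study", "tau2_obs", "tau2_species"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.phylo_signal <= 1.0:
            raise ValueError("phylo_signal must lie in [0, 1]")
        if self.obs_per_study[0] > self.obs_per_study[1] or not self.genotype_levels:
            raise ValueError("empty range")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paths"] = {f"{a}->{b}": v for (a, b), v in self.paths.items()}
        return d


def simulate_tree(config: SyntheticConfig) -> str:
    """A pure-birth (Yule) species tree, tips sp_1..sp_n, seed-reproducible."""
    from dendropy.model import birthdeath
    import dendropy

    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _pyrandom.Random(config.seed)
    taxa = dendropy.TaxonNamespace(
        [f"sp_{i + 1}" for i in range(config.n_species)])
    tree = birthdeath.birth_death_tree(
        birth_rate=config.birth_rate, death_rate=0.0,
        num_extant_tips=config.n_species, taxon_namespace=taxa, rng=rng)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _species_effects(config: SyntheticConfig, tree: str | None,
                     rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    labels = [f"sp_{i + 1}" for i in range(config.n_species)]
    if config.tau2_species == 0:
        return np.zeros(config.n_species), labels
    if tree is not None and config.phylo_signal > 0:
        phylo = tree if isinstance(tree, PhyloCorrelation) else phylo_correlation(tree)
        R = phylo.subset(labels)
    else:
        R = np.eye(config.n_species)
    cov = config.tau2_species * (
        config.phylo_signal * R + (1 - config.phylo_signal) * np.eye(config.n_species))
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(config.n_species))
    return L @ rng.standard_normal(config.n_species), labels


def _draw_summaries(theta, n_t, n_c, sigma, rng, fast):
    """Two-arm summary statistics with standardized difference theta."""
    if fast:
        m = n_t + n_c - 2
        vd = (n_t + n_c) / (n_t * n_c) + theta**2 / (2.0 * (n_t + n_c))
        d = theta + np.sqrt(vd) * rng.standard_normal()
        # emit summaries that reproduce d exactly with unit SDs
        return 10.0 + d, 10.0, 1.0, 1.0
    ctrl = rng.normal(10.0 * sigma, sigma, size=n_c)
    treat = rng.normal(10.0 * sigma + theta * sigma, sigma, size=n_t)
    return (float(treat.mean()), float(ctrl.mean()),
            float(treat.std(ddof=1)), float(ctrl.std(ddof=1)))


def _moderators(rng: np.random.Generator) -> dict[str, str]:
    eco = rng.choice(list(_ECOSYSTEM_PROBS), p=list(_ECOSYSTEM_PROBS.values()))
    life = "woody" if eco in ("forest", "shrubland") or rng.random() < 0.1 \
        else "herbaceous"
    expt = rng.choice(["plot", "pot", "indoor"], p=[0.70, 0.25, 0.05])
    clim = "indoor" if expt == "indoor" \
        else ("temperate" if rng.random() < 0.8 else "tropical")
    return {"ecosystem": str(eco), "life_form": life,
            "experiment_type": expt, "climate_zone": clim}


def simulate_observations(
    config: SyntheticConfig,
    tree: str | PhyloCorrelation | None = None,
    fast: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Generate an observation table in the dataio schema plus ground truth.

    Returns ``(observations, truth)``; ``truth`` records every planted
    parameter and the per-observation true standardized differences, so
    recovery tests and subset bookkeeping have an oracle.  With ``fast=True``
    the (g, v)-relevant summaries are drawn from the sampling distribution
    of the effect size instead of per-subject arms.
    """
    ss = np.random.SeedSequence(config.seed)
    sp_seed, *study_seeds = ss.spawn(config.n_studies + 1)
    u_sp, sp_labels = _species_effects(config, tree,
                                       np.random.default_rng(sp_seed))
    groups = list(TROPHIC_GROUPS)
    probs = [config.group_probs[g] for g in groups]
    rows: list[dict] = []
    theta_truth: dict[str, float] = {}
    censored = 0
    for si, seed_i in enumerate(study_seeds):
        rng = np.random.default_rng(seed_i)
        study_id = f"study_{si + 1:04d}"
        sp_idx = int(rng.integers(config.n_species))
        mods = _moderators(rng)
        u_study = rng.normal(0.0, np.sqrt(config.tau2_study))
        n_obs = int(rng.integers(config.obs_per_study[0],
                                 config.obs_per_study[1] + 1))
        for oi in range(n_obs):
            grp = str(rng.choice(groups, p=probs))
            cat = str(rng.choice(_CATEGORIES_BY_GROUP[grp]))
            G = int(rng.choice(config.genotype_levels))
            u_obs = rng.normal(0.0, np.sqrt(config.tau2_obs))
            theta = (config.true_means[grp]
                     + config.genotype_slope * np.log2(G)
                     + u_sp[sp_idx] + u_study + u_obs)
            n_t = int(rng.integers(config.arm_n[0], config.arm_n[1] + 1))
            n_c = int(rng.integers(config.arm_n[0], config.arm_n[1] + 1))
            sigma = float(rng.uniform(*config.sd_range))
            m_t, m_c, s_t, s_c = _draw_summaries(theta, n_t, n_c, sigma, rng, fast)
            obs_id = f"{study_id}_obs{oi + 1}"
            if config.censor is not None:
                eff = es.smd_from_stats(m_t, m_c, s_t, s_c, n_t, n_c)
                z = eff.g / np.sqrt(eff.v)
                signif = z > config.censor.z_crit \
                    if config.censor.direction == "positive" \
                    else z < -config.censor.z_crit
                if not signif and rng.random() < config.censor.prob:
                    censored += 1
                    continue
            rows.append({
                "obs_id": obs_id, "study_id": study_id,
                "plant_species": sp_labels[sp_idx],
                "trophic_group": grp, "response_category": cat,
                "mean_treat": m_t, "mean_ctrl": m_c,
                "sd_treat": s_t, "sd_ctrl": s_c,
                "n_treat": n_t, "n_ctrl": n_c,
                "n_genotypes_added": G, **mods,
                "site_id": None, "plot_id": None,
                "latitude": None, "longitude": None,
            })
            theta_truth[obs_id] = float(theta)
    obs = pd.DataFrame(rows)
    truth = {
        "config": config.to_dict(),
        "species_effects": dict(zip(sp_labels, map(float, u_sp))),
        "theta": theta_truth,
        "n_censored": censored,
    }
    return obs, truth


def simulate_trophic_links(
    config: SyntheticConfig,
    n_studies: int | None = None,
    contrasts_per_study: tuple[int, int] = (1, 3),
    fast: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Co-measured (enemy, herbivore, plant) observations from a linear DAG.

    Per contrast with ``x = log2(added genotypes)`` the true standardized
    differences follow

    .. math::

        \\theta_E = a_{DE} x + u_E + \\varepsilon, \\quad
        \\theta_H = a_{DH} x + a_{EH}\\theta_E + u_H + \\varepsilon, \\quad
        \\theta_P = a_{DP} x + a_{HP}\\theta_H + u_P + \\varepsilon,

    with study-level intercepts ``u`` and exogenous noise of SD
    ``link_noise_sd``.  Every contrast yields three observation rows, so
    the pair/triple builders have a known planted co-measurement structure
    (recorded in the truth table).
    """
    n_studies = config.n_studies if n_studies is None else n_studies
    p = {f"{a}->{b}": val for (a, b), val in config.paths.items()}
    ss = np.random.SeedSequence((config.seed, 777))
    study_seeds = ss.spawn(n_studies)
    rows: list[dict] = []
    planted: list[dict] = []
    cat_for = {"natural_enemy": "predator_abundance",
               "herbivore": "herbivore_abundance",
               "plant": "plant_growth"}
    for si, seed_i in enumerate(study_seeds):
        rng = np.random.default_rng(seed_i)
        study_id = f"link_{si + 1:04d}"
        sp = f"sp_{int(rng.integers(config.n_species)) + 1}"
        mods = _moderators(rng)
        u = {n: rng.normal(0.0, np.sqrt(config.tau2_study))
             for n in ("enemy", "herbivore", "plant")}
        n_con = int(rng.integers(contrasts_per_study[0],
                                 contrasts_per_study[1] + 1))
        levels = rng.choice(config.genotype_levels, size=n_con, replace=False) \
            if n_con <= len(config.genotype_levels) \
            else rng.choice(config.genotype_levels, size=n_con)
        for G in np.atleast_1d(levels):
            x = np.log2(float(G))
            noise = rng.normal(0.0, config.link_noise_sd, size=3)
            th_e = p["diversity->enemy"] * x + u["enemy"] + noise[0]
            th_h = (p["diversity->herbivore"] * x
                    + p["enemy->herbivore"] * th_e + u["herbivore"] + noise[1])
            th_p = (p["diversity->plant"] * x
                    + p["herbivore->plant"] * th_h + u["plant"] + noise[2])
            theta = {"natural_enemy": th_e, "herbivore": th_h, "plant": th_p}
            for grp, th in theta.items():
                n_t = int(rng.integers(config.arm_n[0], config.arm_n[1] + 1))
                n_c = int(rng.integers(config.arm_n[0], config.arm_n[1] + 1))
                sigma = float(rng.uniform(*config.sd_range))
                m_t, m_c, s_t, s_c = _draw_summaries(th, n_t, n_c, sigma,
                                                     rng, fast)
                rows.append({
                    "obs_id": f"{study_id}_g{G}_{grp}", "study_id": study_id,
                    "plant_species": sp, "trophic_group": grp,
                    "response_category": cat_for[grp],
                    "mean_treat": m_t, "mean_ctrl": m_c,
                    "sd_treat": s_t, "sd_ctrl": s_c,
                    "n_treat": n_t, "n_ctrl": n_c,
                    "n_genotypes_added": int(G), **mods,
                    "site_id": None, "plot_id": None,
                    "latitude": None, "longitude": None,
                })
            planted.append({"study_id": study_id, "n_genotypes_added": int(G),
                            **{f"theta_{k}": float(v) for k, v in theta.items()}})
    obs = pd.DataFrame(rows)
    truth = {"config": config.to_dict(), "planted": pd.DataFrame(planted)}
    return obs, truth
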
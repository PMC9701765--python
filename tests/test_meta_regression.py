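"""REML meta-regression: phylogeny, closed forms, oracles, invariances."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from divmeta import meta_regression as mr
from divmeta import synthetic_data as syn
from divmeta import effect_sizes as es


# --- phylogenetic correlation ---------------------------------------------

def test_star_phylogeny_gives_identity():
    phylo = mr.phylo_correlation("(A:1,B:1,C:1,D:1);")
    assert np.allclose(phylo.R, np.eye(4))


def test_sister_tips_share_ninety_percent_depth():
    phylo = mr.phylo_correlation("((B:0.1,C:0.1):0.9,A:1.0);",
                                 species=["A", "B", "C"])
    assert phylo.R[1, 2] == pytest.approx(0.9, abs=1e-12)
    assert phylo.R[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(np.diag(phylo.R), 1.0)


def test_nonultrametric_tree_normalized_by_tip_depths():
    # shared depth 0.5; tip depths 1.5 and 0.7
    phylo = mr.phylo_correlation("((B:1.0,C:0.2):0.5,A:1.0);",
                                 species=["B", "C"])
    assert phylo.R[0, 1] == pytest.approx(0.5 / np.sqrt(1.5 * 0.7), abs=1e-12)


def test_bad_newick_raises_format_error():
    with pytest.raises(mr.PhyloFormatError):
        mr.phylo_correlation("((A:1,B:1;")
    with pytest.raises(mr.PhyloFormatError):
        mr.phylo_correlation("((A:1,A:1):1,B:2);")


# --- closed forms and oracles ---------------------------------------------

def test_all_tau_zero_is_inverse_variance_weighted_mean(toy_meta_table):
    fit = mr.fit_meta(toy_meta_table, moderators=(), intercept=True,
                      components=())
    w = 1.0 / toy_meta_table["v"].to_numpy()
    expected = np.sum(w * toy_meta_table["g"]) / np.sum(w)
    assert fit.beta.iloc[0] == pytest.approx(expected, abs=1e-10)
    assert fit.se.iloc[0] == pytest.approx(1 / np.sqrt(w.sum()), abs=1e-10)


def _reml_grid_oracle(y, v, study, tau2_grid):
    """Brute-force restricted likelihood over a 1-D tau2_study grid,
    written from the definition with generic linear algebra."""
    y = np.asarray(y, float)
    X = np.ones((len(y), 1))
    Z = pd.get_dummies(pd.Series(study)).to_numpy(float)
    lls = []
    for t2 in tau2_grid:
        V = np.diag(v) + t2 * Z @ Z.T
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        ll = -0.5 * ((len(y) - 1) * np.log(2 * np.pi)
                     + np.linalg.slogdet(V)[1]
                     + np.linalg.slogdet(XtViX)[1]
                     + r @ Vi @ r)
        lls.append(ll)
    return np.asarray(lls)


def test_reml_matches_grid_search_oracle(toy_meta_table):
    fit = mr.fit_meta(toy_meta_table, moderators=(), intercept=True,
                      components=("tau2_study",))
    grid = np.arange(0.0, 1.0, 1e-5)
    lls = _reml_grid_oracle(toy_meta_table["g"], toy_meta_table["v"],
                            toy_meta_table["study_id"], grid)
    t2_grid = grid[np.argmax(lls)]
    assert fit.variance_components["tau2_study"] == pytest.approx(
        t2_grid, abs=1e-4)
    assert fit.loglik == pytest.approx(lls.max(), abs=1e-6)


def test_identity_phylo_equivalent_to_iid_species(toy_meta_table):
    df = toy_meta_table.copy()
    df["plant_species"] = ["spA", "spA", "spB", "spB",
                           "spC", "spC", "spD", "spD"]
    ident = mr.PhyloCorrelation(("spA", "spB", "spC", "spD"), np.eye(4))
    f_phylo = mr.fit_meta(df, moderators=(), intercept=True,
                          components=("tau2_species_phylo",), phylo=ident)
    f_iid = mr.fit_meta(df, moderators=(), intercept=True,
                        components=("tau2_species_iid",))
    assert f_phylo.loglik == pytest.approx(f_iid.loglik, abs=1e-6)
    assert f_phylo.beta.iloc[0] == pytest.approx(f_iid.beta.iloc[0], abs=1e-6)


def test_against_metafor_rma_mv(tmp_path):
    """Independent oracle: rma.mv REML with effect sizes nested in studies.

    metafor's restricted likelihood includes a +0.5 log|X'X| constant;
    comparison adjusts for it.
    """
    rng = np.random.default_rng(42)
    n = 30
    study = np.repeat([f"s{i}" for i in range(10)], 3)
    v = rng.uniform(0.05, 0.3, n)
    y = (0.4 + rng.normal(0, np.sqrt(0.15), 10).repeat(3)
         + rng.normal(0, np.sqrt(0.05), n) + rng.normal(0, np.sqrt(v)))
    df = pd.DataFrame({"g": y, "v": v, "study_id": study, "obs": range(n)})
    csv = tmp_path / "toy.csv"
    df.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(metafor))
        d <- read.csv("{csv}")
        f <- rma.mv(g, v, random = ~1|study_id/obs, data=d, method="REML")
        cat(sprintf("%.8f %.8f %.8f %.8f\\n",
            coef(f), f$sigma2[1], f$sigma2[2], logLik(f)))
    """)
    rfile = tmp_path / "rma.R"
    rfile.write_text(script)
    out = subprocess.run(["Rscript", str(rfile)], capture_output=True,
                         text=True, check=True).stdout.split()
    b_ref, t2_st, t2_obs, ll_ref = map(float, out)
    fit = mr.fit_meta(df, moderators=(), intercept=True,
                      components=("tau2_study", "tau2_obs"))
    assert fit.beta.iloc[0] == pytest.approx(b_ref, abs=1e-5)
    assert fit.variance_components["tau2_study"] == pytest.approx(t2_st, abs=1e-5)
    assert fit.variance_components["tau2_obs"] == pytest.approx(t2_obs, abs=1e-5)
    assert fit.loglik + 0.5 * np.log(n) == pytest.approx(ll_ref, abs=1e-5)


# --- LRT --------------------------------------------------------------------

def test_lrt_identical_models(toy_meta_table):
    fit = mr.fit_meta(toy_meta_table, moderators=(), intercept=True,
                      components=("tau2_study",), method="ml")
    stat, df, p = mr.lrt(fit, fit)
    assert stat == 0.0 and df == 0 and p == 1.0


def test_lrt_rejects_reml_across_fixed_structures(small_effects):
    full = mr.fit_meta(small_effects, moderators=("trophic_group",))
    red = mr.fit_meta(small_effects, moderators=(), intercept=True)
    with pytest.raises(mr.UsageError):
        mr.lrt(full, red)


def test_lrt_rejects_different_data(toy_meta_table):
    f1 = mr.fit_meta(toy_meta_table, moderators=(), intercept=True,
                     method="ml")
    other = toy_meta_table.copy()
    other["g"] = other["g"] + 0.1
    f2 = mr.fit_meta(other, moderators=(), intercept=True, method="ml")
    with pytest.raises(mr.UsageError):
        mr.lrt(f1, f2)


def test_lrt_power_for_strong_moderator():
    """A +0.5 shift on half the observations is detected essentially always."""
    hits = 0
    reps = 60
    for r in range(reps):
        rng = np.random.default_rng(1000 + r)
        n = 200
        study = np.repeat([f"s{i}" for i in range(50)], 4)
        mod = rng.choice(["lo", "hi"], n)
        v = rng.uniform(0.05, 0.3, n)
        y = (0.5 * (mod == "hi")
             + rng.normal(0, np.sqrt(0.10), 50).repeat(4)
             + rng.normal(0, np.sqrt(v)))
        df = pd.DataFrame({"g": y, "v": v, "study_id": study, "mod": mod})
        full = mr.fit_meta(df, moderators=("mod",), intercept=True,
                           method="ml", n_restarts=0)
        red = mr.fit_meta(df, moderators=(), intercept=True,
                          method="ml", n_restarts=0)
        _, _, p = mr.lrt(full, red)
        hits += p < 0.05
    assert hits / reps > 0.80


# --- category estimates -----------------------------------------------------

def test_single_level_estimate_equals_coefficient(toy_meta_table):
    fit = mr.fit_meta(toy_meta_table, moderators=(), intercept=True,
                      components=("tau2_study",))
    (est,) = mr.category_estimates(fit)
    assert est.effect == pytest.approx(fit.beta.iloc[0])
    assert est.t == pytest.approx(fit.beta.iloc[0] / fit.se.iloc[0])
    assert est.ci_low < est.effect < est.ci_high
    assert est.k_obs == fit.n_obs and est.k_studies == fit.n_studies


def test_category_counts_follow_contrast_support(small_effects):
    fit = mr.fit_meta(small_effects, moderators=("trophic_group",))
    for e in mr.category_estimates(fit):
        grp = e.label.split("[")[1].rstrip("]")
        sub = small_effects[small_effects["trophic_group"] == grp]
        assert e.k_obs == len(sub)
        assert e.k_studies == sub["study_id"].nunique()


# --- invariances ------------------------------------------------------------

def test_row_permutation_invariance(small_effects):
    fit1 = mr.fit_meta(small_effects, moderators=("trophic_group",))
    rng = np.random.default_rng(5)
    shuffled = small_effects.sample(frac=1.0, random_state=5)
    fit2 = mr.fit_meta(shuffled, moderators=("trophic_group",))
    assert np.allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-10)
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)
    for k in fit1.variance_components:
        assert fit1.variance_components[k] == pytest.approx(
            fit2.variance_components[k], abs=1e-7)


def test_fit_is_local_optimum(toy_meta_table, small_effects):
    for frame in (toy_meta_table, small_effects):
        fit = mr.fit_meta(frame, moderators=(), intercept=True,
                          components=("tau2_study", "tau2_obs"))
        assert mr.check_local_optimum(fit, n_perturb=64, seed=11)


def test_rank_deficient_design_raises(small_effects):
    df = small_effects.copy()
    df["dup"] = df["trophic_group"]
    with pytest.raises(mr.DesignError):
        mr.fit_meta(df, moderators=("trophic_group", "dup"))


def test_species_missing_from_tree_warns(small_effects):
    phylo = mr.PhyloCorrelation(("sp_1",), np.eye(1))
    with pytest.warns(UserWarning, match="absent from tree"):
        mr.fit_meta(small_effects,
                    components=("tau2_species_phylo", "tau2_study"),
                    phylo=phylo)
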
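"""Multilevel mixed-effects meta-regression by restricted maximum likelihood.

The marginal model for the vector of effect sizes ``y`` with known sampling
variances ``v_i`` is

.. math::

    y \\sim N(X\\beta,\\; V), \\qquad
    V = \\mathrm{diag}(v_i)
      + \\tau^2_{sp,phylo}\\, Z_{sp} R Z_{sp}^\\top
      + \\tau^2_{sp,iid}\\, Z_{sp} Z_{sp}^\\top
      + \\tau^2_{study}\\, Z_{st} Z_{st}^\\top
      + \\tau^2_{obs}\\, I,

where ``R`` is a phylogenetic correlation matrix among plant species (shared
Brownian-motion branch length, unit diagonal), ``Z_sp`` and ``Z_st`` are
species and study incidence matrices, and the observation-level component
represents effect sizes nested within studies.  Variance components are
estimated by maximizing the restricted likelihood on a log scale
(non-negativity enforced); fixed effects are the GLS solution at the
optimum.  Wald inference uses t statistics with ``df = n_obs - p``.

Likelihood-ratio tests for fixed-effect terms must compare ML fits (REML
likelihoods are not comparable across fixed-effect structures); variance
components may be compared under REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "PhyloCorrelation",
    "MetaFit",
    "CategoryEstimate",
    "phylo_correlation",
    "build_design",
    "fit_meta",
    "lrt",
    "category_estimates",
    "check_local_optimum",
    "DesignError",
    "ConvergenceError",
    "UsageError",
    "PhyloFormatError",
]

_LOG2PI = np.log(2.0 * np.pi)
_EPS = 1e-10  # tau^2 offset on the log scale
_DEFAULT_SEED = 20221127

ALL_COMPONENTS = ("tau2_species_phylo", "tau2_species_iid",
                  "tau2_study", "tau2_obs")


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable fixed-effects design."""


class ConvergenceError(RuntimeError):
    """REML/ML optimizer failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class UsageError(ValueError):
    """Operation applied to incompatible fits (e.g. non-nested LRT)."""


class PhyloFormatError(ValueError):
    """Unparsable tree or duplicate tip labels."""


# ---------------------------------------------------------------------------
# Phylogenetic correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloCorrelation:
    """Correlation matrix among species under Brownian motion on a tree."""

    species_labels: tuple[str, ...]
    R: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, float)
        if R.shape != (len(self.species_labels),) * 2:
            raise ValueError("R dimensions do not match label count")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("R must have unit diagonal")
        if np.min(linalg.eigvalsh(R)) < -1e-10:
            raise ValueError("R is not positive semi-definite")

    def subset(self, species: Sequence[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.species_labels)}
        pos = [idx[s] for s in species]
        return self.R[np.ix_(pos, pos)]


def phylo_correlation(tree, species: Sequence[str] | None = None) -> PhyloCorrelation:
    """Brownian-motion correlation matrix from a Newick tree.

    The covariance of two tips is the branch length shared from the root
    (depth of their most recent common ancestor); rescaling by tip depths
    gives a correlation matrix with unit diagonal, valid for non-ultrametric
    trees as well.

    Parameters
    ----------
    tree
        Newick string, path to a Newick file, or a ``dendropy.Tree``.
    species
        Optional ordering of tip labels for the output; defaults to the
        tree's taxon order.  Every requested species must be a tip.
    """
    import dendropy

    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        try:
            if "(" in text:
                t = dendropy.Tree.get(data=text, schema="newick")
            else:
                t = dendropy.Tree.get(path=text, schema="newick")
        except Exception as exc:
            raise PhyloFormatError(f"cannot parse Newick tree: {exc}") from exc
    labels = [lf.taxon.label for lf in t.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise PhyloFormatError("duplicate tip labels in tree")
    # depth of every node from the root
    depth: dict = {}
    for node in t.preorder_node_iter():
        el = node.edge.length or 0.0
        depth[node] = (depth.get(node.parent_node, 0.0) + el) if node.parent_node else 0.0
    tips = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
    if species is None:
        species = labels
    else:
        missing = [s for s in species if s not in tips]
        if missing:
            raise PhyloFormatError(f"species not in tree: {missing}")
    n = len(species)
    pdm = t.phylogenetic_distance_matrix()
    dvec = np.array([depth[tips[s]] for s in species])
    if np.any(dvec <= 0):
        # star phylogeny / zero-depth tips: no shared history
        return PhyloCorrelation(tuple(species), np.eye(n))
    C = np.empty((n, n))
    for i, si in enumerate(species):
        C[i, i] = dvec[i]
        for jj in range(i + 1, n):
            dij = pdm.patristic_distance(tips[si].taxon, tips[species[jj]].taxon)
            C[i, jj] = C[jj, i] = 0.5 * (dvec[i] + dvec[jj] - dij)
    R = C / np.sqrt(np.outer(dvec, dvec))
    np.fill_diagonal(R, 1.0)
    return PhyloCorrelation(tuple(species), R)


# ---------------------------------------------------------------------------
# Fixed-effects design
# ---------------------------------------------------------------------------

def build_design(
    df: pd.DataFrame,
    terms: Sequence[str],
    intercept: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Build a fixed-effects design matrix from term names.

    Terms are column names; categorical (object/category) columns expand to
    indicator columns — cell-means coding without an intercept, treatment
    coding (first level dropped) with one.  ``"a:b"`` denotes an
    interaction (elementwise product of the two expansions).  Empty levels
    are dropped with a warning; a rank-deficient result raises
    :class:`DesignError` naming the aliased columns.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        blocks.append(np.ones((len(df), 1)))
        names.append("intercept")

    def expand(term: str, drop_first: bool) -> tuple[np.ndarray, list[str]]:
        col = df[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), drop_first=False)
            empty = [c for c in dummies.columns if dummies[c].sum() == 0]
            if empty:
                warnings.warn(f"dropping empty levels of {term}: {empty}")
                dummies = dummies.drop(columns=empty)
            if drop_first:
                dummies = dummies.iloc[:, 1:]
            return dummies.to_numpy(float), [f"{term}[{c}]" for c in dummies.columns]
        return col.to_numpy(float)[:, None], [term]

    for term in terms:
        # every categorical block after the first is treatment-coded, else
        # stacked cell-means sets would be aliased
        drop = bool(blocks)
        if ":" in term:
            a, b = term.split(":", 1)
            Xa, na = expand(a, drop)
            Xb, nb = expand(b, True)
            for j, nbj in enumerate(nb):
                blocks.append(Xa * Xb[:, [j]])
                names.extend(f"{nai}:{nbj}" for nai in na)
        else:
            Xt, nt = expand(term, drop)
            blocks.append(Xt)
            names.extend(nt)
    X = np.column_stack(blocks) if blocks else np.ones((len(df), 1))
    if not blocks:
        names = ["intercept"]
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = [names[j] for j in piv[r:]]
        raise DesignError(f"design matrix rank deficient; aliased: {aliased}")
    return X, names


# ---------------------------------------------------------------------------
# REML / ML machinery
# ---------------------------------------------------------------------------

@dataclass
class MetaFit:
    """A fitted multilevel meta-regression model."""

    beta: pd.Series
    se: pd.Series
    vcov_beta: np.ndarray
    variance_components: dict[str, float]
    loglik: float
    method: str
    n_obs: int
    n_studies: int
    n_species: int
    df_resid: int
    converged: bool
    free_components: tuple[str, ...]
    restart_lls: tuple[float, ...] = ()
    _X: np.ndarray = field(default=None, repr=False)
    _names: list[str] = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _v: np.ndarray = field(default=None, repr=False)
    _G: dict = field(default=None, repr=False)
    _study_ids: np.ndarray = field(default=None, repr=False)

    @property
    def restricted_loglik(self) -> float:
        if self.method != "reml":
            raise AttributeError("fit was not obtained by REML")
        return self.loglik

    @property
    def n_params(self) -> int:
        return len(self.beta) + len(self.free_components)


@dataclass(frozen=True)
class CategoryEstimate:
    """Mean effect for one category with t-based inference."""

    label: str
    effect: float
    se: float
    t: float
    ci_low: float
    ci_high: float
    p: float
    k_obs: int
    k_studies: int


def _component_matrices(
    df: pd.DataFrame,
    components: Sequence[str],
    phylo: PhyloCorrelation | None,
) -> dict[str, np.ndarray]:
    n = len(df)
    G: dict[str, np.ndarray] = {}
    need_species = any(c.startswith("tau2_species") for c in components)
    if need_species:
        sp = df["plant_species"].astype(str).to_numpy()
        sp_levels, sp_idx = np.unique(sp, return_inverse=True)
        Zsp = np.zeros((n, len(sp_levels)))
        Zsp[np.arange(n), sp_idx] = 1.0
    if "tau2_species_phylo" in components:
        if phylo is None:
            raise UsageError("tau2_species_phylo requested without a phylogeny")
        in_tree = np.isin(sp_levels, phylo.species_labels)
        if not in_tree.all():
            missing = list(sp_levels[~in_tree])
            warnings.warn(
                f"species absent from tree get iid component only: {missing}")
        Rfull = np.zeros((len(sp_levels), len(sp_levels)))
        present = np.where(in_tree)[0]
        if len(present):
            Rsub = phylo.subset(list(sp_levels[present]))
            Rfull[np.ix_(present, present)] = Rsub
        G["tau2_species_phylo"] = Zsp @ Rfull @ Zsp.T
    if "tau2_species_iid" in components:
        G["tau2_species_iid"] = Zsp @ Zsp.T
    if "tau2_study" in components:
        st = df["study_id"].astype(str).to_numpy()
        _, st_idx = np.unique(st, return_inverse=True)
        Zst = np.zeros((n, st_idx.max() + 1))
        Zst[np.arange(n), st_idx] = 1.0
        G["tau2_study"] = Zst @ Zst.T
    if "tau2_obs" in components:
        G["tau2_obs"] = np.eye(n)
    return G


def _ll_dense(V, X, y, method: str) -> float:
    """Profile (over beta) log-likelihood of y ~ N(X beta, V)."""
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    ViX = linalg.cho_solve((c, low), X, check_finite=False)
    Viy = linalg.cho_solve((c, low), y, check_finite=False)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    try:
        cx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    beta = linalg.cho_solve(cx, XtViy, check_finite=False)
    quad = float(y @ Viy - XtViy @ beta)
    n, p = X.shape
    if method == "reml":
        logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
        return -0.5 * ((n - p) * _LOG2PI + logdetV + logdetX + quad)
    return -0.5 * (n * _LOG2PI + logdetV + quad)


def _loglik(tau2: np.ndarray, G_list, D, X, y, method: str) -> float:
    V = np.diag(D)
    for t2, G in zip(tau2, G_list):
        if t2 > 0:
            V = V + t2 * G
    return _ll_dense(V, X, y, method)


def fit_meta(
    data: pd.DataFrame,
    moderators: Sequence[str] = ("trophic_group",),
    intercept: bool = False,
    components: Sequence[str] = ("tau2_study", "tau2_obs"),
    fixed_components: Mapping[str, float] | None = None,
    phylo: PhyloCorrelation | None = None,
    method: str = "reml",
    n_restarts: int = 1,
    seed: int = _DEFAULT_SEED,
    max_tau2: float = 100.0,
) -> MetaFit:
    """Fit the multilevel meta-regression model.

    Parameters
    ----------
    data
        Effect-size table with columns ``g`` (effect), ``v`` (sampling
        variance), ``study_id``, and any moderator columns; a
        ``plant_species`` column is required when species components are
        requested.
    moderators
        Fixed-effect terms (see :func:`build_design`).  The default fits
        trophic-group cell means.
    components
        Variance components to estimate, a subset of ``ALL_COMPONENTS``.
    fixed_components
        Components held at a given value (e.g. ``{"tau2_obs": 0.0}``)
        instead of estimated.
    phylo
        Phylogenetic correlation; required iff ``tau2_species_phylo`` is in
        ``components``.
    method
        ``"reml"`` (default) or ``"ml"``.
    n_restarts
        Extra optimizer starts from dispersed values; the best restricted
        likelihood wins, ties broken by the smallest total heterogeneity.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    fixed_components = dict(fixed_components or {})
    # canonical row order: makes every reported number exactly invariant to
    # the input permutation (the optimizer then sees identical matrices)
    sort_keys = [c for c in ("study_id", "plant_species", "g", "v")
                 if c in data.columns]
    data = data.sort_values(sort_keys, kind="stable").reset_index(drop=True)
    if data["study_id"].nunique() < 2:
        raise UsageError("need at least 2 studies")
    y = data["g"].to_numpy(float)
    D = data["v"].to_numpy(float)
    if np.any(D <= 0):
        raise ValueError("sampling variances must be positive")
    X, names = build_design(data, moderators, intercept=intercept)
    n, p = X.shape
    if n - p < 1:
        raise DesignError("residual df < 1")

    all_comp = list(components) + [c for c in fixed_components if c not in components]
    G = _component_matrices(data, all_comp, phylo)
    free = [c for c in components if c not in fixed_components]
    G_free = [G[c] for c in free]
    # fixed components fold into the diagonal-plus-known part
    D_eff = D.copy()
    base = np.zeros((n, n))
    for c, val in fixed_components.items():
        if val < 0:
            raise ValueError("variance components must be nonnegative")
        if val > 0:
            base = base + val * G[c]
    if base.any():
        # absorb into a constant matrix added to every V evaluation
        G_free = G_free + [base]
        const_idx = len(G_free) - 1
    else:
        const_idx = None

    def ll_at(tau2_free: np.ndarray) -> float:
        t2 = list(tau2_free)
        if const_idx is not None:
            t2 = t2 + [1.0]
        return _loglik(np.asarray(t2), G_free, D_eff, X, y, method)

    tau2_hat = np.zeros(len(free))
    restart_lls: list[float] = []
    converged = True
    if free:
        rng = np.random.default_rng(seed)
        vy = float(np.var(y)) or 1.0
        start0 = np.full(len(free), max(vy / (2 * len(free)), 1e-4))
        starts = [start0]
        for _ in range(n_restarts):
            starts.append(start0 * rng.uniform(0.05, 5.0, size=len(free)))
        best = None
        lo, hi = np.log(_EPS), np.log(max_tau2)
        for s in starts:
            theta0 = np.log(np.clip(s, _EPS, max_tau2))
            res = optimize.minimize(
                lambda th: -ll_at(np.exp(th) - _EPS),
                theta0, method="L-BFGS-B",
                bounds=[(lo, hi)] * len(free),
                options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
            )
            cand_tau2 = np.clip(np.exp(res.x) - _EPS, 0.0, None)
            cand_ll = ll_at(cand_tau2)
            restart_lls.append(cand_ll)
            if not np.isfinite(cand_ll):
                continue
            if best is None or cand_ll > best[0] + 1e-8 or (
                    abs(cand_ll - best[0]) <= 1e-8
                    and cand_tau2.sum() < best[1].sum()):
                best = (cand_ll, cand_tau2, res)
        if best is None:
            raise ConvergenceError("all optimizer starts failed", trace=restart_lls)
        ll_best, tau2_hat, res = best
        if not res.success and not np.isfinite(ll_best):
            raise ConvergenceError(str(res.message), trace=res)
        converged = bool(np.isfinite(ll_best))
    ll_final = ll_at(tau2_hat)

    # GLS solution at the optimum
    V = np.diag(D_eff)
    for t2, Gk in zip(tau2_hat, G_free[:len(free)]):
        V = V + t2 * Gk
    if const_idx is not None:
        V = V + G_free[const_idx]
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    ViX = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ ViX
    vcov = linalg.inv(XtViX)
    beta = vcov @ (ViX.T @ y)
    se = np.sqrt(np.diag(vcov))

    vc = {name: float(t2) for name, t2 in zip(free, tau2_hat)}
    vc.update({k: float(v_) for k, v_ in fixed_components.items()})

    n_species = data["plant_species"].nunique() if "plant_species" in data else 0
    return MetaFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        vcov_beta=vcov,
        variance_components=vc,
        loglik=float(ll_final),
        method=method,
        n_obs=n,
        n_studies=int(data["study_id"].nunique()),
        n_species=int(n_species),
        df_resid=n - p,
        converged=converged,
        free_components=tuple(free),
        restart_lls=tuple(restart_lls),
        _X=X, _names=names, _y=y, _v=D, _G=G,
        _study_ids=data["study_id"].astype(str).to_numpy(),
    )


def lrt(fit_full: MetaFit, fit_reduced: MetaFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, p).

    Fixed-effect comparisons must use ML fits; REML fits are accepted only
    when the fixed-effects structure is identical (variance-component tests).
    """
    if fit_full.n_obs != fit_reduced.n_obs or not np.array_equal(
            fit_full._y, fit_reduced._y):
        raise UsageError("fits are not on identical observation sets")
    if fit_full.method != fit_reduced.method:
        raise UsageError("fits use different likelihoods")
    if fit_full.method == "reml" and len(fit_full.beta) != len(fit_reduced.beta):
        raise UsageError(
            "REML likelihoods are not comparable across fixed-effect "
            "structures; refit both models by ML")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise UsageError("full model has fewer parameters than reduced model")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def category_estimates(
    fit: MetaFit,
    contrasts: Mapping[str, Sequence[float]] | None = None,
    alpha: float = 0.05,
) -> list[CategoryEstimate]:
    """Per-category mean effects with t statistics and CIs.

    With no explicit contrasts, every coefficient of a cell-means fit is
    reported (one estimate per category level).  A contrast is a coefficient
    combination ``c`` giving effect ``c'beta``; observation and study counts
    are taken over the rows the contrast loads on.
    """
    if contrasts is None:
        p = len(fit.beta)
        contrasts = {name: np.eye(p)[i] for i, name in enumerate(fit.beta.index)}
    df = fit.df_resid
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    out = []
    for label, cvec in contrasts.items():
        cvec = np.asarray(cvec, float)
        if cvec.shape != (len(fit.beta),):
            raise DesignError(f"contrast {label!r} has wrong length")
        eff = float(cvec @ fit.beta.to_numpy())
        var = float(cvec @ fit.vcov_beta @ cvec)
        if var <= 0:
            raise DesignError(f"contrast {label!r} is not estimable")
        se = np.sqrt(var)
        t = eff / se
        loaded = np.abs(fit._X @ cvec) > 1e-12
        out.append(CategoryEstimate(
            label=label, effect=eff, se=se, t=float(t),
            ci_low=eff - tcrit * se, ci_high=eff + tcrit * se,
            p=float(2.0 * stats.t.sf(abs(t), df)),
            k_obs=int(loaded.sum()),
            k_studies=int(len(np.unique(fit._study_ids[loaded]))),
        ))
    return out


def check_local_optimum(fit: MetaFit, n_perturb: int = 64,
                        scale: float = 0.5, seed: int = 0,
                        tol: float = 1e-6) -> bool:
    """Audit: the returned likelihood beats random perturbations of tau^2."""
    free = list(fit.free_components)
    if not free:
        return True
    rng = np.random.default_rng(seed)
    tau2 = np.array([fit.variance_components[c] for c in free])
    G_free = [fit._G[c] for c in free]
    base = np.zeros((fit.n_obs, fit.n_obs))
    for cname, val in fit.variance_components.items():
        if cname not in free and val > 0 and cname in fit._G:
            base = base + val * fit._G[cname]
    D = np.asarray(fit._v, float)

    def ll(t2):
        V = np.diag(D) + base
        for tk, Gk in zip(t2, G_free):
            V = V + tk * Gk
        return _ll_dense(V, fit._X, fit._y, fit.method)

    ll0 = ll(tau2)
    for _ in range(n_perturb):
        pert = tau2 * np.exp(rng.normal(0, scale, len(free))) \
            + rng.uniform(0, 0.05, len(free))
        if ll(np.clip(pert, 0, None)) > ll0 + tol:
            return False
    return True


def _ll_dense(V, X, y, method):
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    ViX = linalg.cho_solve((c, low), X, check_finite=False)
    Viy = linalg.cho_solve((c, low), y, check_finite=False)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    cx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
    beta = linalg.cho_solve(cx, XtViy, check_finite=False)
    quad = float(y @ Viy - XtViy @ beta)
    n, p = X.shape
    if method == "reml":
        logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
        return -0.5 * ((n - p) * _LOG2PI + logdetV + logdetX + quad)
    return -0.5 * (n * _LOG2PI + logdetV + quad)
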
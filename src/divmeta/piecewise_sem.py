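"""Piecewise structural equation models over effect-size subsets.

A piecewise SEM is specified as a DAG over named variables (an exogenous
diversity measure plus the SMDs of trophic groups).  Each endogenous node
gets one component model — a weighted linear mixed model with random
intercepts for studies (and any finer grouping present), prior weights
``1/v_i`` from the response's sampling variance, and the residual scale
fixed at 1 so the residual variance equals the supplied sampling variance.
Global fit is tested through the d-separation basis set: every non-adjacent
ordered pair, conditioned on the union of both nodes' parents, contributes
an independence claim; Fisher's C combines their p-values,

.. math::

    C = -2 \\sum_{i=1}^{k} \\ln p_i \\sim \\chi^2_{2k} .

The canonical DAGs are the bi-trophic chain (diversity -> antagonist ->
plant, plus the direct diversity -> plant edge) and the tri-trophic cascade
(diversity -> enemy/herbivore/plant, enemy -> herbivore, herbivore ->
plant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta_regression import fit_meta, UsageError

__all__ = [
    "SemSpec", "SemResult", "PathEstimate", "DsepClaim",
    "basis_set", "fit_component", "fishers_c", "run_sem",
    "BI_TROPHIC", "TRI_TROPHIC", "SemSpecError",
]


class SemSpecError(ValueError):
    """Cyclic graph or malformed SEM specification."""


@dataclass(frozen=True)
class SemSpec:
    """A DAG over named variables with per-node data-column bindings.

    ``columns`` maps node name -> (value column, variance column or None);
    exogenous nodes (no variance column) enter only as predictors.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    columns: Mapping[str, tuple[str, str | None]]

    def __post_init__(self):
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise SemSpecError(f"edge ({a}, {b}) uses unknown node")
        if self._topo_order() is None:
            raise SemSpecError("graph is cyclic")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(a for a, b in self.edges if b == node)

    def endogenous(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.parents(n))

    def _topo_order(self) -> list[str] | None:
        remaining = set(self.nodes)
        order: list[str] = []
        while remaining:
            free = [n for n in remaining
                    if not (set(self.parents(n)) & remaining)]
            if not free:
                return None
            for n in sorted(free, key=self.nodes.index):
                order.append(n)
                remaining.discard(n)
        return order

    def relabel(self, mapping: Mapping[str, str]) -> "SemSpec":
        return SemSpec(
            nodes=tuple(mapping.get(n, n) for n in self.nodes),
            edges=tuple((mapping.get(a, a), mapping.get(b, b))
                        for a, b in self.edges),
            columns={mapping.get(n, n): c for n, c in self.columns.items()},
        )


def _spec(nodes, edges, columns):
    return SemSpec(tuple(nodes), tuple(edges), dict(columns))


#: diversity -> antagonist -> plant with a direct diversity -> plant edge
BI_TROPHIC = _spec(
    ["diversity", "antagonist", "plant"],
    [("diversity", "antagonist"), ("diversity", "plant"),
     ("antagonist", "plant")],
    {"diversity": ("log2_genotypes", None),
     "antagonist": ("g_lower", "v_lower"),
     "plant": ("g_upper", "v_upper")},
)

#: diversity -> {enemy, herbivore, plant}, enemy -> herbivore, herbivore -> plant
TRI_TROPHIC = _spec(
    ["diversity", "enemy", "herbivore", "plant"],
    [("diversity", "enemy"), ("diversity", "herbivore"),
     ("diversity", "plant"), ("enemy", "herbivore"),
     ("herbivore", "plant")],
    {"diversity": ("log2_genotypes", None),
     "enemy": ("g_enemy", "v_enemy"),
     "herbivore": ("g_herbivore", "v_herbivore"),
     "plant": ("g_plant", "v_plant")},
)


@dataclass(frozen=True)
class PathEstimate:
    source: str
    target: str
    estimate: float
    se: float
    t: float
    p: float


@dataclass(frozen=True)
class DsepClaim:
    first: str
    second: str
    conditioning: tuple[str, ...]
    p: float | None = None


@dataclass
class SemResult:
    paths: list[PathEstimate]
    dsep_claims: list[DsepClaim]
    fisher_c: float | None
    fisher_df: int
    fisher_p: float | None
    component_fits: dict = field(default_factory=dict)

    def path(self, source: str, target: str) -> PathEstimate:
        for p in self.paths:
            if p.source == source and p.target == target:
                return p
        raise KeyError((source, target))

    def indirect_effect(self, chain: Sequence[str]) -> float:
        """Product of path coefficients along a chain of nodes."""
        out = 1.0
        for a, b in zip(chain[:-1], chain[1:]):
            out *= self.path(a, b).estimate
        return out


def basis_set(spec: SemSpec) -> list[DsepClaim]:
    """The d-separation basis: independence claims implied by the DAG.

    One claim per non-adjacent pair, ordered topologically (the earlier node
    tested against the later one), conditioning on the union of both nodes'
    parents.  Deterministic canonical ordering.
    """
    order = spec._topo_order()
    assert order is not None
    pos = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in spec.edges}
    claims = []
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if frozenset((a, b)) in adjacent:
                continue
            cond = tuple(sorted(
                (set(spec.parents(a)) | set(spec.parents(b))) - {a, b},
                key=pos.__getitem__))
            claims.append(DsepClaim(a, b, cond))
    return claims


def fit_component(
    data: pd.DataFrame,
    response: str,
    parents: Sequence[str],
    spec: SemSpec,
    random_groups: Sequence[str] = ("study_id",),
) -> tuple[dict[str, PathEstimate], object]:
    """One component model: weighted LMM for an endogenous node.

    The response SMD gets fixed prior weights ``1/v_i`` (the residual scale
    is fixed at 1 so the residual variance equals the sampling variance),
    a between-study intercept, and an observation-level heterogeneity
    component that absorbs exogenous noise beyond sampling error — without
    it the d-separation tests are anticonservative whenever true effects
    vary within studies.  Grouping factors absent from the subset are
    dropped.  Returns per-parent path estimates and the underlying fit.
    """
    ycol, vcol = spec.columns[response]
    if vcol is None:
        raise UsageError(f"{response!r} is exogenous")
    if len(data) < 10:
        raise UsageError("component model needs at least 10 rows")
    cols = {"g": data[ycol], "v": data[vcol], "study_id": data["study_id"]}
    mods = []
    for par in parents:
        pcol, pvcol = spec.columns[par]
        cols[f"x_{par}"] = data[pcol]
        mods.append(f"x_{par}")
    frame = pd.DataFrame(cols).reset_index(drop=True)
    components = ["tau2_study", "tau2_obs"]
    for gcol in random_groups:
        if gcol in ("study", "study_id"):
            continue
        if gcol in data.columns and data[gcol].notna().any() \
                and data[gcol].nunique() > 1:
            frame["plant_species"] = data[gcol].to_numpy()
            components.append("tau2_species_iid")
        else:
            warnings.warn(f"grouping factor {gcol!r} absent; dropped")
    fit = fit_meta(frame, moderators=mods, intercept=True,
                   components=components)
    ests = {}
    tdf = fit.df_resid
    for par in mods:
        name = f"{par}"
        # coefficient name as produced by build_design
        est = float(fit.beta[name])
        se = float(fit.se[name])
        t = est / se
        ests[par[2:]] = PathEstimate(
            source=par[2:], target=response, estimate=est, se=se,
            t=float(t), p=float(2 * stats.t.sf(abs(t), tdf)))
    return ests, fit


def fishers_c(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C over d-separation p-values: (C, df, p)."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        raise UsageError("no independence claims")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clipped to 1e-16")
        p = np.clip(p, 1e-16, 1.0)
    C = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return C, df, float(stats.chi2.sf(C, df))


def run_sem(
    spec: SemSpec,
    data: pd.DataFrame,
    random_groups: Sequence[str] = ("study_id",),
) -> SemResult:
    """Fit all component models, test the basis set, combine via Fisher's C.

    For a saturated DAG the basis set is empty: ``fisher_df = 0`` and no
    global test is emitted (C and p are ``None``).
    """
    paths: list[PathEstimate] = []
    fits: dict[str, object] = {}
    for node in spec.endogenous():
        try:
            ests, fit = fit_component(data, node, spec.parents(node), spec,
                                      random_groups=random_groups)
        except Exception as exc:
            raise RuntimeError(f"component model for {node!r} failed") from exc
        fits[node] = fit
        for par in spec.parents(node):
            paths.append(ests[par])

    claims = []
    for claim in basis_set(spec):
        # test: regress the claim's endogenous member on the other member
        # plus the conditioning set; Wald t p-value of the other member
        resp, other = claim.second, claim.first
        if spec.columns[resp][1] is None:
            resp, other = claim.first, claim.second
        ests, _ = fit_component(
            data, resp, [other, *claim.conditioning], spec,
            random_groups=random_groups)
        claims.append(DsepClaim(claim.first, claim.second,
                                claim.conditioning, p=ests[other].p))
    if claims:
        C, df, p = fishers_c([c.p for c in claims])
    else:
        C, df, p = None, 0, None
    return SemResult(paths=paths, dsep_claims=claims,
                     fisher_c=C, fisher_df=df, fisher_p=p,
                     component_fits=fits)
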
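"""Module evaluation: target distance, three-group ANOVA, drug-pair suggestion.

A biologically meaningful sensitivity module should sit close to the drug's
target(s) in the interaction network, and its alteration status should
stratify an *independent* response profile.  Three procedures:

* :func:`module_target_distance` — unweighted shortest-path distance from
  each module gene to the nearest drug target, averaged per side and overall;
* :func:`assign_groups` + :func:`anova_three_group` — samples are grouped as
  altered in decreased-sensitivity genes only / increased only / unaltered
  (both-sides samples are excluded by default), and a one-way ANOVA tests for
  response differences across the groups;
* :func:`suggest_drug_pairs` — two drugs whose final modules share genes with
  *opposite* side labels are candidate combination partners (an alteration
  that sensitizes to one drug while conferring resistance to the other).

:func:`benjamini_hochberg` applies the standard step-up FDR adjustment when
many modules are tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AlterationMatrix
from .objective import TwoSidedModule

logger = logging.getLogger(__name__)

__all__ = [
    "TargetSet",
    "GroupedResponse",
    "module_target_distance",
    "assign_groups",
    "anova_three_group",
    "suggest_drug_pairs",
    "benjamini_hochberg",
]

GROUPS = ("decreased_only", "increased_only", "unaltered", "excluded")


@dataclass(frozen=True)
class TargetSet:
    drug: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        if not self.targets:
            raise ValueError(f"empty target set for drug {self.drug!r}")


@dataclass(frozen=True)
class GroupedResponse:
    """Per-sample group label (disjoint and exhaustive) and response value."""

    labels: dict[str, str]  # sample -> group
    responses: dict[str, float]

    def group(self, name: str) -> list[float]:
        return [self.responses[s] for s, g in self.labels.items() if g == name]


@dataclass(frozen=True)
class DistanceReport:
    increased_mean: float  # nan when that side has no reachable gene
    decreased_mean: float
    overall_mean: float
    n_unreachable: int
    per_gene: dict[str, float]


def module_target_distance(
    M: TwoSidedModule, T: TargetSet, G: nx.Graph
) -> DistanceReport:
    """Mean hop distance from module genes to the nearest drug target.

    A gene's distance is the minimum unweighted shortest-path length to any
    target (0 if the gene is itself a target).  Genes unreachable from every
    target are excluded from the means and counted; unmapped targets are
    dropped with a warning.
    """
    targets = [t for t in T.targets if G.has_node(t)]
    for t in T.targets - set(targets):
        logger.warning("drug %s target %s not in network; dropped", T.drug, t)
    if not targets:
        return DistanceReport(math.nan, math.nan, math.nan, len(M.genes), {})

    # one BFS from all targets at once (multi-source)
    dist = nx.multi_source_dijkstra_path_length(G, set(targets), weight=None)
    per_gene: dict[str, float] = {}
    unreachable = 0
    for g in sorted(M.genes):
        if g in dist:
            per_gene[g] = float(dist[g])
        else:
            unreachable += 1
            if not G.has_node(g):
                logger.warning("module gene %s not in network", g)

    def mean_of(genes) -> float:
        vals = [per_gene[g] for g in genes if g in per_gene]
        return float(np.mean(vals)) if vals else math.nan

    report = DistanceReport(
        increased_mean=mean_of(M.increased),
        decreased_mean=mean_of(M.decreased),
        overall_mean=mean_of(M.genes),
        n_unreachable=unreachable,
        per_gene=per_gene,
    )
    if unreachable == len(M.genes):
        logger.warning("no module gene reachable from any target of %s", T.drug)
    return report


def assign_groups(
    M: TwoSidedModule,
    A: AlterationMatrix,
    responses=None,
    both_sides_group: bool = False,
) -> GroupedResponse:
    """Label each sample by its alteration status w.r.t. the module.

    Samples altered in genes of both sides do not fit the three-group design
    and are excluded by default (``both_sides_group=True`` keeps them as a
    fourth tested group instead).
    """
    inc = [g for g in M.increased if g in A.data.index]
    dec = [g for g in M.decreased if g in A.data.index]
    hit_inc = A.data.loc[inc].to_numpy().any(axis=0) if inc else np.zeros(A.n_samples, bool)
    hit_dec = A.data.loc[dec].to_numpy().any(axis=0) if dec else np.zeros(A.n_samples, bool)
    labels = {}
    for pos, s in enumerate(A.samples):
        i, d = bool(hit_inc[pos]), bool(hit_dec[pos])
        if i and d:
            labels[s] = "both_sides" if both_sides_group else "excluded"
        elif i:
            labels[s] = "increased_only"
        elif d:
            labels[s] = "decreased_only"
        else:
            labels[s] = "unaltered"
    if responses is None:
        responses = {s: math.nan for s in A.samples}
    else:
        responses = {s: float(responses[s]) for s in A.samples}
    return GroupedResponse(labels=labels, responses=responses)


def anova_three_group(gr: GroupedResponse, min_group_size: int = 2):
    """One-way fixed-effects ANOVA across the alteration-status groups.

    Returns (F, p); (nan, nan) when fewer than two groups reach
    ``min_group_size`` samples.
    """
    groups = [
        vals
        for name in ("decreased_only", "increased_only", "unaltered", "both_sides")
        for vals in [gr.group(name)]
        if len(vals) >= min_group_size
    ]
    if len(groups) < 2:
        return (math.nan, math.nan)
    if all(np.var(g) == 0 for g in groups):
        # zero within-group variance: the F ratio is undefined (0/0) or
        # degenerate-infinite; report not-testable
        return (math.nan, math.nan)
    f, p = stats.f_oneway(*groups)
    return (float(f), float(p))


def suggest_drug_pairs(
    modules_by_drug: dict[str, list],
    min_shared: int = 1,
    min_jaccard: float = 0.0,
) -> list[dict]:
    """Drug pairs sharing >= min_shared genes with opposite side labels.

    ``modules_by_drug`` maps a drug to its final modules (TwoSidedModule or
    ModuleSolution).  A gene witnesses a pair (d1, d2) when it is increased
    for one drug and decreased for the other.  Output is sorted by drug names
    and symmetric in the pair.
    """

    def sides(mods) -> tuple[frozenset, frozenset]:
        inc, dec = set(), set()
        for m in mods:
            mod = getattr(m, "module", m)
            inc |= mod.increased
            dec |= mod.decreased
        return frozenset(inc), frozenset(dec)

    merged = {d: sides(mods) for d, mods in modules_by_drug.items()}
    out = []
    drugs = sorted(merged)
    for i, d1 in enumerate(drugs):
        for d2 in drugs[i + 1 :]:
            inc1, dec1 = merged[d1]
            inc2, dec2 = merged[d2]
            witnesses = sorted((inc1 & dec2) | (dec1 & inc2))
            if len(witnesses) < min_shared or not witnesses:
                continue
            if min_jaccard > 0:
                union = (inc1 | dec1) | (inc2 | dec2)
                if not union or len(witnesses) / len(union) < min_jaccard:
                    continue
            out.append({"drug1": d1, "drug2": d2, "shared_genes": witnesses})
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjusted q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
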
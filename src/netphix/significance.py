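"""Candidate generation, permutation significance, maximal-module selection.

Candidates are the exact optima of one ILP per grid point (module size 1..k_max
x connectivity model x penalty option).  Each candidate's association with the
phenotype is assessed by permuting the phenotype values across samples
(alterations fixed), re-solving the *same* grid point, and recording the null
optima; the add-one estimator p = (1 + #{null >= observed}) / (1 + n_perm) is
never zero.  Finally only maximal significant modules are kept: a significant
module strictly contained (side labels respected) in another significant
module is redundant and dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .ilp import ModuleSolution, NetphixILP, SolverConfig
from .io import AlterationMatrix, PhenotypeProfile
from .objective import PenaltyScheme

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "SignificanceResult",
    "generate_candidates",
    "permutation_test",
    "select_final_modules",
]


@dataclass(frozen=True)
class CandidateSet:
    """One optimal module per grid point."""

    candidates: tuple[ModuleSolution, ...]
    errors: tuple[tuple[SolverConfig, str], ...] = ()

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class SignificanceResult:
    candidate: ModuleSolution
    null_objectives: tuple[float, ...]
    p_value: float
    n_permutations: int
    seed: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


def grid_configs(
    k_max: int,
    models=("combined", "separate"),
    penalties=(PenaltyScheme(),),
    base: SolverConfig | None = None,
) -> list[SolverConfig]:
    """The candidate grid: sizes 1..k_max x models x penalty options."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    base = base or SolverConfig()
    return [
        replace(base, k=k, model=m, penalty=pen)
        for m in models
        for pen in penalties
        for k in range(1, k_max + 1)
    ]


def generate_candidates(
    A: AlterationMatrix,
    w: PhenotypeProfile,
    G: nx.Graph,
    k_max: int,
    models=("combined", "separate"),
    penalties=(PenaltyScheme(),),
    base: SolverConfig | None = None,
) -> CandidateSet:
    """Solve every grid point; per-point failures are recorded, not fatal."""
    candidates, errors = [], []
    for cfg in grid_configs(k_max, models, penalties, base):
        try:
            sol = NetphixILP(A, w, G, cfg).solve()
            candidates.append(sol)
            logger.info(
                "grid k=%d model=%s pen=%s: obj=%.4f status=%s (%.2fs)",
                cfg.k, cfg.model, cfg.penalty.mode, sol.objective, sol.status,
                sol.solve_seconds,
            )
        except Exception as exc:  # noqa: BLE001 - per-point isolation
            logger.warning("grid point %s failed: %s", cfg, exc)
            errors.append((cfg, str(exc)))
    return CandidateSet(tuple(candidates), tuple(errors))


def permutation_test(
    candidate: ModuleSolution,
    A: AlterationMatrix,
    w: PhenotypeProfile,
    G: nx.Graph,
    n_permutations: int = 100,
    seed: int = 0,
) -> SignificanceResult:
    """Re-solve the candidate's grid point under permuted phenotypes.

    The constraint system is built once; only the objective changes per
    permutation.  Fully determined by ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    problem = NetphixILP(A, w, G, candidate.config)
    weights = w.values.reindex(A.samples).to_numpy(float)
    rng = np.random.default_rng(seed)
    nulls, n_failed = [], 0
    for _ in range(n_permutations):
        perm = rng.permutation(weights)
        try:
            nulls.append(problem.solve_with_weights(perm).objective)
        except Exception as exc:  # noqa: BLE001
            n_failed += 1
            logger.warning("permutation solve failed: %s", exc)
    if n_failed:
        logger.warning("%d/%d permutation solves failed", n_failed, n_permutations)
    if not nulls:
        raise RuntimeError("all permutation solves failed")
    n_ok = len(nulls)
    exceed = sum(1 for v in nulls if v >= candidate.objective - 1e-9)
    p = (1 + exceed) / (1 + n_ok)
    return SignificanceResult(
        candidate=candidate,
        null_objectives=tuple(nulls),
        p_value=p,
        n_permutations=n_ok,
        seed=seed,
        n_failed=n_failed,
    )


def select_final_modules(
    results,
    alpha: float = 0.05,
    respect_sides: bool = True,
    include_time_limited: bool = False,
) -> list[ModuleSolution]:
    """Keep significant, maximal modules.

    Among candidates with p < alpha, any module whose (side-labeled by
    default) gene set is a strict subset of another significant module's is
    dropped.  Output is ordered by descending objective, then lexicographic
    gene names — deterministic.
    """
    sig = [
        r for r in results
        if r.p_value < alpha
        and not r.candidate.module.is_empty()
        and (include_time_limited or r.candidate.status == "optimal")
    ]

    def key(r: SignificanceResult):
        m = r.candidate.module
        return frozenset(m.labeled_genes()) if respect_sides else frozenset(m.genes)

    # drop strict subsets of another significant module; deduplicate identical
    # gene sets keeping the best objective
    maximal = [r for r in sig if not any(key(r) < key(o) for o in sig)]
    dedup: dict[frozenset, SignificanceResult] = {}
    for r in maximal:
        gs = key(r)
        if gs not in dedup or r.candidate.objective > dedup[gs].candidate.objective:
            dedup[gs] = r
    final = [r.candidate for r in dedup.values()]
    final.sort(key=lambda s: (-s.objective, sorted(s.module.genes)))
    return final
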
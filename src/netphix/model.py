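"""Model / Results surface tying the pipeline together.

:class:`NetphixModel` holds the aligned data (alteration matrix, phenotype,
network) and the analysis options; :meth:`NetphixModel.fit` runs candidate
generation over the (k, connectivity model, penalty) grid, permutation
significance, and maximal-module selection, returning a
:class:`NetphixResults` with the final modules, their p-values, diagnostics
and a ``summary()`` table.

    >>> model = NetphixModel.from_dataframes(alterations_df, phenotype_series, G)
    >>> results = model.fit(k_max=3, n_permutations=100, seed=7)
    >>> print(results.summary())
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from . import io as nio
from .ilp import ModuleSolution, SolverConfig
from .objective import PenaltyScheme, cross_side_overlap
from .significance import (
    CandidateSet,
    SignificanceResult,
    generate_candidates,
    permutation_test,
    select_final_modules,
)

logger = logging.getLogger(__name__)

__all__ = ["NetphixModel", "NetphixResults"]


class NetphixModel:
    """Connected-set-cover association model for one phenotype profile.

    Parameters
    ----------
    alterations : AlterationMatrix
        Binary gene x sample incidence.
    phenotype : PhenotypeProfile
        Continuous per-sample response; z-scored here if not already
        normalized (set ``negate=True`` for raw IC50-style values where
        smaller means more sensitive).
    network : networkx.Graph
        Undirected gene interaction network.
    min_freq, max_freq : float
        Alteration-frequency filter applied to genes before solving.
    """

    def __init__(
        self,
        alterations: nio.AlterationMatrix,
        phenotype: nio.PhenotypeProfile,
        network: nx.Graph,
        *,
        negate: bool = False,
        min_freq: float = 0.01,
        max_freq: float = 1.0,
        require_in_network: bool = True,
    ) -> None:
        A, w = nio.align_samples(alterations, phenotype)
        if not w.normalized or negate:
            w = nio.normalize_phenotype(w, negate=negate)
        A = nio.filter_genes(
            A, network, min_freq=min_freq, max_freq=max_freq,
            require_in_network=require_in_network,
        )
        if A.n_genes == 0:
            raise nio.DegenerateInputError("no genes survive the filters")
        self.alterations = A
        self.phenotype = w
        self.network = network

    @classmethod
    def from_dataframes(
        cls,
        alterations: pd.DataFrame,
        phenotype: pd.Series,
        network: nx.Graph,
        **kwargs,
    ) -> "NetphixModel":
        return cls(
            nio.AlterationMatrix(alterations.astype(np.int8)),
            nio.PhenotypeProfile(phenotype.astype(float)),
            network,
            **kwargs,
        )

    @classmethod
    def from_files(
        cls,
        alterations_path,
        phenotype_path,
        network_path,
        *,
        min_edge_score: float = 0.0,
        **kwargs,
    ) -> "NetphixModel":
        return cls(
            nio.load_alterations(alterations_path),
            nio.load_phenotype(phenotype_path),
            nio.load_network(network_path, min_edge_score=min_edge_score),
            **kwargs,
        )

    def fit(
        self,
        k_max: int = 3,
        models=("combined", "separate"),
        penalty: PenaltyScheme | None = None,
        no_penalty_grid: bool = False,
        n_permutations: int = 100,
        alpha: float = 0.05,
        seed: int = 0,
        solver: SolverConfig | None = None,
    ) -> "NetphixResults":
        """Run candidates -> permutation test -> maximal selection."""
        t0 = time.perf_counter()
        penalties = [penalty or PenaltyScheme()]
        if no_penalty_grid:
            penalties.append(PenaltyScheme(mode="none", lam=0.0))
        base = solver or SolverConfig(seed=seed)
        candidates = generate_candidates(
            self.alterations, self.phenotype, self.network,
            k_max=k_max, models=models, penalties=penalties, base=base,
        )
        # one deterministic sub-seed per grid point
        ss = np.random.SeedSequence(seed)
        sub_seeds = [int(s) % (2**31) for s in ss.generate_state(max(len(candidates), 1))]
        sig_results = []
        for cand, sub in zip(candidates, sub_seeds):
            if cand.module.is_empty():
                continue  # nothing to test; cannot be significant
            sig_results.append(
                permutation_test(
                    cand, self.alterations, self.phenotype, self.network,
                    n_permutations=n_permutations, seed=sub,
                )
            )
        final = select_final_modules(sig_results, alpha=alpha)
        return NetphixResults(
            model=self,
            candidates=candidates,
            significance=tuple(sig_results),
            final_modules=tuple(final),
            alpha=alpha,
            seed=seed,
            n_permutations=n_permutations,
            fit_seconds=time.perf_counter() - t0,
        )


@dataclass(frozen=True)
class NetphixResults:
    """Fitted results: candidates, permutation p-values, final modules."""

    model: NetphixModel
    candidates: CandidateSet
    significance: tuple[SignificanceResult, ...]
    final_modules: tuple[ModuleSolution, ...]
    alpha: float
    seed: int
    n_permutations: int
    fit_seconds: float

    def p_value_of(self, sol: ModuleSolution) -> float:
        for r in self.significance:
            if r.candidate is sol or (
                r.candidate.module == sol.module and r.candidate.config == sol.config
            ):
                return r.p_value
        return float("nan")

    def summary(self) -> str:
        """Plain-text summary table of candidates and final modules."""
        lines = [
            "NETPHIX connected set cover association",
            "=" * 62,
            f"genes: {self.model.alterations.n_genes}   "
            f"samples: {self.model.alterations.n_samples}   "
            f"permutations: {self.n_permutations}   alpha: {self.alpha}",
            "",
            f"{'k':>2} {'model':<9} {'penalty':<10} {'objective':>10} "
            f"{'p':>8} {'status':<10} module",
            "-" * 62,
        ]
        for cand in self.candidates:
            p = self.p_value_of(cand)
            mod = _format_module(cand)
            lines.append(
                f"{cand.config.k:>2} {cand.config.model:<9} "
                f"{cand.config.penalty.mode:<10} {cand.objective:>10.4f} "
                f"{p:>8.4f} {cand.status:<10} {mod}"
            )
        lines += ["", f"final maximal modules (p < {self.alpha}): "
                  f"{len(self.final_modules)}"]
        for sol in self.final_modules:
            lines.append(
                f"  obj={sol.objective:.4f} p={self.p_value_of(sol):.4f} "
                f"{_format_module(sol)}"
            )
        lines.append(f"(fitted in {self.fit_seconds:.1f} s)")
        return "\n".join(lines)

    def to_records(self, drug: str | None = None) -> list[dict]:
        """One JSON-ready record per final module."""
        recs = []
        for sol in self.final_modules:
            rec = {
                "genes_increased": sorted(sol.module.increased),
                "genes_decreased": sorted(sol.module.decreased),
                "objective": sol.objective,
                "k": sol.config.k,
                "model": sol.config.model,
                "penalty": sol.config.penalty.mode,
                "penalty_lambda": sol.config.penalty.lam,
                "p_value": self.p_value_of(sol),
                "n_permutations": self.n_permutations,
                "seed": self.seed,
                "cross_side_overlap": cross_side_overlap(
                    sol.module, self.model.alterations
                ),
            }
            if drug is not None:
                rec = {"drug": drug, **rec}
            recs.append(rec)
        return recs

    def to_jsonl(self, path, drug: str | None = None) -> None:
        with open(path, "w") as fh:
            for rec in self.to_records(drug):
                fh.write(json.dumps(rec) + "\n")

    def to_frame(self) -> pd.DataFrame:
        """Candidate-level table (one row per grid point)."""
        rows = []
        for cand in self.candidates:
            rows.append(
                {
                    "k": cand.config.k,
                    "model": cand.config.model,
                    "penalty": cand.config.penalty.mode,
                    "objective": cand.objective,
                    "p_value": self.p_value_of(cand),
                    "status": cand.status,
                    "genes_increased": ",".join(sorted(cand.module.increased)),
                    "genes_decreased": ",".join(sorted(cand.module.decreased)),
                    "solve_seconds": cand.solve_seconds,
                }
            )
        return pd.DataFrame(rows)


def _format_module(sol: ModuleSolution) -> str:
    inc = "+" + ",".join(sorted(sol.module.increased)) if sol.module.increased else ""
    dec = "-" + ",".join(sorted(sol.module.decreased)) if sol.module.decreased else ""
    return " ".join(x for x in (inc, dec) if x) or "(empty)"
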
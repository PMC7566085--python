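"""Synthetic instances with a planted phenotype-associated subnetwork.

Each instance consists of a random scale-free (or Erdos-Renyi, or supplied)
gene network, a binary background alteration matrix, and a continuous
phenotype.  A connected module of a requested size is planted: a subset of
samples (``coverage_target`` of them) receives alterations in the planted
genes — partitioned round-robin in *exclusive* mode so that every covered
sample carries exactly one planted alteration, or sampled independently in
*overlapping* mode — and those covered samples have their phenotype drawn
from N(mu * direction, sigma^2) instead of N(0, sigma^2).  The phenotype is
then z-scored.  All randomness flows from a single seed.

This emulates drug screens where alterations in one functional subnetwork
drive sensitivity (or resistance) against a mutational background; it does
not reproduce real mutation-rate heterogeneity across genes or samples, nor
real interactome topology beyond the degree distribution of the chosen
random-graph model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    AlterationMatrix,
    PhenotypeProfile,
    normalize_phenotype,
    write_alterations,
    write_network,
    write_phenotype,
)
from .objective import TwoSidedModule

__all__ = ["SimulationParams", "SimulatedInstance", "simulate_instance", "recoverability_report"]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative model; defaults give a strongly recoverable signal.

    effect_size is the mean phenotype shift (in noise-sd units times
    noise_sd) of samples covered by the planted module; effect_size=0 yields
    a null instance for calibration.
    """

    n_genes: int = 150
    n_samples: int = 100
    network_model: str = "barabasi_albert"  # | erdos_renyi | from_file
    network: nx.Graph | None = None  # used with network_model='from_file'
    ba_m: int = 2
    er_p: float = 0.05
    background_rate: float = 0.05
    planted_size: int = 3
    planted_direction: str = "increased"  # | decreased | mixed
    coverage_target: float = 0.3
    exclusivity: str = "exclusive"  # | overlapping
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.planted_size <= self.n_genes:
            raise ValueError("planted_size must be in [1, n_genes]")
        if not 0 < self.background_rate < 1:
            raise ValueError("background_rate must be in (0, 1)")
        if not 0 <= self.coverage_target <= 1:
            raise ValueError("coverage_target must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.planted_direction not in ("increased", "decreased", "mixed"):
            raise ValueError(f"unknown direction {self.planted_direction!r}")
        if self.exclusivity not in ("exclusive", "overlapping"):
            raise ValueError(f"unknown exclusivity {self.exclusivity!r}")


@dataclass(frozen=True)
class SimulatedInstance:
    A: AlterationMatrix
    w: PhenotypeProfile
    G: nx.Graph
    planted: TwoSidedModule
    params: SimulationParams

    def write(self, outdir) -> None:
        """Write the three TSV artifacts plus a ground-truth JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alterations(self.A, outdir / "alterations.tsv")
        write_phenotype(self.w, outdir / "phenotype.tsv")
        write_network(self.G, outdir / "network.tsv")
        truth = {
            "planted_increased": sorted(self.planted.increased),
            "planted_decreased": sorted(self.planted.decreased),
            "params": {
                k: v for k, v in vars(self.params).items() if k != "network"
            },
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def _build_network(params: SimulationParams, rng: np.random.Generator) -> nx.Graph:
    names = [f"g{i:04d}" for i in range(params.n_genes)]
    if params.network_model == "from_file":
        if params.network is None:
            raise ValueError("network_model='from_file' requires a network")
        return params.network
    graph_seed = int(rng.integers(0, 2**31 - 1))
    if params.network_model == "barabasi_albert":
        G = nx.barabasi_albert_graph(params.n_genes, params.ba_m, seed=graph_seed)
    elif params.network_model == "erdos_renyi":
        G = nx.gnp_random_graph(params.n_genes, params.er_p, seed=graph_seed)
    else:
        raise ValueError(f"unknown network model {params.network_model!r}")
    G = nx.relabel_nodes(G, dict(enumerate(names)))
    for _, _, d in G.edges(data=True):
        d["score"] = 1.0
    return G


def _random_connected_subgraph(
    G: nx.Graph, size: int, rng: np.random.Generator, max_tries: int = 200
) -> list[str]:
    """Grow a connected gene set by a random walk on the frontier."""
    nodes = sorted(G.nodes)
    for _ in range(max_tries):
        current = [nodes[rng.integers(len(nodes))]]
        frontier = sorted(G.neighbors(current[0]))
        while len(current) < size and frontier:
            nxt = frontier[rng.integers(len(frontier))]
            current.append(nxt)
            frontier = sorted(set(frontier) | set(G.neighbors(nxt)) - set(current))
            frontier = [f for f in frontier if f not in current]
        if len(current) == size:
            return current
    raise RuntimeError(f"could not grow a connected subgraph of size {size}")


def simulate_instance(params: SimulationParams) -> SimulatedInstance:
    """Generate one fully seed-determined instance."""
    rng = np.random.default_rng(params.seed)
    G = _build_network(params, rng)
    planted = _random_connected_subgraph(G, params.planted_size, rng)

    genes = sorted(G.nodes)
    samples = [f"s{i:04d}" for i in range(params.n_samples)]
    n, m = len(genes), params.n_samples
    gidx = {g: i for i, g in enumerate(genes)}

    # background alterations
    A = (rng.random((n, m)) < params.background_rate).astype(np.int8)

    # planted coverage: a fixed fraction of samples, assigned to planted genes
    n_cov = int(round(params.coverage_target * m))
    covered = rng.choice(m, size=n_cov, replace=False)
    planted_rows = [gidx[g] for g in planted]
    if params.exclusivity == "exclusive":
        # wipe background on planted genes so coverage is exactly one gene each
        A[planted_rows, :] = 0
        for j, p in enumerate(covered):
            A[planted_rows[j % len(planted_rows)], p] = 1
    else:
        A[planted_rows, :] = 0
        for p in covered:
            hits = rng.random(len(planted_rows)) < 0.5
            if not hits.any():
                hits[rng.integers(len(planted_rows))] = True
            for j in np.flatnonzero(hits):
                A[planted_rows[j], p] = 1

    # direction assignment
    if params.planted_direction == "mixed" and len(planted) > 1:
        half = len(planted) // 2
        inc, dec = planted[:half] or planted[:1], planted[half:]
        if not inc:
            inc, dec = planted[:1], planted[1:]
    elif params.planted_direction == "decreased":
        inc, dec = [], planted
    else:
        inc, dec = planted, []
    module = TwoSidedModule(increased=frozenset(inc), decreased=frozenset(dec))

    # phenotype: shifted for covered samples, direction by covering gene's side
    pheno = rng.normal(0.0, params.noise_sd, size=m)
    shift = params.effect_size * params.noise_sd
    inc_rows = [gidx[g] for g in inc]
    dec_rows = [gidx[g] for g in dec]
    cov_inc = A[inc_rows].any(axis=0) if inc_rows else np.zeros(m, bool)
    cov_dec = A[dec_rows].any(axis=0) if dec_rows else np.zeros(m, bool)
    pheno = pheno + shift * cov_inc - shift * cov_dec

    Amat = AlterationMatrix(pd.DataFrame(A, index=genes, columns=samples))
    w = PhenotypeProfile(pd.Series(pheno, index=samples))
    if np.std(pheno) > 1e-12:
        w = normalize_phenotype(w)
    return SimulatedInstance(Amat, w, G, module, params)


def recoverability_report(
    inst: SimulatedInstance,
    found,
    direction_aware: bool = False,
) -> tuple[float, float, float]:
    """Precision, recall and F1 of a recovered module against the planted truth.

    ``found`` is a TwoSidedModule or a ModuleSolution.  By default genes are
    compared direction-agnostically (union of both sides); with
    ``direction_aware`` the side labels must match too.
    """
    module = getattr(found, "module", found)
    if direction_aware:
        f = module.labeled_genes()
        t = inst.planted.labeled_genes()
    else:
        f = module.genes
        t = inst.planted.genes
    if not f:
        return (0.0, 0.0, 0.0)
    tp = len(f & t)
    precision = tp / len(f)
    recall = tp / len(t) if t else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return (precision, recall, f1)
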
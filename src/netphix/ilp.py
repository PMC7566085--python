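"""Exact ILP for the maximum-objective connected two-sided module.

Decision variables, per instance:

* ``x[g, side]``  — gene g selected on the increased / decreased side,
* ``y[p, side]``  — sample p covered by that side's selected genes,
* ``r[g, comp]``  — g is the flow root of a required connected component,
* ``t[comp]``     — that component is nonempty,
* ``f[arc, comp]``— single-commodity flow on directed network arcs.

Coverage is tied to selection from both directions (``y <= sum of selected
altered genes``; ``y >= x_g`` for each selected altered gene), so y is the
coverage indicator at any optimum.  The penalized objective is linear:

    sum_sides sum_p (w_s(p) + pt_s(p)) * y[p,s]  -  pt_s(p) * c(p,s)

with ``c(p,s) = sum_{g altered in p} x[g,s]`` — algebraically identical to
W(S) = sum_{covered} w(p) - pt(p)(c(p,S)-1) because c = 0 off coverage.

Connectivity uses single-commodity flow: each required component (one for
the union under the *combined* model, one per side under *separate*) elects
exactly one selected root when nonempty; every other selected gene must
absorb one unit of flow that can only travel along network edges whose head
is selected, which forces the selected genes to induce a connected subgraph.

The backend is the HiGHS mixed-integer solver behind
:func:`scipy.optimize.milp`; it proves optimality to ``mip_gap`` and honors
``time_limit``.  :func:`brute_force_best` is an independent enumeration
oracle for small instances.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .io import AlterationMatrix, PhenotypeProfile
from .objective import PenaltyScheme, TwoSidedModule, two_sided_objective

__all__ = [
    "SolverConfig",
    "ModuleSolution",
    "NetphixILP",
    "build_ilp",
    "solve",
    "brute_force_best",
    "module_is_connected",
]

SIDES = ("increased", "decreased")


class BuildError(ValueError):
    """Inputs cannot be assembled into a model (misalignment, missing genes)."""


class SolverError(RuntimeError):
    """The MIP backend failed."""


@dataclass(frozen=True)
class SolverConfig:
    """Parameters of one candidate-generation solve.

    k is the *upper bound* on the total number of genes across both sides
    (``exact_size=True`` forces exactly k, for parity experiments).  model
    selects the connectivity contract: 'combined' requires the union of both
    sides to induce one connected subgraph, 'separate' requires each
    nonempty side to be connected on its own.  ``sides`` restricts the
    search direction — e.g. ``("increased",)`` when the association
    direction is known, as in planted-signal simulation studies.
    """

    k: int = 3
    model: str = "combined"
    penalty: PenaltyScheme = field(default_factory=PenaltyScheme)
    time_limit: float = 600.0
    mip_gap: float = 1e-6
    backend: str = "highs"
    seed: int = 0
    exact_size: bool = False
    sides: tuple[str, ...] = SIDES

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.sides or any(s not in SIDES for s in self.sides):
            raise ValueError(f"sides must be a nonempty subset of {SIDES}")
        if self.model not in ("combined", "separate"):
            raise ValueError(f"unknown connectivity model {self.model!r}")
        if self.time_limit <= 0:
            raise ValueError("time_limit must be positive")
        if not 0 <= self.mip_gap < 1:
            raise ValueError("mip_gap must be in [0, 1)")


@dataclass(frozen=True)
class ModuleSolution:
    module: TwoSidedModule
    objective: float
    config: SolverConfig
    status: str  # optimal | feasible_time_limited | infeasible
    solve_seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.module.size > self.config.k:
            raise ValueError("module exceeds the size bound k")


def module_is_connected(M: TwoSidedModule, G: nx.Graph, model: str) -> bool:
    """Check the connectivity contract of a module by graph traversal."""

    def connected(genes: frozenset[str]) -> bool:
        if len(genes) <= 1:
            return all(G.has_node(g) for g in genes)
        sub = G.subgraph(genes)
        return sub.number_of_nodes() == len(genes) and nx.is_connected(sub)

    if model == "combined":
        return connected(M.genes)
    return connected(M.increased) and connected(M.decreased)


class NetphixILP:
    """One ILP instance; reusable across phenotype permutations.

    The constraint system depends only on the alteration matrix, the network
    and the config; the phenotype enters through the objective vector alone,
    so re-solving under a permuted phenotype (:meth:`solve_with_weights`)
    reuses the assembled sparse constraints.
    """

    def __init__(
        self,
        A: AlterationMatrix,
        w: PhenotypeProfile,
        G: nx.Graph,
        cfg: SolverConfig,
    ) -> None:
        if list(w.samples) != list(A.samples):
            raise BuildError("phenotype samples are not aligned with the matrix")
        missing = [g for g in A.genes if not G.has_node(g)]
        if missing:
            raise BuildError(
                f"{len(missing)} gene(s) absent from the network, e.g. {missing[:5]}"
            )
        self.A = A
        self.w = w
        self.G = G
        self.cfg = cfg
        self.genes = list(A.genes)
        self.samples = list(A.samples)
        self._Anp = A.data.to_numpy(np.int8)
        self._weights = w.values.to_numpy(float)
        self._build_structure()

    # -- variable layout ----------------------------------------------------

    def _build_structure(self) -> None:
        n, m = self._Anp.shape
        k = self.cfg.k
        genes = self.genes
        gidx = {g: i for i, g in enumerate(genes)}

        # directed arcs over network edges restricted to matrix genes
        arcs: list[tuple[int, int]] = []
        for u, v in self.G.subgraph(genes).edges():
            arcs.append((gidx[u], gidx[v]))
            arcs.append((gidx[v], gidx[u]))
        self._arcs = arcs

        comps = ("all",) if self.cfg.model == "combined" else SIDES
        self._comps = comps

        # x[side, gene], y[side, sample], r[comp, gene], t[comp], f[comp, arc]
        ofs = 0
        self._x = {s: ofs + i * n for i, s in enumerate(SIDES)}
        ofs += 2 * n
        self._y = {s: ofs + i * m for i, s in enumerate(SIDES)}
        ofs += 2 * m
        self._r = {c: ofs + i * n for i, c in enumerate(comps)}
        ofs += len(comps) * n
        self._t = {c: ofs + i for i, c in enumerate(comps)}
        ofs += len(comps)
        self._f = {c: ofs + i * len(arcs) for i, c in enumerate(comps)}
        ofs += len(comps) * len(arcs)
        self.n_vars = ofs

        integrality = np.ones(ofs)
        integrality[min(self._f.values()) if arcs else ofs:] = 0  # flows continuous
        lb = np.zeros(ofs)
        ub = np.ones(ofs)
        for c in comps:
            f0 = self._f[c]
            ub[f0 : f0 + len(arcs)] = max(k - 1, 0)
        for s in SIDES:
            if s not in self.cfg.sides:  # direction disabled: no selections
                ub[self._x[s] : self._x[s] + n] = 0.0
        self._integrality = integrality
        self._bounds = Bounds(lb, ub)

        rows, cols, vals = [], [], []
        con_lb, con_ub = [], []
        nrow = 0

        def add(entries, lo, hi):
            nonlocal nrow
            for col, val in entries:
                rows.append(nrow)
                cols.append(col)
                vals.append(val)
            con_lb.append(lo)
            con_ub.append(hi)
            nrow += 1

        INF = np.inf

        # a gene sits on at most one side
        for g in range(n):
            add([(self._x["increased"] + g, 1.0), (self._x["decreased"] + g, 1.0)], -INF, 1.0)

        # cardinality over both sides
        card = [(self._x[s] + g, 1.0) for s in SIDES for g in range(n)]
        if self.cfg.exact_size:
            add(card, float(k), float(k))
        else:
            add(card, -INF, float(k))

        # coverage: y_p,s <= sum of selected altered genes; y_p,s >= each x_g,s
        alt_by_sample = [np.flatnonzero(self._Anp[:, p]) for p in range(m)]
        for s in SIDES:
            for p in range(m):
                gs = alt_by_sample[p]
                entries = [(self._y[s] + p, 1.0)] + [(self._x[s] + g, -1.0) for g in gs]
                add(entries, -INF, 0.0)
                for g in gs:
                    add([(self._x[s] + g, 1.0), (self._y[s] + p, -1.0)], -INF, 0.0)

        # connectivity per required component
        in_arcs: dict[int, list[int]] = {g: [] for g in range(n)}
        out_arcs: dict[int, list[int]] = {g: [] for g in range(n)}
        for a, (i, j) in enumerate(arcs):
            out_arcs[i].append(a)
            in_arcs[j].append(a)

        for c in comps:
            if c == "all":
                u_of = lambda g: [(self._x[s] + g, 1.0) for s in SIDES]
            else:
                u_of = lambda g, side=c: [(self._x[side] + g, 1.0)]
            r0, t0, f0 = self._r[c], self._t[c], self._f[c]
            # root must be selected; exactly one root iff nonempty
            for g in range(n):
                add([(r0 + g, 1.0)] + [(col, -v) for col, v in u_of(g)], -INF, 0.0)
                add(u_of(g) + [(t0, -1.0)], -INF, 0.0)
            add([(r0 + g, 1.0) for g in range(n)] + [(t0, -1.0)], 0.0, 0.0)
            # arc capacity gated on the head's selection
            for a, (i, j) in enumerate(arcs):
                add([(f0 + a, 1.0)] + [(col, -(k - 1) * v) for col, v in u_of(j)], -INF, 0.0)
            # balance: inflow - outflow >= u_g - k * r_g
            for g in range(n):
                entries = (
                    [(f0 + a, 1.0) for a in in_arcs[g]]
                    + [(f0 + a, -1.0) for a in out_arcs[g]]
                    + [(col, -v) for col, v in u_of(g)]
                    + [(r0 + g, float(k))]
                )
                add(entries, 0.0, INF)

        mat = sp.csr_array(
            (vals, (rows, cols)), shape=(nrow, self.n_vars), dtype=float
        )
        self._constraints = LinearConstraint(mat, np.array(con_lb), np.array(con_ub))

    # -- objective ----------------------------------------------------------

    def _objective_vector(self, weights: np.ndarray) -> np.ndarray:
        n, m = self._Anp.shape
        c = np.zeros(self.n_vars)
        for s, sign in (("increased", 1.0), ("decreased", -1.0)):
            ws = sign * weights
            pt = self.cfg.penalty.per_sample(ws)
            c[self._y[s] : self._y[s] + m] = ws + pt
            # each selected gene pays pt(p) for every sample it alters
            c[self._x[s] : self._x[s] + n] = -(self._Anp * pt[None, :]).sum(axis=1)
        return -c  # scipy minimizes

    # -- solving ------------------------------------------------------------

    def solve_with_weights(self, weights: np.ndarray) -> ModuleSolution:
        t0 = time.perf_counter()
        res = milp(
            c=self._objective_vector(np.asarray(weights, float)),
            constraints=self._constraints,
            integrality=self._integrality,
            bounds=self._bounds,
            options={
                "time_limit": self.cfg.time_limit,
                "mip_rel_gap": self.cfg.mip_gap,
                "disp": False,
            },
        )
        elapsed = time.perf_counter() - t0
        if res.status == 2:
            return ModuleSolution(
                TwoSidedModule(), float("-inf"), self.cfg, "infeasible", elapsed
            )
        if res.x is None:
            raise SolverError(f"backend returned no solution: {res.message}")
        status = "optimal" if res.status == 0 else "feasible_time_limited"
        module = TwoSidedModule(
            increased=frozenset(
                g for i, g in enumerate(self.genes)
                if res.x[self._x["increased"] + i] > 0.5
            ),
            decreased=frozenset(
                g for i, g in enumerate(self.genes)
                if res.x[self._x["decreased"] + i] > 0.5
            ),
        )
        w_prof = PhenotypeProfile(pd.Series(weights, index=self.samples))
        obj = two_sided_objective(module, self.A, w_prof, self.cfg.penalty)
        if status == "optimal" and abs(obj - (-res.fun)) > 1e-5 * max(1.0, abs(obj)):
            raise SolverError(
                f"reported optimum {-res.fun:.8g} disagrees with recomputed "
                f"objective {obj:.8g}"
            )
        if not module_is_connected(module, self.G, self.cfg.model):
            raise SolverError("solver returned a module violating connectivity")
        return ModuleSolution(module, obj, self.cfg, status, elapsed)

    def solve(self) -> ModuleSolution:
        return self.solve_with_weights(self._weights)

    def to_text(self) -> str:
        """Human-readable model dump (variable counts and constraint shape)."""
        mat = self._constraints.A
        return (
            f"netphix MILP: {self.n_vars} vars "
            f"({2 * len(self.genes)} selection, {2 * len(self.samples)} coverage, "
            f"{len(self._comps) * len(self._arcs)} flow), "
            f"{mat.shape[0]} constraints, model={self.cfg.model}, k={self.cfg.k}"
        )


def build_ilp(
    A: AlterationMatrix, w: PhenotypeProfile, G: nx.Graph, cfg: SolverConfig
) -> NetphixILP:
    """Assemble the MILP for one grid point."""
    return NetphixILP(A, w, G, cfg)


def solve(model: NetphixILP, cfg: SolverConfig | None = None) -> ModuleSolution:
    """Solve a built model (cfg override rebuilds if it changes the structure)."""
    if cfg is not None and cfg != model.cfg:
        model = NetphixILP(model.A, model.w, model.G, cfg)
    return model.solve()


# ---------------------------------------------------------------------------
# enumeration oracle


def brute_force_best(
    A: AlterationMatrix,
    w: PhenotypeProfile,
    G: nx.Graph,
    cfg: SolverConfig,
    max_genes: int = 15,
) -> ModuleSolution:
    """Exhaustive optimum over all side-labeled connected gene sets of size <= k.

    Independent of the ILP: enumerates subsets, checks connectivity by graph
    traversal, and scores with vectorized arithmetic.  Ties are broken by the
    enumeration order — subsets in lexicographic order of sorted gene names,
    side assignments with 'increased' before 'decreased' — so the result is
    deterministic.  Guarded to <= ``max_genes`` genes.
    """
    genes = sorted(A.genes)
    if len(genes) > max_genes:
        raise ValueError(f"brute force limited to {max_genes} genes, got {len(genes)}")

    Anp = A.data.loc[genes].to_numpy(np.int8)
    weights = w.values.reindex(A.samples).to_numpy(float)
    side_w = {"increased": weights, "decreased": -weights}
    side_pt = {s: cfg.penalty.per_sample(v) for s, v in side_w.items()}

    def score(idx: tuple[int, ...], sides: tuple[str, ...]) -> float:
        total = 0.0
        for s in SIDES:
            rows = [i for i, lab in zip(idx, sides) if lab == s]
            if not rows:
                continue
            counts = Anp[rows].sum(axis=0)
            cov = counts >= 1
            ws, pt = side_w[s], side_pt[s]
            total += ws[cov].sum() - (pt[cov] * (counts[cov] - 1)).sum()
        return float(total)

    best_obj = float("-inf") if cfg.exact_size else 0.0
    best_mod = TwoSidedModule()
    sizes = [cfg.k] if cfg.exact_size else range(1, cfg.k + 1)
    sub = G.subgraph(genes)
    for size in sizes:
        for combo in itertools.combinations(range(len(genes)), size):
            names = [genes[i] for i in combo]
            if cfg.model == "combined" and size > 1:
                s = sub.subgraph(names)
                if s.number_of_nodes() < size or not nx.is_connected(s):
                    continue
            if any(not sub.has_node(g) for g in names):
                continue
            for assign in itertools.product(cfg.sides, repeat=size):
                mod = TwoSidedModule(
                    increased=frozenset(g for g, a in zip(names, assign) if a == "increased"),
                    decreased=frozenset(g for g, a in zip(names, assign) if a == "decreased"),
                )
                if not module_is_connected(mod, sub, cfg.model):
                    continue
                obj = score(combo, assign)
                if obj > best_obj + 1e-12:
                    best_obj, best_mod = obj, mod
    if best_obj == float("-inf"):
        return ModuleSolution(TwoSidedModule(), best_obj, cfg, "infeasible")
    return ModuleSolution(best_mod, best_obj, cfg, "optimal")
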
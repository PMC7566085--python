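"""Connected-set-cover objective with a mutual-exclusivity penalty.

For a gene set S over an alteration matrix A and per-sample weights w, the
coverage P(S) is the set of samples altered in at least one gene of S, and
the penalized objective is

    W(S) = sum_{p in P(S)} w(p)  -  sum_{p in P(S)} pt(p) * (c(p, S) - 1)

where c(p, S) counts the selected genes altered in p and pt(p) >= 0 is the
per-sample overlap penalty.  With pt identically zero this is the plain
weighted-coverage objective; with pt > 0 a sample that is hit by several
selected genes is charged for each extra hit, which softly enforces mutual
exclusivity of the selected alterations.

A module has two sides: genes whose alterations associate with *increased*
sensitivity (scored against +w) and genes associated with *decreased*
sensitivity (scored against -w).  The two-sided objective is the sum of the
two one-sided evaluations; a sample covered by both sides contributes to
both independently (see :func:`cross_side_overlap` for a diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlterationMatrix, PhenotypeProfile

__all__ = [
    "TwoSidedModule",
    "PenaltyScheme",
    "coverage",
    "overlap_count",
    "one_sided_objective",
    "two_sided_objective",
    "cross_side_overlap",
]


@dataclass(frozen=True)
class TwoSidedModule:
    """A candidate module: disjoint increased- and decreased-sensitivity gene sets."""

    increased: frozenset[str] = frozenset()
    decreased: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "increased", frozenset(self.increased))
        object.__setattr__(self, "decreased", frozenset(self.decreased))
        overlap = self.increased & self.decreased
        if overlap:
            raise ValueError(f"genes on both sides: {sorted(overlap)}")

    @property
    def genes(self) -> frozenset[str]:
        return self.increased | self.decreased

    @property
    def size(self) -> int:
        return len(self.increased) + len(self.decreased)

    def is_empty(self) -> bool:
        return self.size == 0

    def swapped(self) -> "TwoSidedModule":
        """The module with side labels exchanged."""
        return TwoSidedModule(increased=self.decreased, decreased=self.increased)

    def labeled_genes(self) -> frozenset[tuple[str, str]]:
        """Side-labeled gene set, for containment comparisons."""
        return frozenset(
            [(g, "increased") for g in self.increased]
            + [(g, "decreased") for g in self.decreased]
        )


@dataclass(frozen=True)
class PenaltyScheme:
    """Overlap penalty pt(p).

    mode 'none'       -> pt(p) = 0 (plain coverage objective)
    mode 'abs_weight' -> pt(p) = lam * |w_side(p)|, commensurate with the
                         reward and invariant to phenotype rescaling
    mode 'constant'   -> pt(p) = lam
    """

    mode: str = "abs_weight"
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "abs_weight", "constant"):
            raise ValueError(f"unknown penalty mode {self.mode!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")

    def per_sample(self, weights: np.ndarray) -> np.ndarray:
        """pt(p) for each sample, given that side's (possibly negated) weights."""
        if self.mode == "none":
            return np.zeros_like(weights, dtype=float)
        if self.mode == "abs_weight":
            return self.lam * np.abs(weights)
        return np.full_like(weights, self.lam, dtype=float)


NO_PENALTY = PenaltyScheme(mode="none", lam=0.0)


def coverage(S, A: AlterationMatrix) -> frozenset[str]:
    """P(S): samples altered in at least one gene of S."""
    S = list(S)
    if not S:
        return frozenset()
    sub = A.data.loc[S]  # raises KeyError on unknown genes
    hit = sub.to_numpy().any(axis=0)
    return frozenset(np.asarray(A.samples)[hit])


def overlap_count(p: str, S, A: AlterationMatrix) -> int:
    """c(p, S): number of genes of S altered in sample p."""
    S = list(S)
    if p not in A.data.columns:
        raise KeyError(p)
    if not S:
        return 0
    return int(A.data.loc[S, p].sum())


def one_sided_objective(
    S,
    A: AlterationMatrix,
    w: PhenotypeProfile,
    pen: PenaltyScheme = NO_PENALTY,
) -> float:
    """W(S) for a single side, scored against the given weights."""
    S = list(S)
    if not S:
        return 0.0
    weights = w.values.reindex(A.samples).to_numpy(float)
    counts = A.data.loc[S].to_numpy().sum(axis=0)  # c(p, S)
    covered = counts >= 1
    pt = pen.per_sample(weights)
    reward = weights[covered].sum()
    penalty = (pt[covered] * (counts[covered] - 1)).sum()
    return float(reward - penalty)


def _negated(w: PhenotypeProfile) -> PhenotypeProfile:
    return PhenotypeProfile(-w.values, normalized=False)


def two_sided_objective(
    M: TwoSidedModule,
    A: AlterationMatrix,
    w: PhenotypeProfile,
    pen: PenaltyScheme = NO_PENALTY,
) -> float:
    """Sum of the increased side against +w and the decreased side against -w."""
    return one_sided_objective(M.increased, A, w, pen) + one_sided_objective(
        M.decreased, A, _negated(w), pen
    )


def cross_side_overlap(M: TwoSidedModule, A: AlterationMatrix) -> int:
    """Number of samples covered by both sides (diagnostic; not penalized)."""
    return len(coverage(M.increased, A) & coverage(M.decreased, A))
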
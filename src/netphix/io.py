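"""Input artifacts: alteration matrix, phenotype profile, gene network.

Three tab-separated artifacts drive an analysis:

* an **alteration matrix** — binary genes x samples incidence (1 = the gene
  carries a somatic mutation / CNV in that sample),
* a **phenotype profile** — one continuous value per sample (e.g. z-scored
  drug response, higher = more sensitive after normalization),
* a **gene network** — an undirected weighted edge list over gene symbols
  (STRING-style ``gene1<TAB>gene2<TAB>score`` with scores in [0, 1]).

Loading validates; nothing is imputed.  Samples missing a phenotype value are
dropped from both artifacts at alignment time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlterationMatrix",
    "PhenotypeProfile",
    "load_alterations",
    "write_alterations",
    "load_phenotype",
    "write_phenotype",
    "load_network",
    "write_network",
    "normalize_phenotype",
    "filter_genes",
    "align_samples",
]


class FormatError(ValueError):
    """A file violates the input contract (non-binary entry, bad score...)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but unusable (e.g. zero-variance phenotype)."""


@dataclass(frozen=True)
class AlterationMatrix:
    """Binary gene x sample incidence matrix.

    ``data`` is an int8 DataFrame indexed by gene, with sample columns.
    Entries are strictly 0/1; gene and sample identifiers are unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        vals = df.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise FormatError(
                "non-binary entry at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def frequencies(self) -> pd.Series:
        """Fraction of samples altered, per gene."""
        return self.data.mean(axis=1)

    def altered_samples(self, gene: str) -> frozenset[str]:
        row = self.data.loc[gene]
        return frozenset(row.index[row == 1])

    def subset_genes(self, genes) -> "AlterationMatrix":
        return AlterationMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples) -> "AlterationMatrix":
        return AlterationMatrix(self.data[list(samples)])


@dataclass(frozen=True)
class PhenotypeProfile:
    """Per-sample continuous phenotype weights.

    After :func:`normalize_phenotype` the weights are population z-scores
    (mean 0, sd 1) and ``normalized`` is set; by convention larger weight
    means more sensitive to the drug.
    """

    values: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        if self.values.isna().any():
            n = int(self.values.isna().sum())
            raise FormatError(f"{n} missing phenotype value(s); drop them upstream")
        if self.normalized and len(self.values) > 1:
            v = self.values.to_numpy(float)
            if abs(v.mean()) > 1e-9 or abs(v.std() - 1.0) > 1e-9:
                raise ValueError("normalized flag set but weights are not z-scores")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def weight(self, sample: str) -> float:
        return float(self.values[sample])


# ---------------------------------------------------------------------------
# loaders / writers


def load_alterations(path) -> AlterationMatrix:
    """Read a genes x samples TSV (header = sample IDs, first column = gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing entries are not allowed")
    try:
        num = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry ({exc})") from exc
    if not np.isin(num.to_numpy(), (0, 1)).all():
        bad = np.argwhere(~np.isin(num.to_numpy(), (0, 1)))[0]
        raise FormatError(
            f"{path}: non-binary entry at gene {num.index[bad[0]]!r}, "
            f"sample {num.columns[bad[1]]!r}"
        )
    return AlterationMatrix(num.astype(np.int8))


def write_alterations(A: AlterationMatrix, path) -> None:
    A.data.to_csv(path, sep="\t", index_label="gene")


def load_phenotype(path, drop_missing: bool = True) -> PhenotypeProfile:
    """Read a two-column ``sample<TAB>value`` TSV (with or without header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns, got {df.shape[1]}")
    # tolerate a header line such as "sample\tvalue"
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    values.index = df.iloc[:, 0].astype(str)
    if values.isna().any():
        n = int(values.isna().sum())
        if not drop_missing:
            raise FormatError(f"{path}: {n} missing/non-numeric phenotype value(s)")
        logger.info("dropping %d sample(s) with missing phenotype", n)
        values = values.dropna()
    return PhenotypeProfile(values.astype(float))


def write_phenotype(w: PhenotypeProfile, path) -> None:
    w.values.to_csv(path, sep="\t", header=False)


def load_network(path, min_edge_score: float = 0.0) -> nx.Graph:
    """Read a ``gene1<TAB>gene2<TAB>score`` edge list into an undirected graph.

    Self-loops are rejected; duplicate pairs keep the maximum score; edges
    below ``min_edge_score`` are dropped at load.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene1", "gene2", "score"],
        dtype={"gene1": str, "gene2": str}, comment="#",
    )
    if df["score"].isna().any():
        # tolerate an optional header row
        df = df.iloc[1:].copy()
        df["score"] = pd.to_numeric(df["score"], errors="raise")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise FormatError(f"{path}: edge score outside [0, 1]")
    if (df["gene1"] == df["gene2"]).any():
        raise FormatError(f"{path}: self-loop edge")
    G = nx.Graph()
    for g1, g2, s in df.itertuples(index=False):
        s = float(s)
        if s < min_edge_score:
            continue
        if G.has_edge(g1, g2):
            G[g1][g2]["score"] = max(G[g1][g2]["score"], s)
        else:
            G.add_edge(g1, g2, score=s)
    return G


def write_network(G: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v), d.get("score", 1.0)) for u, v, d in G.edges(data=True))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# transformations


def normalize_phenotype(w: PhenotypeProfile, negate: bool = False) -> PhenotypeProfile:
    """Z-score the phenotype (population sd), optionally sign-flipping first.

    ``negate=True`` accommodates raw IC50-style inputs where *smaller* means
    more sensitive; after negation, larger weight = more sensitive.  Centering
    makes random coverage carry zero expected weight, which the set-cover
    objective relies on.
    """
    v = w.values.to_numpy(float)
    if len(v) < 2:
        raise DegenerateInputError("need at least 2 samples to normalize")
    if negate:
        v = -v
    sd = v.std()
    if sd < 1e-12:
        raise DegenerateInputError("phenotype has zero variance")
    z = (v - v.mean()) / sd
    return PhenotypeProfile(pd.Series(z, index=w.values.index), normalized=True)


def filter_genes(
    A: AlterationMatrix,
    G: nx.Graph | None = None,
    min_freq: float = 0.01,
    max_freq: float = 1.0,
    require_in_network: bool = True,
) -> AlterationMatrix:
    """Keep genes altered in a fraction of samples within [min_freq, max_freq].

    With ``require_in_network`` (and a network given), genes absent from the
    network are dropped too — connectivity constraints are meaningless for
    them.  An empty result is returned with a warning, never raised.
    """
    if not 0 <= min_freq <= max_freq <= 1:
        raise ValueError("need 0 <= min_freq <= max_freq <= 1")
    freq = A.frequencies()
    keep = (freq >= min_freq) & (freq <= max_freq)
    if require_in_network and G is not None:
        in_net = A.data.index.to_series().apply(G.has_node)
        for gene in A.data.index[keep & ~in_net]:
            logger.info("dropping gene %s: not in the network", gene)
        keep &= in_net
    if not keep.any():
        logger.warning("gene filter removed every gene")
    return AlterationMatrix(A.data.loc[keep])


def align_samples(
    A: AlterationMatrix, w: PhenotypeProfile
) -> tuple[AlterationMatrix, PhenotypeProfile]:
    """Restrict both artifacts to their common samples, in matrix order.

    Subsetting invalidates any prior z-scoring, so the returned profile is
    un-normalized; normalize after alignment.
    """
    common = [s for s in A.samples if s in set(w.samples)]
    if not common:
        raise DegenerateInputError("no samples shared between alterations and phenotype")
    dropped = (A.n_samples - len(common)) + (len(w.samples) - len(common))
    if dropped:
        logger.info("alignment dropped %d unmatched sample(s)", dropped)
    return (
        A.subset_samples(common),
        PhenotypeProfile(w.values.loc[common], normalized=False),
    )
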
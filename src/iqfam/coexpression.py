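"""Mutual-Rank co-expression analysis.

For each gene, its potential partners are ranked by descending Pearson
correlation (rank 1 = highest, average rank on ties, self excluded);
the Mutual Rank of a pair is the geometric mean of the two reciprocal
ranks, MR(a,b) = sqrt(rank_ab * rank_ba).  Low MR means strong mutual
co-expression; guide-gene networks keep partners with MR at or below a
cutoff (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    Constant (zero-variance) gene rows cannot enter a correlation and
    are excluded on construction; their ids are kept in ``excluded``.
    """

    data: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 samples")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        variances = self.data.var(axis=1, ddof=0)
        dead = variances[variances == 0].index.tolist()
        if dead:
            self.excluded = list(self.excluded) + dead
            self.data = self.data.drop(index=dead)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    def write(self, path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, lineterminator="\n")


@dataclass(frozen=True)
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    pearson_r: float
    rank_ab: float
    rank_ba: float
    mr: float


def pearson_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between all gene pairs (diagonal = 1)."""
    values = expr.data.to_numpy(dtype=float)
    if np.any(values.std(axis=1) == 0):
        raise ValueError("zero-variance row reached correlation stage")
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.data.index, columns=expr.data.index)


def rank_matrix(corr: pd.DataFrame) -> np.ndarray:
    """Per-row partner ranks by descending r, self excluded, average
    rank on ties.  Entry [i, j] is the rank of gene j among gene i's
    partners; the diagonal is 0 (undefined)."""
    n = corr.shape[0]
    c = corr.to_numpy(dtype=float)
    ranks = np.zeros((n, n))
    for i in range(n):
        others = np.delete(np.arange(n), i)
        r = rankdata(-c[i, others], method="average")
        ranks[i, others] = r
    return ranks


def mutual_rank(corr: pd.DataFrame) -> pd.DataFrame:
    """MR(a,b) = sqrt(rank_ab * rank_ba); symmetric, >= 1 off the
    diagonal (diagonal set to 0)."""
    n = corr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 genes for mutual ranks")
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    ranks = rank_matrix(corr)
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return pd.DataFrame(mr, index=corr.index, columns=corr.columns)


def _edge(corr: pd.DataFrame, ranks: np.ndarray, mr: pd.DataFrame, ia: int, ib: int) -> CoexpressionEdge:
    a, b = corr.index[ia], corr.index[ib]
    ga, gb = sorted([(a, ia), (b, ib)])
    (a, ia), (b, ib) = ga, gb
    return CoexpressionEdge(
        gene_a=a,
        gene_b=b,
        pearson_r=float(corr.iat[ia, ib]),
        rank_ab=float(ranks[ia, ib]),
        rank_ba=float(ranks[ib, ia]),
        mr=float(mr.iat[ia, ib]),
    )


def guide_gene_network(
    mr: pd.DataFrame,
    guides: list[str],
    mr_cutoff: float = 10.0,
    hierarchy: int = 1,
    corr: pd.DataFrame | None = None,
) -> list[CoexpressionEdge]:
    """Edges around guide genes with MR <= cutoff.

    Hierarchy 1 keeps direct guide-partner edges; hierarchy 2
    additionally expands one shell outward from the first-shell
    partners.  The edge list is deduplicated and sorted by (MR, ids).
    """
    unknown = [g for g in guides if g not in mr.index]
    if unknown:
        raise ValueError(f"unknown guide genes: {unknown}")
    if hierarchy not in (1, 2):
        raise ValueError("hierarchy must be 1 or 2")
    if corr is None:
        corr = pd.DataFrame(np.nan, index=mr.index, columns=mr.columns)
    ranks = rank_matrix(corr) if not corr.isna().all().all() else np.zeros(mr.shape)
    idx = {g: i for i, g in enumerate(mr.index)}
    m = mr.to_numpy()

    def shell(sources: set[str]) -> set[tuple[int, int]]:
        found = set()
        for g in sources:
            i = idx[g]
            partners = np.where((m[i] <= mr_cutoff) & (m[i] > 0))[0]
            for j in partners:
                found.add((min(i, j), max(i, j)))
        return found

    pairs = shell(set(guides))
    if hierarchy == 2:
        first_shell = {mr.index[j] for i, j in pairs} | {mr.index[i] for i, j in pairs}
        pairs |= shell(first_shell - set(guides))
    edges = [_edge(corr, ranks, mr, i, j) for i, j in pairs]
    edges.sort(key=lambda e: (e.mr, e.gene_a, e.gene_b))
    return edges


def edges_to_frame(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "r": e.pearson_r,
                "rank_ab": e.rank_ab,
                "rank_ba": e.rank_ba,
                "MR": e.mr,
            }
            for e in edges
        ],
        columns=["gene_a", "gene_b", "r", "rank_ab", "rank_ba", "MR"],
    )
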
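"""Pearson-correlation, rank and Mutual Rank matrices.

The Mutual Rank (MR) of a gene pair is the geometric mean of the two
asymmetric correlation ranks,

    MR(A,B) = sqrt(Rank(AB) * Rank(BA)),

where Rank(AB) is the position of gene B when all of A's partners are
sorted by their Pearson correlation to A.  Reciprocal best partners get
MR = 1; a low MR means strong, mutual co-expression regardless of how
crowded either gene's correlation neighbourhood is.

Conventions
-----------
* Self-correlation is excluded from ranking, so rank 1 is the best
  non-self partner and MR spans [1, G-1] on tie-free inputs.
* Ties receive average ranks.
* Genes with a constant profile have undefined correlation; they are
  flagged and excluded from ranking rather than assigned a value.
* Ranking direction is explicit: ``descending_pcc`` (rank 1 = largest
  correlation; the positive network) or ``ascending_pcc`` (rank 1 = most
  negative correlation; the negative network).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import MRNetError
from .io_formats import ExpressionMatrix

DESCENDING = "descending_pcc"
ASCENDING = "ascending_pcc"

#: Dense G x G matrices above this many genes are refused with a clear
#: error; the quadratic memory contract is explicit, not silent.
MAX_DENSE_GENES = 30_000


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Pearson-correlation matrix.

    Entries involving a flagged (zero-variance) gene are NaN and listed
    in :attr:`undefined`; the diagonal is exactly 1 for defined genes.
    """

    values: pd.DataFrame
    undefined: tuple[str, ...] = ()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def defined_genes(self) -> list[str]:
        und = set(self.undefined)
        return [g for g in self.values.index if g not in und]


@dataclass
class RankMatrix:
    """Asymmetric rank matrix: entry (A, B) = Rank(AB).

    Each defined row holds a permutation-with-ties of 1..(D-1) over the
    off-diagonal defined partners (average ranks on ties); the diagonal
    and undefined genes are NaN.
    """

    values: pd.DataFrame
    direction: str
    undefined: tuple[str, ...] = ()


@dataclass
class MRMatrix:
    """Symmetric Mutual Rank matrix, MR(A,B) = sqrt(Rank(AB)*Rank(BA))."""

    values: pd.DataFrame
    direction: str
    undefined: tuple[str, ...] = ()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def pcc_matrix(expr: ExpressionMatrix, max_genes: int = MAX_DENSE_GENES) -> CorrelationMatrix:
    """All-pairs Pearson correlation of gene TPM profiles.

    Requires at least 3 samples.  Zero-variance genes yield NaN
    rows/columns and are reported in ``undefined``; if every gene is
    constant there is nothing to correlate and an error is raised.
    """
    if expr.n_samples < 3:
        raise MRNetError(
            f"need at least 3 samples to correlate, got {expr.n_samples}"
        )
    genes = expr.gene_ids
    if len(genes) > max_genes:
        raise MRNetError(
            f"{len(genes)} genes exceeds the dense-matrix cap of {max_genes}; "
            "subset the matrix or raise max_genes explicitly"
        )
    arr = expr.values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    defined = sd > 0
    if not defined.any():
        raise MRNetError("no variable genes")
    full = np.full((len(genes), len(genes)), np.nan)
    sub = np.corrcoef(arr[defined])
    sub = np.clip((sub + sub.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sub, 1.0)
    idx = np.flatnonzero(defined)
    full[np.ix_(idx, idx)] = sub
    values = pd.DataFrame(full, index=genes, columns=genes)
    undefined = tuple(np.asarray(genes, dtype=object)[~defined])
    return CorrelationMatrix(values=values, undefined=undefined)


def rank_matrix(corr: CorrelationMatrix, direction: str = DESCENDING) -> RankMatrix:
    """Rank every gene's partners by correlation in the given direction.

    Self and undefined partners are excluded; ties get average ranks.
    """
    if direction not in (DESCENDING, ASCENDING):
        raise MRNetError(
            f"direction must be {DESCENDING!r} or {ASCENDING!r}, got {direction!r}"
        )
    genes = corr.gene_ids
    defined = corr.defined_genes
    if len(defined) < 3:
        raise MRNetError(
            f"fewer than 3 defined genes ({len(defined)}) — cannot rank"
        )
    pos = {g: i for i, g in enumerate(genes)}
    d_idx = np.array([pos[g] for g in defined])
    sub = corr.values.to_numpy()[np.ix_(d_idx, d_idx)].copy()
    np.fill_diagonal(sub, np.nan)
    scores = -sub if direction == DESCENDING else sub
    ranks = rankdata(scores, axis=1, nan_policy="omit")
    full = np.full((len(genes), len(genes)), np.nan)
    full[np.ix_(d_idx, d_idx)] = ranks
    values = pd.DataFrame(full, index=genes, columns=genes)
    return RankMatrix(values=values, direction=direction, undefined=corr.undefined)


def mutual_rank(ranks: RankMatrix) -> MRMatrix:
    """Combine the two asymmetric ranks of each pair into their geometric mean."""
    r = ranks.values.to_numpy()
    mr = np.sqrt(r * r.T)
    values = pd.DataFrame(mr, index=ranks.values.index, columns=ranks.values.columns)
    return MRMatrix(values=values, direction=ranks.direction, undefined=ranks.undefined)


def mr_from_expression(
    expr: ExpressionMatrix, direction: str = DESCENDING
) -> tuple[CorrelationMatrix, MRMatrix]:
    """Convenience pipeline: expression -> (PCC matrix, MR matrix)."""
    corr = pcc_matrix(expr)
    return corr, mutual_rank(rank_matrix(corr, direction))
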
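"""GO-driven calibration of the co-expression thresholds.

The network is treated as a binary classifier of gene pairs: a pair is
"predicted linked" when its correlation passes the sign-appropriate PCC
cutoff and its Mutual Rank falls below an MR cutoff.  Ground truth comes
from Gene Ontology biological-process terms of bounded size (4-20 genes
by default): a pair is a true link when the two genes share at least one
such prior term.  Sweeping the MR cutoff over a grid traces TPR/FPR
points; the cutoff with the largest single-point AUC is selected.

The per-cutoff AUC is the area of the one-knot ROC through (0,0),
(FPR,TPR), (1,1), i.e. (1 + TPR - FPR)/2, which makes "the AUC at a
given MR cutoff" well defined; the trapezoidal area over the whole sweep
is reported alongside as a diagnostic.

Only genes that appear in the expression matrix *and* carry at least one
retained prior term enter the calibration universe — unannotated genes
cannot be labelled and would otherwise inflate the negative class.  The
final network is built over all genes regardless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation_core import CorrelationMatrix, MRMatrix
from .errors import MRNetError
from .io_formats import GOAnnotationTable

DEFAULT_MR_GRID = tuple(range(5, 105, 5))


@dataclass
class PriorGeneSets:
    """GO terms of bounded size used as ground-truth gene sets.

    ``sets`` maps each retained term to its member genes intersected with
    the expression universe; ``universe`` is the union of the retained
    sets (the genes eligible for pair labelling).
    """

    sets: dict[str, frozenset[str]]
    universe: tuple[str, ...]
    min_genes: int = 4
    max_genes: int = 20

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PairLabels:
    """Co-annotation labels over every unordered pair of universe genes."""

    genes: tuple[str, ...]
    co_annotated: np.ndarray  # bool, symmetric, False diagonal

    @property
    def _triu(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(len(self.genes), k=1)

    @property
    def positive_vector(self) -> np.ndarray:
        """Boolean label per unordered pair, upper-triangle order."""
        return self.co_annotated[self._triu]

    @property
    def n_positive(self) -> int:
        return int(self.positive_vector.sum())

    @property
    def n_negative(self) -> int:
        v = self.positive_vector
        return int(v.size - v.sum())


@dataclass
class CalibrationResult:
    """ROC sweep over MR cutoffs at a fixed PCC cutoff."""

    pcc_cutoff: float
    sign: str
    mr_grid: tuple[float, ...]
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]
    point_auc: tuple[float, ...]
    selected_mr_cutoff: float
    selected_auc: float
    curve_auc: float

    def to_dict(self) -> dict:
        return {
            "pcc_cutoff": self.pcc_cutoff,
            "sign": self.sign,
            "mr_grid": list(self.mr_grid),
            "tpr": list(self.tpr),
            "fpr": list(self.fpr),
            "point_auc": list(self.point_auc),
            "selected_mr_cutoff": self.selected_mr_cutoff,
            "selected_auc": self.selected_auc,
            "curve_auc": self.curve_auc,
        }

    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mr_cutoff": self.mr_grid,
                "fpr": self.fpr,
                "tpr": self.tpr,
                "point_auc": self.point_auc,
            }
        )


def select_prior_sets(
    go: GOAnnotationTable,
    universe,
    min_genes: int = 4,
    max_genes: int = 20,
    namespace: str = "BP",
) -> PriorGeneSets:
    """Retain GO terms whose gene count inside ``universe`` is within bounds.

    ``universe`` is typically the gene set of the expression matrix.
    Bounds are inclusive.  Raises when no term qualifies.
    """
    uni = set(universe)
    if not uni:
        raise MRNetError("empty gene universe")
    df = go.records
    if namespace is not None:
        df = df[df["namespace"] == namespace]
    if not len(df):
        raise MRNetError(f"no GO records in namespace {namespace!r}")
    sets: dict[str, frozenset[str]] = {}
    for term, sub in df.groupby("go_term"):
        members = frozenset(sub["gene_id"]) & uni
        if min_genes <= len(members) <= max_genes:
            sets[term] = frozenset(members)
    if not sets:
        raise MRNetError(
            f"no GO term has between {min_genes} and {max_genes} genes in the "
            "universe; widen the bounds or check the annotation table"
        )
    pair_universe = tuple(sorted(set().union(*sets.values())))
    return PriorGeneSets(
        sets=sets, universe=pair_universe, min_genes=min_genes, max_genes=max_genes
    )


def label_gene_pairs(priors: PriorGeneSets) -> PairLabels:
    """Label each unordered universe pair positive iff it shares a prior term."""
    genes = priors.universe
    if len(genes) < 4:
        raise MRNetError(f"pair universe has {len(genes)} genes, need at least 4")
    pos = {g: i for i, g in enumerate(genes)}
    # gene x term membership indicator; co-annotation = shared column
    member = np.zeros((len(genes), len(priors.sets)), dtype=bool)
    for j, members in enumerate(priors.sets.values()):
        for g in members:
            member[pos[g], j] = True
    co = (member.astype(np.uint16) @ member.T.astype(np.uint16)) > 0
    np.fill_diagonal(co, False)
    return PairLabels(genes=genes, co_annotated=co)


def _predicted_matrix(
    mr: MRMatrix,
    pcc: CorrelationMatrix,
    genes: tuple[str, ...],
    pcc_cutoff: float,
    mr_cutoff: float,
    sign: str,
) -> np.ndarray:
    missing = [g for g in genes if g not in pcc.values.index]
    if missing:
        raise MRNetError(f"genes absent from correlation matrix: {missing[:5]}")
    P = pcc.values.loc[list(genes), list(genes)].to_numpy()
    M = mr.values.loc[list(genes), list(genes)].to_numpy()
    if sign == "positive":
        passes_pcc = P > pcc_cutoff
    elif sign == "negative":
        passes_pcc = P < -abs(pcc_cutoff)
    else:
        raise MRNetError(f"sign must be 'positive' or 'negative', got {sign!r}")
    with np.errstate(invalid="ignore"):
        pred = passes_pcc & (M < mr_cutoff)
    np.fill_diagonal(pred, False)
    return pred


def classifier_rates(
    mr: MRMatrix,
    pcc: CorrelationMatrix,
    labels: PairLabels,
    pcc_cutoff: float,
    mr_cutoff: float,
    sign: str = "positive",
) -> tuple[float, float]:
    """TPR and FPR of the thresholded network against the pair labels."""
    y = labels.positive_vector
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MRNetError(
            f"rates undefined: {n_pos} positive / {n_neg} negative pair labels"
        )
    pred = _predicted_matrix(mr, pcc, labels.genes, pcc_cutoff, mr_cutoff, sign)
    p = pred[np.triu_indices(len(labels.genes), k=1)]
    tpr = float((p & y).sum() / n_pos)
    fpr = float((p & ~y).sum() / n_neg)
    return tpr, fpr


def single_point_auc(tpr: float, fpr: float) -> float:
    """Area of the ROC through (0,0), (FPR,TPR), (1,1): (1 + TPR - FPR)/2."""
    if not (0.0 <= tpr <= 1.0 and 0.0 <= fpr <= 1.0):
        raise MRNetError(f"rates out of [0,1]: tpr={tpr}, fpr={fpr}")
    return (1.0 + tpr - fpr) / 2.0


def auc_trapezoid(points) -> float:
    """Trapezoidal area under an ROC given (FPR, TPR) points.

    The endpoints (0,0) and (1,1) are appended if absent; FPR must be
    non-decreasing.
    """
    pts = [(float(f), float(t)) for f, t in points]
    if not pts or pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    if np.any(np.diff(fpr) < 0):
        raise MRNetError("FPR sequence must be non-decreasing")
    return float(np.trapezoid(tpr, fpr))


def select_mr_threshold(
    mr: MRMatrix,
    pcc: CorrelationMatrix,
    labels: PairLabels,
    pcc_cutoff: float = 0.7,
    mr_grid=DEFAULT_MR_GRID,
    sign: str = "positive",
) -> CalibrationResult:
    """Sweep the MR grid, score each cutoff, and pick the AUC-maximising one.

    Ties are broken toward the smaller cutoff (the sparser network).
    """
    grid = tuple(sorted(float(c) for c in mr_grid))
    if not grid:
        raise MRNetError("empty MR grid")
    tprs, fprs, aucs = [], [], []
    for cutoff in grid:
        tpr, fpr = classifier_rates(mr, pcc, labels, pcc_cutoff, cutoff, sign)
        tprs.append(tpr)
        fprs.append(fpr)
        aucs.append(single_point_auc(tpr, fpr))
    best = 0
    for i in range(1, len(grid)):
        if aucs[i] > aucs[best]:
            best = i
    return CalibrationResult(
        pcc_cutoff=pcc_cutoff,
        sign=sign,
        mr_grid=grid,
        tpr=tuple(tprs),
        fpr=tuple(fprs),
        point_auc=tuple(aucs),
        selected_mr_cutoff=grid[best],
        selected_auc=aucs[best],
        curve_auc=auc_trapezoid(list(zip(fprs, tprs))),
    )
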
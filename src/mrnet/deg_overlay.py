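"""Differential-expression calls and their overlay on network nodes.

The caller works directly on the TPM matrix (no raw counts are
available to a TPM-level toolkit), with a deliberately transparent
recipe: per gene, log2 fold change log2((mean_a + c)/(mean_b + c)) with
pseudocount c = 1, a Welch (unequal-variance) t-test on log2(TPM + 1),
Benjamini-Hochberg adjustment across genes, and a combined fold-change +
adjusted-p gate.  Genes below a minimum-expression floor in both groups
are reported as 'ns' with p = 1 rather than dropped, so tables stay
aligned with the matrix.

Overlaying a DEG table on a network assigns each node one status:
'up' / 'down' (the red/blue display convention), 'ns', or 'absent' when
the gene is missing from the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MRNetError
from .io_formats import ExpressionMatrix
from .network_build import CoexpressionNetwork

DEG_COLUMNS = [
    "gene_id", "comparison", "log2_fold_change", "p_value", "adjusted_p", "direction",
]


@dataclass
class DEGTable:
    """Per-gene differential-expression results for one comparison."""

    records: pd.DataFrame  # DEG_COLUMNS
    comparison: str
    fc_threshold: float
    alpha: float
    pseudocount: float = 1.0

    def direction_of(self) -> dict[str, str]:
        return dict(zip(self.records["gene_id"], self.records["direction"]))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AnnotatedNetwork:
    """Co-expression network plus an up/down/ns/absent status per node."""

    network: CoexpressionNetwork
    node_status: dict[str, str]
    comparison: str

    def status_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.node_status),
                "status": list(self.node_status.values()),
                "comparison": self.comparison,
            }
        )


def call_degs(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    min_expression: float = 1.0,
) -> DEGTable:
    """Call DEGs for group_a vs group_b (positive log2FC = higher in a).

    direction is 'up' when log2FC >= fc_threshold and adjusted_p < alpha,
    'down' when log2FC <= -fc_threshold and adjusted_p < alpha, else 'ns'.
    """
    samples_a = expr.group_samples(group_a)
    samples_b = expr.group_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise MRNetError(
            f"each group needs >= 2 samples (got {len(samples_a)} in {group_a!r}, "
            f"{len(samples_b)} in {group_b!r})"
        )
    a = expr.values[samples_a].to_numpy(dtype=float)
    b = expr.values[samples_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(
            np.log2(a + 1.0), np.log2(b + 1.0), axis=1, equal_var=False
        )
    pvals = np.asarray(pvals, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0  # zero-variance-in-both-groups genes
    low = (mean_a < min_expression) & (mean_b < min_expression)
    pvals[low] = 1.0
    tested = ~low
    adjusted = np.ones_like(pvals)
    if tested.any():
        adjusted[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    direction = np.full(len(log2fc), "ns", dtype=object)
    sig = adjusted < alpha
    direction[(log2fc >= fc_threshold) & sig & tested] = "up"
    direction[(log2fc <= -fc_threshold) & sig & tested] = "down"
    comparison = f"{group_a}_vs_{group_b}"
    records = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "comparison": comparison,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "adjusted_p": adjusted,
            "direction": direction,
        },
        columns=DEG_COLUMNS,
    )
    return DEGTable(
        records=records,
        comparison=comparison,
        fc_threshold=fc_threshold,
        alpha=alpha,
        pseudocount=pseudocount,
    )


def overlay(net: CoexpressionNetwork, degs: DEGTable) -> AnnotatedNetwork:
    """Attach the DEG status of each network node; missing genes -> 'absent'."""
    directions = degs.direction_of()
    status = {g: directions.get(g, "absent") for g in sorted(net.node_set)}
    return AnnotatedNetwork(network=net, node_status=status, comparison=degs.comparison)
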
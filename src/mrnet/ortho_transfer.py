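"""Interolog transfer: project a reference PPI network through orthologs.

Each reference interaction (a1, a2) is expanded to every target-species
pair (b1, b2) with b1 an ortholog of a1 and b2 an ortholog of a2.
Many-to-many ortholog relations expand combinatorially by default; the
``one_to_one`` switch restricts the map to genes that are uniquely
mapped in both directions.  Pairs collapsing onto a single target gene
(both reference genes sharing the ortholog) are dropped as self-loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import MRNetError
from .io_formats import OrthologMap, PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class TransferReport:
    """Bookkeeping for one interolog projection."""

    n_ref_edges: int
    n_mapped: int          # reference edges yielding >= 1 target edge
    n_unmapped: int        # reference edges with an unmapped endpoint
    n_self_loops_dropped: int
    provenance: pd.DataFrame  # gene_a, gene_b, ref_a, ref_b


def _one_to_one(orthos: OrthologMap) -> dict[str, list[str]]:
    df = orthos.records
    ref_counts = df["ref_gene_id"].value_counts()
    tgt_counts = df["target_gene_id"].value_counts()
    keep = df[
        df["ref_gene_id"].map(ref_counts).eq(1)
        & df["target_gene_id"].map(tgt_counts).eq(1)
    ]
    return {r: [t] for r, t in keep.itertuples(index=False)}


def transfer_ppi(
    ref_ppi: PPINetwork,
    orthos: OrthologMap,
    one_to_one: bool = False,
    species: str = "",
) -> tuple[PPINetwork, TransferReport]:
    """Map every reference edge through the ortholog table.

    Returns the deduplicated target network plus a report with
    mapped/unmapped reference-edge counts and an edge-level provenance
    table (which reference edge produced each target edge).
    """
    if not len(orthos):
        raise MRNetError("empty ortholog map")
    targets = _one_to_one(orthos) if one_to_one else orthos.targets_of()
    rows: list[tuple[str, str, str, str]] = []
    n_mapped = n_unmapped = n_loops = 0
    for a1, a2 in ref_ppi.edges[["gene_a", "gene_b"]].itertuples(index=False):
        t1 = targets.get(a1, ())
        t2 = targets.get(a2, ())
        if not t1 or not t2:
            n_unmapped += 1
            continue
        emitted = False
        for b1 in t1:
            for b2 in t2:
                if b1 == b2:
                    n_loops += 1
                    logger.debug(
                        "self-loop %s from reference edge (%s, %s) dropped",
                        b1, a1, a2,
                    )
                    continue
                lo, hi = (b1, b2) if b1 < b2 else (b2, b1)
                rows.append((lo, hi, a1, a2))
                emitted = True
        n_mapped += emitted
        n_unmapped += not emitted
    provenance = pd.DataFrame(rows, columns=["gene_a", "gene_b", "ref_a", "ref_b"])
    edges = provenance[["gene_a", "gene_b"]].drop_duplicates()
    net = PPINetwork(edges=edges.reset_index(drop=True), species=species)
    report = TransferReport(
        n_ref_edges=len(ref_ppi),
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        n_self_loops_dropped=n_loops,
        provenance=provenance,
    )
    if n_loops:
        logger.warning("dropped %d self-loop target pair(s) during transfer", n_loops)
    return net, report
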
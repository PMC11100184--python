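"""Materialise signed co-expression networks and answer topology queries.

An edge joins genes A and B in the positive network when PCC(A,B) >
pcc_cutoff and MR(A,B) < mr_cutoff, and in the negative network when
PCC(A,B) < -|pcc_cutoff| and MR(A,B) < mr_cutoff.  Both inequalities are
strict, so boundary pairs are excluded.  Edges are undirected, stored
once with gene_a < gene_b, and keep their pcc/mr values as attributes.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .correlation_core import CorrelationMatrix, MRMatrix
from .errors import MRNetError
from .io_formats import _read_tsv

EDGE_COLUMNS = ["gene_a", "gene_b", "pcc", "mr", "sign"]


@dataclass
class CoexpressionNetwork:
    """Signed, weighted co-expression edge set with threshold provenance.

    The node set defaults to the edge endpoints (isolated genes are
    excluded from exports); pass ``nodes`` explicitly to keep track of a
    larger universe, e.g. for statistics.
    """

    edges: pd.DataFrame  # EDGE_COLUMNS
    sign: str = "positive"
    pcc_cutoff: float | None = None
    mr_cutoff: float | None = None
    nodes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        df = self.edges
        if list(df.columns) != EDGE_COLUMNS:
            raise MRNetError(f"edge table must have columns {EDGE_COLUMNS}")
        if len(df):
            if (df["gene_a"] == df["gene_b"]).any():
                raise MRNetError("self-loop in co-expression network")
            flip = df["gene_a"] > df["gene_b"]
            if flip.any():
                a = df["gene_a"].where(~flip, df["gene_b"])
                b = df["gene_b"].where(~flip, df["gene_a"])
                df = df.assign(gene_a=a, gene_b=b)
            df = df.drop_duplicates(subset=["gene_a", "gene_b"])
            df = df.sort_values(["gene_a", "gene_b"])
        self.edges = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def node_set(self) -> set[str]:
        if self.nodes is not None:
            return set(self.nodes)
        if not len(self.edges):
            return set()
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            map(tuple, self.edges[["gene_a", "gene_b"]].to_numpy())
        )

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_set)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, pcc=row.pcc, mr=row.mr)
        return g


def build_network(
    pcc: CorrelationMatrix,
    mr: MRMatrix,
    sign: str = "positive",
    pcc_cutoff: float = 0.7,
    mr_cutoff: float = 40.0,
) -> CoexpressionNetwork:
    """Collect exactly the gene pairs passing both strict threshold filters."""
    genes = pcc.gene_ids
    if genes != mr.gene_ids:
        raise MRNetError("PCC and MR matrices cover different gene universes")
    if not (np.isfinite(pcc_cutoff) and np.isfinite(mr_cutoff)):
        raise MRNetError("cutoffs must be finite")
    if sign not in ("positive", "negative"):
        raise MRNetError(f"sign must be 'positive' or 'negative', got {sign!r}")
    P = pcc.values.to_numpy()
    M = mr.values.to_numpy()
    with np.errstate(invalid="ignore"):
        if sign == "positive":
            cond = P > pcc_cutoff
        else:
            cond = P < -abs(pcc_cutoff)
        cond &= M < mr_cutoff
    iu = np.triu_indices(len(genes), k=1)
    keep = cond[iu]
    ga = np.asarray(genes, dtype=object)[iu[0][keep]]
    gb = np.asarray(genes, dtype=object)[iu[1][keep]]
    edges = pd.DataFrame(
        {
            "gene_a": ga,
            "gene_b": gb,
            "pcc": P[iu][keep],
            "mr": M[iu][keep],
            "sign": sign,
        },
        columns=EDGE_COLUMNS,
    )
    return CoexpressionNetwork(
        edges=edges, sign=sign, pcc_cutoff=pcc_cutoff, mr_cutoff=mr_cutoff
    )


def neighborhood(
    net: CoexpressionNetwork, gene: str, order: int = 1
) -> CoexpressionNetwork:
    """Induced subnetwork of nodes within graph distance ``order`` of ``gene``."""
    nodes = net.node_set
    if gene not in nodes:
        close = difflib.get_close_matches(gene, nodes, n=3)
        hint = f"; closest matches: {close}" if close else ""
        raise MRNetError(f"gene {gene!r} not in network{hint}")
    if order < 0:
        raise MRNetError("order must be >= 0")
    g = net.to_graph()
    reach = set(nx.single_source_shortest_path_length(g, gene, cutoff=order))
    mask = net.edges["gene_a"].isin(reach) & net.edges["gene_b"].isin(reach)
    return CoexpressionNetwork(
        edges=net.edges[mask].reset_index(drop=True),
        sign=net.sign,
        pcc_cutoff=net.pcc_cutoff,
        mr_cutoff=net.mr_cutoff,
        nodes=tuple(sorted(reach)),
    )


def network_stats(net: CoexpressionNetwork) -> dict:
    """Node/edge counts and degree-distribution quantiles."""
    g = net.to_graph()
    degrees = np.array([d for _, d in g.degree()]) if g.number_of_nodes() else np.array([])
    if degrees.size:
        q = np.quantile(degrees, [0.0, 0.25, 0.5, 0.75, 1.0])
        quantiles = {k: float(v) for k, v in zip(("min", "q25", "median", "q75", "max"), q)}
        mean_degree = float(degrees.mean())
    else:
        quantiles = {k: 0.0 for k in ("min", "q25", "median", "q75", "max")}
        mean_degree = 0.0
    return {
        "n_nodes": int(g.number_of_nodes()),
        "n_edges": int(g.number_of_edges()),
        "mean_degree": mean_degree,
        "degree_quantiles": quantiles,
    }


def read_coexpression_network(path) -> CoexpressionNetwork:
    """Read an edge-list TSV written by :func:`mrnet.io_formats.write_edge_list`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_a": str, "gene_b": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise MRNetError(f"{path} lacks edge columns {missing}")
    df = df[EDGE_COLUMNS]
    sign = df["sign"].iloc[0] if len(df) else "positive"
    return CoexpressionNetwork(edges=df, sign=sign)
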
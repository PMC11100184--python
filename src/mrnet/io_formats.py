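"""Readers and writers for the plain-text tables the toolkit exchanges.

All files are tab-separated UTF-8; lines starting with ``#`` are comments.
Matrices are dense (an empty expression cell is an error, never imputed),
undirected edges are stored once in lexicographic order so that file diffs
are stable, and every reader is total on its own writer's output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MRNetError

logger = logging.getLogger(__name__)

_GO_ID = re.compile(r"^GO:\d{7}$")
_KO_ID = re.compile(r"^K\d+$")
_PATHWAY_ID = re.compile(r"^(map|ko)\d+$")
_NAMESPACES = frozenset({"BP", "MF", "CC"})


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with optional sample-group labels.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    All entries must be finite and non-negative. Genes whose profile is
    constant across samples are retained but flagged via
    :attr:`constant_genes` (their Pearson correlation is undefined and
    they are excluded from ranking downstream).
    """

    values: pd.DataFrame
    sample_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise MRNetError(f"duplicate gene id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise MRNetError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise MRNetError("expression matrix must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise MRNetError(
                f"non-finite expression value at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise MRNetError(
                f"negative TPM value at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.sample_groups is not None:
            unknown = set(self.sample_groups) - set(cols)
            if unknown:
                raise MRNetError(
                    f"sample_groups refer to unknown samples: {sorted(unknown)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def constant_genes(self) -> list[str]:
        arr = self.values.to_numpy()
        const = (arr == arr[:, [0]]).all(axis=1)
        return list(self.values.index[const])

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to ``group`` (requires sample_groups)."""
        if self.sample_groups is None:
            raise MRNetError("expression matrix carries no sample-group design")
        out = [s for s in self.sample_ids if self.sample_groups.get(s) == group]
        if not out:
            raise MRNetError(f"unknown sample group {group!r}")
        return out


@dataclass
class GOAnnotationTable:
    """Gene -> GO term records with a BP/MF/CC namespace per record."""

    records: pd.DataFrame  # columns: gene_id, go_term, namespace

    def __post_init__(self) -> None:
        df = self.records
        bad_ns = set(df["namespace"]) - _NAMESPACES
        if bad_ns:
            raise MRNetError(f"unknown GO namespace(s): {sorted(bad_ns)}")
        bad = [t for t in df["go_term"].unique() if not _GO_ID.match(t)]
        if bad:
            raise MRNetError(f"malformed GO identifier {bad[0]!r}")
        # (gene, term) pairs unique after parsing
        self.records = df.drop_duplicates(subset=["gene_id", "go_term"]).reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class OrthologMap:
    """Reference-species gene -> target-species gene pairs (many-to-many)."""

    records: pd.DataFrame  # columns: ref_gene_id, target_gene_id

    def __post_init__(self) -> None:
        df = self.records.drop_duplicates().reset_index(drop=True)
        if len(df) and (df["ref_gene_id"].eq("").any() or df["target_gene_id"].eq("").any()):
            raise MRNetError("empty identifier in ortholog map")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def targets_of(self) -> dict[str, list[str]]:
        d: dict[str, list[str]] = {}
        for r, t in self.records.itertuples(index=False):
            d.setdefault(r, []).append(t)
        return d


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction edges, canonically ordered."""

    edges: pd.DataFrame  # columns: gene_a, gene_b (gene_a < gene_b)
    species: str = ""

    def __post_init__(self) -> None:
        df = self.edges
        if len(df):
            loops = df["gene_a"] == df["gene_b"]
            if loops.any():
                raise MRNetError("self-loop in PPI network")
            a = df[["gene_a", "gene_b"]].min(axis=1)
            b = df[["gene_a", "gene_b"]].max(axis=1)
            df = pd.DataFrame({"gene_a": a, "gene_b": b})
            df = df.drop_duplicates().sort_values(["gene_a", "gene_b"])
        self.edges = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(map(tuple, self.edges.to_numpy()))

    @property
    def nodes(self) -> set[str]:
        if not len(self.edges):
            return set()
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


@dataclass
class PathwayAnnotationTable:
    """Gene -> KEGG orthology (KO) and pathway annotation records."""

    records: pd.DataFrame  # columns: gene_id, ko_id, pathway_id, description

    def __post_init__(self) -> None:
        df = self.records
        bad_ko = [k for k in df["ko_id"].unique() if not _KO_ID.match(str(k))]
        if bad_ko:
            raise MRNetError(f"malformed KO identifier {bad_ko[0]!r}")
        bad_pw = [
            p
            for p in df["pathway_id"].unique()
            if str(p) != "" and not _PATHWAY_ID.match(str(p))
        ]
        if bad_pw:
            raise MRNetError(f"malformed pathway identifier {bad_pw[0]!r}")
        self.records = df.drop_duplicates().reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, **kw)


def read_expression_matrix(
    path: str | Path, groups_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a genes x samples TPM table (first row samples, first column genes).

    Duplicated gene or sample ids, non-numeric cells, empty cells and
    negative values are hard errors naming the offending row/column.
    Gene order in the file is preserved.
    """
    raw = _read_tsv(path, header=0, index_col=0)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise MRNetError(f"duplicate gene id {dup!r} in {path}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise MRNetError(f"duplicate sample id {dup!r} in {path}")
    try:
        values = raw.astype(float)
    except ValueError:
        for gene, row in raw.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except ValueError:
                    raise MRNetError(
                        f"non-numeric cell {cell!r} at gene {gene!r}, "
                        f"sample {sample!r} in {path}"
                    ) from None
        raise
    groups = read_sample_groups(groups_path) if groups_path is not None else None
    return ExpressionMatrix(values=values, sample_groups=groups)


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id<TAB>group design table."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 2:
        raise MRNetError(f"design table {path} needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "group"]
    if len(df) and tuple(df.iloc[0]) == ("sample_id", "group"):
        df = df.iloc[1:]
    return dict(zip(df["sample_id"], df["group"]))


def read_go_annotations(path: str | Path) -> GOAnnotationTable:
    """Read gene_id<TAB>go_term[<TAB>namespace] records; namespace defaults to BP."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 2:
        raise MRNetError(f"GO table {path} needs at least two columns")
    df = df.iloc[:, :3] if df.shape[1] >= 3 else df.iloc[:, :2]
    if df.shape[1] == 2:
        df.columns = ["gene_id", "go_term"]
        df["namespace"] = "BP"
    else:
        df.columns = ["gene_id", "go_term", "namespace"]
        df.loc[df["namespace"] == "", "namespace"] = "BP"
    if len(df) and tuple(df.iloc[0][["gene_id", "go_term"]]) == ("gene_id", "go_term"):
        df = df.iloc[1:].reset_index(drop=True)
    return GOAnnotationTable(records=df.reset_index(drop=True))


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read ref_gene_id<TAB>target_gene_id pairs (extra columns ignored)."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 2:
        raise MRNetError(f"ortholog table {path} needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["ref_gene_id", "target_gene_id"]
    if len(df) and tuple(df.iloc[0]) == ("ref_gene_id", "target_gene_id"):
        df = df.iloc[1:]
    return OrthologMap(records=df.reset_index(drop=True))


def read_ppi_edges(path: str | Path, species: str = "") -> PPINetwork:
    """Read an undirected edge list; self-loops are dropped with a warning."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 2:
        raise MRNetError(f"PPI table {path} needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    if len(df) and tuple(df.iloc[0]) == ("gene_a", "gene_b"):
        df = df.iloc[1:]
    loops = df["gene_a"] == df["gene_b"]
    if loops.any():
        logger.warning(
            "dropping %d self-loop(s) from %s (e.g. %r)",
            int(loops.sum()), path, df.loc[loops, "gene_a"].iloc[0],
        )
        df = df[~loops]
    return PPINetwork(edges=df.reset_index(drop=True), species=species)


def read_kegg_annotations(path: str | Path) -> PathwayAnnotationTable:
    """Read gene_id<TAB>ko_id[<TAB>pathway_id[<TAB>description]] records."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 2:
        raise MRNetError(f"KEGG table {path} needs at least two columns")
    for col in range(df.shape[1], 4):
        df[col] = ""
    df = df.iloc[:, :4]
    df.columns = ["gene_id", "ko_id", "pathway_id", "description"]
    if len(df) and tuple(df.iloc[0][["gene_id", "ko_id"]]) == ("gene_id", "ko_id"):
        df = df.iloc[1:]
    return PathwayAnnotationTable(records=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_groups(groups: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def write_square_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x genes matrix in the expression-matrix dialect."""
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_square_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise MRNetError(f"{path} is not a square gene x gene matrix")
    return df


def write_edge_list(network, path: str | Path) -> None:
    """Write a co-expression network (gene_a, gene_b, pcc, mr, sign) or a
    PPI network (gene_a, gene_b) as a sorted, headered TSV."""
    if isinstance(network, PPINetwork):
        df = network.edges.sort_values(["gene_a", "gene_b"])
    else:  # CoexpressionNetwork duck-typed to avoid an import cycle
        df = network.edges.sort_values(["gene_a", "gene_b"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
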
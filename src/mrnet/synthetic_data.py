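"""Seeded generators for every input table the toolkit consumes.

The expression generator plants co-expression modules with a
latent-factor model on the log scale: for gene i of module m,

    log2(TPM_i + 1) = baseline_i + s_i * lambda * f_m(sample)
                      + shift_i(group) + eps,

with f_m a standard-normal factor drawn per sample, s_i = -1 for the
anti-correlated fraction of each module, eps ~ Normal(0, noise_sd), and
values back-transformed to TPM >= 0.  Two same-sign genes of one module
then have expected correlation lambda^2 / (lambda^2 + noise_sd^2); the
config states that target correlation directly and the loading is solved
from it.  Background genes carry no factor (lambda = 0).

GO annotation follows the planted truth: each module gets its own
biological-process term (so module-sized terms fall inside the 4-20
prior window), while background genes share a handful of large generic
terms that the prior-size filter excludes, as the large
"metabolic-process"-style terms of a real annotation would be.

All generators are pure functions of (config, seed); seeds are mandatory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MRNetError
from .io_formats import (
    ExpressionMatrix,
    GOAnnotationTable,
    OrthologMap,
    PathwayAnnotationTable,
    PPINetwork,
    write_edge_list,
    write_expression_matrix,
    write_sample_groups,
)

#: default study conditions: a miniature of a multi-tissue TPM compendium
#: (300 genes, 30 samples over 5 tissues, 10 planted modules of 10 genes
#: with within-module correlation 0.9, one fruit-elevated module).
DEFAULT_GROUP_LABELS = ("root", "stem", "leaf", "flower", "mature_fruit")


@dataclass
class SimulationConfig:
    """Parameters of the planted-module simulation.

    ``within_module_corr`` is the expected Pearson correlation between
    two same-sign genes of a module (the intraclass correlation
    lambda^2/(lambda^2+noise_sd^2)); the factor loading is derived from
    it.  ``module_group_shifts`` plants log2-scale expression shifts per
    module and group; by default module 0 is elevated 8x in mature
    fruit, mimicking a fruit-ripening expression program.
    """

    seed: int
    n_genes: int = 300
    n_modules: int = 10
    module_size: int = 10
    within_module_corr: float = 0.9
    anti_correlated_fraction: float = 0.0
    noise_sd: float = 0.2
    group_labels: tuple[str, ...] = DEFAULT_GROUP_LABELS
    group_sizes: tuple[int, ...] = (6, 6, 6, 6, 6)
    module_group_shifts: dict[int, dict[str, float]] = field(
        default_factory=lambda: {0: {"mature_fruit": 3.0}}
    )
    baseline_range: tuple[float, float] = (2.0, 7.0)
    background_go_terms: int = 6
    # interolog-transfer fixture parameters
    n_ref_genes: int = 40
    n_target_genes: int = 50
    ref_ppi_edge_prob: float = 0.08
    ortholog_missing_rate: float = 0.2
    max_orthologs_per_ref: int = 2

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise MRNetError("n_modules * module_size exceeds n_genes")
        if not (0.0 <= self.within_module_corr < 1.0):
            raise MRNetError("within_module_corr must be in [0, 1)")
        if not (0.0 <= self.anti_correlated_fraction < 1.0):
            raise MRNetError("anti_correlated_fraction must be in [0, 1)")
        if self.noise_sd <= 0:
            raise MRNetError("noise_sd must be > 0")
        if len(self.group_labels) != len(self.group_sizes):
            raise MRNetError("group_labels and group_sizes differ in length")
        if min(self.group_sizes) < 1 or self.n_genes < 1 or self.module_size < 1:
            raise MRNetError("all counts must be positive")
        unknown = {
            g
            for shifts in self.module_group_shifts.values()
            for g in shifts
        } - set(self.group_labels)
        if unknown:
            raise MRNetError(f"shift refers to unknown group(s): {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def loading(self) -> float:
        rho = self.within_module_corr
        return self.noise_sd * float(np.sqrt(rho / (1.0 - rho))) if rho > 0 else 0.0


@dataclass
class ModuleTruth:
    """Planted ground truth: membership, signs, GO terms and shifts."""

    module_of: dict[str, int | None]
    sign_of: dict[str, int]           # +1 / -1 for module genes, 0 background
    go_term_of_module: dict[int, str]
    group_shift: dict[str, dict[str, float]]  # gene -> group -> log2 shift

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    def within_module_pairs(self, relation: str = "any") -> set[frozenset[str]]:
        """Planted pairs: 'any', 'same' sign, or 'opposite' sign co-members."""
        pairs: set[frozenset[str]] = set()
        modules = sorted({m for m in self.module_of.values() if m is not None})
        for m in modules:
            genes = self.module_genes(m)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    same = self.sign_of[a] == self.sign_of[b]
                    if (
                        relation == "any"
                        or (relation == "same" and same)
                        or (relation == "opposite" and not same)
                    ):
                        pairs.add(frozenset((a, b)))
        return pairs

    def shifted_genes(self, group: str) -> set[str]:
        return {
            g
            for g, shifts in self.group_shift.items()
            if shifts.get(group, 0.0) != 0.0
        }

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "sign_of": self.sign_of,
            "go_term_of_module": self.go_term_of_module,
            "group_shift": self.group_shift,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, ModuleTruth]:
    """Draw a TPM matrix with planted modules and group shifts."""
    rng = _rng(config, 0)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    sample_ids: list[str] = []
    sample_group: dict[str, str] = {}
    for label, size in zip(config.group_labels, config.group_sizes):
        for r in range(size):
            sid = f"{label}_{r + 1}"
            sample_ids.append(sid)
            sample_group[sid] = label
    n, s = config.n_genes, config.n_samples

    module_of: dict[str, int | None] = {g: None for g in genes}
    sign_of: dict[str, int] = {g: 0 for g in genes}
    n_anti = int(np.floor(config.anti_correlated_fraction * config.module_size))
    for m in range(config.n_modules):
        members = genes[m * config.module_size: (m + 1) * config.module_size]
        for j, g in enumerate(members):
            module_of[g] = m
            sign_of[g] = -1 if j >= config.module_size - n_anti else 1

    lam = config.loading
    baseline = rng.uniform(*config.baseline_range, size=n)
    factors = rng.standard_normal((config.n_modules, s))
    eps = rng.normal(0.0, config.noise_sd, size=(n, s))

    shift_mat = np.zeros((n, s))
    group_of_sample = np.array([sample_group[sid] for sid in sample_ids])
    group_shift: dict[str, dict[str, float]] = {}
    for gi, g in enumerate(genes):
        m = module_of[g]
        shifts = config.module_group_shifts.get(m, {}) if m is not None else {}
        group_shift[g] = dict(shifts)
        for grp, delta in shifts.items():
            shift_mat[gi, group_of_sample == grp] += delta

    log2tpm = baseline[:, None] + eps + shift_mat
    for gi, g in enumerate(genes):
        m = module_of[g]
        if m is not None:
            log2tpm[gi] += sign_of[g] * lam * factors[m]
    tpm = np.maximum(np.exp2(log2tpm) - 1.0, 0.0)

    expr = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=genes, columns=sample_ids),
        sample_groups=sample_group,
    )
    truth = ModuleTruth(
        module_of=module_of,
        sign_of=sign_of,
        go_term_of_module={
            m: f"GO:{9000000 + m:07d}" for m in range(config.n_modules)
        },
        group_shift=group_shift,
    )
    return expr, truth


def simulate_go(truth: ModuleTruth, config: SimulationConfig) -> GOAnnotationTable:
    """Annotate module genes with their truth term, background with generic terms."""
    rng = _rng(config, 1)
    rows: list[tuple[str, str, str]] = []
    for g, m in truth.module_of.items():
        if m is not None:
            rows.append((g, truth.go_term_of_module[m], "BP"))
    background = [g for g, m in truth.module_of.items() if m is None]
    terms = [f"GO:{8000000 + j:07d}" for j in range(config.background_go_terms)]
    if background and terms:
        for g in background:
            for t in rng.choice(terms, size=rng.integers(1, 3), replace=False):
                rows.append((g, t, "BP"))
    return GOAnnotationTable(
        records=pd.DataFrame(rows, columns=["gene_id", "go_term", "namespace"])
    )


def simulate_orthologs_and_ppi(
    config: SimulationConfig,
) -> tuple[OrthologMap, PPINetwork, PPINetwork]:
    """Random reference PPI + many-to-many ortholog map + expected projection.

    The expected target network is expanded here by an exhaustive nested
    loop, independent of the transfer implementation, and serves as its
    oracle in tests.
    """
    rng = _rng(config, 2)
    ref_genes = [f"At{i:03d}" for i in range(config.n_ref_genes)]
    target_pool = [f"Rr{i:03d}" for i in range(config.n_target_genes)]

    rows = []
    for i in range(config.n_ref_genes):
        for j in range(i + 1, config.n_ref_genes):
            if rng.random() < config.ref_ppi_edge_prob:
                rows.append((ref_genes[i], ref_genes[j]))
    ref_ppi = PPINetwork(
        edges=pd.DataFrame(rows, columns=["gene_a", "gene_b"]),
        species="reference",
    )

    pairs = []
    for rg in ref_genes:
        if rng.random() < config.ortholog_missing_rate:
            continue
        k = int(rng.integers(1, config.max_orthologs_per_ref + 1))
        for tg in rng.choice(target_pool, size=k, replace=False):
            pairs.append((rg, tg))
    orthos = OrthologMap(
        records=pd.DataFrame(pairs, columns=["ref_gene_id", "target_gene_id"])
    )

    # exhaustive expansion oracle
    mapping: dict[str, list[str]] = {}
    for rg, tg in pairs:
        mapping.setdefault(rg, []).append(tg)
    expected_edges: set[tuple[str, str]] = set()
    for a1, a2 in rows:
        for b1 in mapping.get(a1, ()):
            for b2 in mapping.get(a2, ()):
                if b1 != b2:
                    expected_edges.add((min(b1, b2), max(b1, b2)))
    expected = PPINetwork(
        edges=pd.DataFrame(sorted(expected_edges), columns=["gene_a", "gene_b"]),
        species="target",
    )
    return orthos, ref_ppi, expected


def simulate_kegg(
    config: SimulationConfig, family_kos: dict[str, str] | None = None
) -> tuple[PathwayAnnotationTable, dict[str, set[str]]]:
    """KEGG-style annotation table with planted enzyme-family members.

    ``family_kos`` maps family label -> KO id (defaults to the shipped
    ascorbate map's first KO per family).  Returns the table plus the
    planted family -> gene truth.
    """
    from .pathway_screen import default_family_map

    rng = _rng(config, 3)
    if family_kos is None:
        fam = default_family_map()
        family_kos = {
            label: sorted(rule.kos)[0] if rule.kos else ""
            for label, rule in fam.families.items()
        }
        keywords = {
            label: rule.keywords[0] if rule.keywords else label
            for label, rule in fam.families.items()
        }
    else:
        keywords = {label: label for label in family_kos}

    rows: list[tuple[str, str, str, str]] = []
    truth: dict[str, set[str]] = {}
    i = 0
    for label in sorted(family_kos):
        members = set()
        for _ in range(int(rng.integers(1, 5))):
            gene = f"k{i:04d}"
            i += 1
            ko = family_kos[label] or f"K{99000 + i:05d}"
            rows.append((gene, ko, "map00053", f"{keywords[label]} [EC candidate]"))
            members.add(gene)
        truth[label] = members
    for _ in range(30):  # decoys with unrelated KOs and descriptions
        gene = f"k{i:04d}"
        i += 1
        rows.append(
            (gene, f"K{10000 + int(rng.integers(0, 5000)):05d}", "",
             "hypothetical protein of unrelated function")
        )
    table = PathwayAnnotationTable(
        records=pd.DataFrame(
            rows, columns=["gene_id", "ko_id", "pathway_id", "description"]
        )
    )
    return table, truth


def write_fixtures(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write the full fixture set for one config.

    Writes expr.tsv, design.tsv, go.tsv, orthologs.tsv, ref_ppi.tsv,
    expected_target_ppi.tsv, kegg.tsv and truth.json; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = simulate_expression(config)
    go = simulate_go(truth, config)
    orthos, ref_ppi, expected = simulate_orthologs_and_ppi(config)
    kegg, _ = simulate_kegg(config)

    paths = {
        "expr": outdir / "expr.tsv",
        "design": outdir / "design.tsv",
        "go": outdir / "go.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "ref_ppi": outdir / "ref_ppi.tsv",
        "expected_target_ppi": outdir / "expected_target_ppi.tsv",
        "kegg": outdir / "kegg.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression_matrix(expr, paths["expr"])
    write_sample_groups(expr.sample_groups, paths["design"])
    go.records.to_csv(paths["go"], sep="\t", index=False, header=False)
    orthos.records.to_csv(paths["orthologs"], sep="\t", index=False, header=False)
    write_edge_list(ref_ppi, paths["ref_ppi"])
    write_edge_list(expected, paths["expected_target_ppi"])
    kegg.records.to_csv(paths["kegg"], sep="\t", index=False, header=False)
    truth.to_json(paths["truth"])
    return paths
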
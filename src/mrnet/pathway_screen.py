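"""Pathway gene-family screening and tissue-elevated expression flags.

A family map (label -> KO identifiers and/or description keywords)
assigns genes from a KEGG annotation table to enzyme families; the
shipped default covers the 18 families of the L-ascorbate biosynthesis
pathway.  A separate screen flags genes whose expression is elevated in
one target tissue: the target-group mean must dominate every other
tissue mean by a fold factor *and* the target-vs-pooled-others
comparison must be a significant up-call under the DEG defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .deg_overlay import call_degs
from .errors import MRNetError
from .io_formats import ExpressionMatrix, PathwayAnnotationTable


@dataclass
class FamilyRule:
    kos: frozenset[str]
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.kos and not self.keywords:
            raise MRNetError("family rule must list at least one KO or keyword")


@dataclass
class FamilyMap:
    """Family label -> matching rule, with optional label aliases."""

    families: dict[str, FamilyRule]
    aliases: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.families:
            raise MRNetError("empty family map")
        self.aliases = self.aliases or {}
        for alias, label in self.aliases.items():
            if label not in self.families:
                raise MRNetError(f"alias {alias!r} points to unknown family {label!r}")

    def resolve(self, label: str) -> str:
        return self.aliases.get(label, label)

    def __len__(self) -> int:
        return len(self.families)


@dataclass
class FamilyAssignments:
    """Gene -> family assignments with the rule evidence that matched."""

    records: pd.DataFrame  # columns: gene_id, family, evidence

    @property
    def counts(self) -> pd.Series:
        return (
            self.records.drop_duplicates(subset=["gene_id", "family"])["family"]
            .value_counts()
            .sort_index()
        )

    def genes_of(self, family: str) -> set[str]:
        return set(self.records.loc[self.records["family"] == family, "gene_id"])

    def __len__(self) -> int:
        return len(self.records)


def load_family_map(path) -> FamilyMap:
    """Load a families.yaml file: family -> {kos: [...], keywords: [...]}."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise MRNetError(f"no families defined in {path}")
    families: dict[str, FamilyRule] = {}
    aliases: dict[str, str] = {}
    for label, rule in raw.items():
        rule = rule or {}
        families[label] = FamilyRule(
            kos=frozenset(rule.get("kos") or ()),
            keywords=tuple(rule.get("keywords") or ()),
        )
        for alias in rule.get("aliases") or ():
            aliases[alias] = label
    return FamilyMap(families=families, aliases=aliases)


def default_family_map() -> FamilyMap:
    """The shipped 18-family L-ascorbate biosynthesis map."""
    ref = resources.files("mrnet") / "data" / "ascorbate_families.yaml"
    with resources.as_file(ref) as path:
        return load_family_map(path)


def screen_families(
    kegg: PathwayAnnotationTable, fam: FamilyMap
) -> FamilyAssignments:
    """Assign genes to families by KO membership or description keyword.

    Keyword matching is case-insensitive on whole words; the evidence
    column records which KO or keyword matched.  Deterministic and
    independent of input row order.
    """
    if not len(fam):
        raise MRNetError("empty family map")
    patterns = {
        label: [
            (kw, re.compile(rf"\b{re.escape(kw)}\b", re.IGNORECASE))
            for kw in rule.keywords
        ]
        for label, rule in fam.families.items()
    }
    rows: list[tuple[str, str, str]] = []
    for gene, ko, _, desc in (
        kegg.records[["gene_id", "ko_id", "pathway_id", "description"]]
        .itertuples(index=False)
    ):
        for label, rule in fam.families.items():
            if ko in rule.kos:
                rows.append((gene, label, f"KO:{ko}"))
                continue
            for kw, pat in patterns[label]:
                if pat.search(str(desc)):
                    rows.append((gene, label, f"keyword:{kw}"))
                    break
    df = pd.DataFrame(rows, columns=["gene_id", "family", "evidence"])
    df = df.drop_duplicates(subset=["gene_id", "family"]).sort_values(
        ["family", "gene_id"]
    )
    return FamilyAssignments(records=df.reset_index(drop=True))


def tissue_elevated(
    expr: ExpressionMatrix,
    target: str,
    fold: float = 2.0,
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Flag genes with expression elevated in the ``target`` tissue.

    A gene is flagged when its mean TPM in the target group is at least
    ``fold`` times the largest mean of any other group, and the
    target-vs-pooled-others comparison calls it 'up' (Welch test on
    log2(TPM+1), BH-adjusted p < alpha, log2FC >= fc_threshold).

    Returns a per-gene table with the group means, the dominance ratio,
    the adjusted p and the final flag.
    """
    if expr.sample_groups is None:
        raise MRNetError("tissue_elevated requires a sample-group design")
    groups = sorted(set(expr.sample_groups.values()))
    if target not in groups:
        raise MRNetError(f"target group {target!r} not in design ({groups})")
    others = [g for g in groups if g != target]
    if not others:
        raise MRNetError("need at least one non-target group")
    target_samples = expr.group_samples(target)
    if len(target_samples) < 2:
        raise MRNetError(f"target group {target!r} needs >= 2 samples")
    means = {
        g: expr.values[expr.group_samples(g)].mean(axis=1) for g in groups
    }
    max_other = pd.concat([means[g] for g in others], axis=1).max(axis=1)
    # pooled-others significance test reuses the DEG caller verbatim
    pooled_design = {
        s: (target if expr.sample_groups[s] == target else "_others")
        for s in expr.sample_groups
    }
    pooled = ExpressionMatrix(values=expr.values, sample_groups=pooled_design)
    degs = call_degs(
        pooled, target, "_others", fc_threshold=fc_threshold, alpha=alpha
    )
    up = degs.records.set_index("gene_id")
    dominance = means[target] >= fold * max_other
    flagged = dominance & (up["direction"] == "up")
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "target_mean": means[target],
            "max_other_mean": max_other,
            "dominant": dominance,
            "adjusted_p": up["adjusted_p"],
            "flagged": flagged,
        }
    ).reset_index(drop=True)
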
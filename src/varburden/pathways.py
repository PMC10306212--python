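"""Pathway-level burden testing by summing per-gene qualifying-variant counts.

Gene sets (KEGG / Reactome / Biocarta style) are first restricted to genes
that actually carry qualifying case variants; each surviving set's case and
control counts are the sums over its member genes, and the same Fisher
machinery used for genes tests the pathway table.  Because counts are summed,
an individual carrying variants in two member genes is counted twice on the
case side; the table is capped at the cohort size and the cap recorded as a
warning when that happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .burden import BurdenResult, GeneCount, fisher_two_sided, odds_ratio
from .qualify import SnpMap


@dataclass(frozen=True)
class GeneSet:
    name: str
    database: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets with source-database labels.

    ``parents`` optionally maps a low-level pathway name to its high-level
    hierarchy label; it is pass-through annotation only — tests always run on
    the low-level sets.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    parents: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def by_database(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for gene_set in self.sets.values():
            counts[gene_set.database] = counts.get(gene_set.database, 0) + 1
        return counts


@dataclass(frozen=True)
class PathwayCount:
    """Summed qualifying-variant counts for one pathway."""

    pathway: str
    database: str
    contributing_genes: tuple[str, ...]
    case_count: int
    control_count: int
    n_cases: int
    n_controls: int


def restrict_sets(sets: GeneSetCollection, snp_map: SnpMap) -> GeneSetCollection:
    """Intersect every set with the SNP-map genes; drop empty intersections.

    The result is what "pathways detected in this arm" means: only genes with
    qualifying case variants can contribute counts.  Idempotent.
    """
    present = set(snp_map)
    kept = {}
    for name, gene_set in sets.sets.items():
        genes = gene_set.genes & present
        if genes:
            kept[name] = GeneSet(name=name, database=gene_set.database, genes=genes)
    return GeneSetCollection(
        sets=kept, parents={n: p for n, p in sets.parents.items() if n in kept}
    )


def aggregate_pathway(
    counts: Mapping[str, GeneCount], gene_set: GeneSet
) -> PathwayCount:
    """Sum case and control counts over the set's member genes.

    Every member gene must have a count row; a gene that belongs to several
    pathways contributes to all of them.  Control sums are capped at the
    control cohort size.
    """
    members = sorted(gene_set.genes)
    missing = [g for g in members if g not in counts]
    if missing:
        raise ValueError(
            f"pathway {gene_set.name!r}: no counts for member genes {missing}"
        )
    n_cases = counts[members[0]].n_cases
    n_controls = counts[members[0]].n_controls
    case_count = sum(counts[g].case_carriers for g in members)
    control_count = min(sum(counts[g].control_count for g in members), n_controls)
    return PathwayCount(
        pathway=gene_set.name,
        database=gene_set.database,
        contributing_genes=tuple(members),
        case_count=case_count,
        control_count=control_count,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def pathway_burden(
    pathway_counts: list[PathwayCount],
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> list[BurdenResult]:
    """Fisher two-sided test per pathway (raw p-values only).

    ``n_tests`` pools every database within the analysis arm — multiplicity
    is corrected over all pathways tested together, redundancy across the
    source databases included (which makes the correction conservative).
    The case-side sum can exceed the number of cases when one individual
    carries variants in several member genes; the table is capped at the
    cohort size and the result flagged.
    """
    results: list[BurdenResult] = []
    for pc in sorted(pathway_counts, key=lambda p: p.pathway):
        ncase = n_cases if n_cases is not None else pc.n_cases
        nctrl = n_controls if n_controls is not None else pc.n_controls
        warning = ""
        a = pc.case_count
        if a > ncase:
            a = ncase
            warning = "case_count_capped_at_n_cases"
        c = min(pc.control_count, nctrl)
        b, d = ncase - a, nctrl - c
        results.append(
            BurdenResult(
                unit=pc.pathway,
                table=(a, b, c, d),
                odds_ratio=odds_ratio(a, b, c, d),
                p_raw=fisher_two_sided(a, b, c, d),
                database=pc.database,
                contributing_genes=pc.contributing_genes,
                warning=warning,
            )
        )
    for result in results:
        result.n_tests = len(results)
    return results
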
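import pytest

from varburden import (
    GeneCount,
    GeneSet,
    GeneSetCollection,
    aggregate_pathway,
    pathway_burden,
    restrict_sets,
)
from varburden import datasets

# published per-pathway (case, control) count pairs by analysis arm;
# the peroxisome pair at gnomAD <= 0.1% is excluded because the underlying
# per-gene table prints internally inconsistent case cells for that arm
PUBLISHED_PAIRS = {
    ("gnomad", 0.01): {
        "Olfactory transduction": (15, 4772),
        "Peroxisome": (6, 609),
        "FCERI mediated Ca+2 mobilization": (4, 90),
        "FCERI mediated MAPK activation": (4, 90),
        "Antigen activates B Cell Receptor (BCR) leading to generation of "
        "second messengers": (4, 110),
        "FCGR activation": (3, 77),
        "FCGR3A-mediated IL10 synthesis": (3, 77),
        "FCGR3A-mediated phagocytosis": (3, 77),
        "Regulation of actin dynamics for phagocytic cup formation": (3, 77),
        "Role of LAT2/NTAL/LAB on calcium mobilization": (3, 77),
        "Role of phospholipids in phagocytosis": (3, 77),
        "DAP12 signaling": (2, 15),
    },
    ("exac", 0.01): {
        "Olfactory transduction": (14, 2564),
        "Peroxisome": (6, 316),
    },
    ("gnomad", 0.001): {
        "Olfactory transduction": (6, 349),
        "Purine metabolism": (4, 274),
        "Post-translational protein phosphorylation": (3, 116),
        "Regulation of Insulin-like Growth Factor (IGF) transport and uptake "
        "by Insulin-like Growth Factor Binding Proteins (IGFBPs)": (3, 116),
        "FCERI mediated Ca+2 mobilization": (4, 90),
        "FCERI mediated MAPK activation": (4, 90),
        "Antigen activates B Cell Receptor (BCR) leading to generation of "
        "second messengers": (4, 110),
        "FCGR activation": (3, 77),
        "FCGR3A-mediated IL10 synthesis": (3, 77),
        "FCGR3A-mediated phagocytosis": (3, 77),
        "Regulation of actin dynamics for phagocytic cup formation": (3, 77),
        "Role of LAT2/NTAL/LAB on calcium mobilization": (3, 77),
        "Role of phospholipids in phagocytosis": (3, 77),
        "DAP12 signaling": (2, 15),
        "Tryptophan metabolism": (4, 266),
        "Retinol metabolism": (4, 275),
        "Drug metabolism cytochrome p450": (4, 310),
    },
    ("exac", 0.001): {
        "Olfactory transduction": (6, 283),
        "Peroxisome": (6, 315),
        "Purine metabolism": (4, 151),
        "Post-translational protein phosphorylation": (3, 71),
        "Regulation of Insulin-like Growth Factor (IGF) transport and uptake "
        "by Insulin-like Growth Factor Binding Proteins (IGFBPs)": (3, 71),
    },
}


def _arm_pathway_counts(control_set, af_max):
    counts = datasets.gene_counts(control_set, af_max)
    snp_map = {gene: [] for gene in counts}
    restricted = restrict_sets(datasets.pathway_sets(), snp_map)
    return {
        name: aggregate_pathway(counts, restricted.sets[name])
        for name in restricted.sets
    }


@pytest.mark.parametrize("arm", sorted(PUBLISHED_PAIRS), ids=lambda a: f"{a[0]}-{a[1]:g}")
def test_published_pathway_count_pairs_reproduce(arm):
    """Summing bundled per-gene counts reproduces the published per-pathway
    case/control counts of the familial lymphoid-cancer study, per arm."""
    pathway_counts = _arm_pathway_counts(*arm)
    for pathway, (cases, controls) in PUBLISHED_PAIRS[arm].items():
        pc = pathway_counts[pathway]
        assert (pc.case_count, pc.control_count) == (cases, controls), pathway


def test_peroxisome_member_genes_match_published_rows():
    sets = datasets.pathway_sets()
    assert sets.sets["Peroxisome"].genes == {"CROT", "GSTK1", "EHHADH", "PEX7"}
    assert sets.parents["DAP12 signaling"] == "Innate Immune System"


def test_counts_conserved_across_aggregation():
    """Every pathway count equals the sum over its contributing genes."""
    for arm in datasets.ARMS:
        counts = datasets.gene_counts(*arm)
        for pc in _arm_pathway_counts(*arm).values():
            assert pc.case_count == sum(
                counts[g].case_carriers for g in pc.contributing_genes
            )
            assert pc.control_count == min(
                sum(counts[g].control_count for g in pc.contributing_genes),
                pc.n_controls,
            )


def _count(gene, case, ctrl, n_cases=38, n_controls=56_885):
    return GeneCount(
        gene=gene,
        case_carriers=case,
        case_alleles=case,
        control_count=ctrl,
        n_cases=n_cases,
        n_controls=n_controls,
    )


class TestRestrictSets:
    COLLECTION = GeneSetCollection(
        sets={
            "SETA": GeneSet("SETA", "KEGG", frozenset({"G1", "G2", "G3"})),
            "SETB": GeneSet("SETB", "Reactome", frozenset({"G9"})),
        }
    )

    def test_intersection_and_dropping(self):
        restricted = restrict_sets(self.COLLECTION, {"G1": [], "G3": []})
        assert set(restricted.sets) == {"SETA"}
        assert restricted.sets["SETA"].genes == {"G1", "G3"}

    def test_idempotent(self):
        once = restrict_sets(self.COLLECTION, {"G1": [], "G9": []})
        twice = restrict_sets(once, {"G1": [], "G9": []})
        assert {n: s.genes for n, s in once.sets.items()} == {
            n: s.genes for n, s in twice.sets.items()
        }

    def test_database_tally(self):
        restricted = restrict_sets(self.COLLECTION, {"G1": [], "G9": []})
        assert restricted.by_database() == {"KEGG": 1, "Reactome": 1}


class TestPathwayBurden:
    def test_single_member_pathway_matches_gene_table(self):
        counts = {"G1": _count("G1", 2, 15)}
        pc = aggregate_pathway(counts, GeneSet("P", "KEGG", frozenset({"G1"})))
        result = pathway_burden([pc])[0]
        assert result.table == (2, 36, 15, 56_870)

    def test_zero_count_gene_does_not_change_p(self):
        counts = {"G1": _count("G1", 2, 15), "G0": _count("G0", 0, 0)}
        lone = aggregate_pathway(counts, GeneSet("P", "KEGG", frozenset({"G1"})))
        padded = aggregate_pathway(counts, GeneSet("P", "KEGG", frozenset({"G1", "G0"})))
        assert pathway_burden([lone])[0].p_raw == pathway_burden([padded])[0].p_raw

    def test_missing_member_count_is_an_error(self):
        with pytest.raises(ValueError, match="no counts"):
            aggregate_pathway({}, GeneSet("P", "KEGG", frozenset({"G1"})))

    def test_case_sum_capped_at_cohort_size_with_warning(self):
        counts = {
            f"G{i}": _count(f"G{i}", 5, 10, n_cases=8) for i in range(3)
        }
        pc = aggregate_pathway(
            counts, GeneSet("P", "KEGG", frozenset(counts))
        )
        assert pc.case_count == 15
        result = pathway_burden([pc])[0]
        assert result.table[0] == 8
        assert result.warning == "case_count_capped_at_n_cases"

    def test_n_tests_pools_databases(self):
        counts = {"G1": _count("G1", 1, 5), "G2": _count("G2", 1, 7)}
        pcs = [
            aggregate_pathway(counts, GeneSet("A", "KEGG", frozenset({"G1"}))),
            aggregate_pathway(counts, GeneSet("B", "Reactome", frozenset({"G2"}))),
        ]
        assert [r.n_tests for r in pathway_burden(pcs)] == [2, 2]
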
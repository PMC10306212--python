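"""Bundled reference counts from a familial lymphoid-cancer burden study.

A published exome study of 38 European familial lymphoid-cancer cases tested
rare-variant burden against two public control cohorts (gnomAD exomes,
N = 56,885, and ExAC, N = 33,370 non-Finnish Europeans) at two allele
frequency thresholds (<= 1% and <= 0.1%).  Its per-gene qualifying-variant
counts for the significantly associated pathways are bundled here as a small
worked dataset: they exercise the pathway aggregation end to end, because the
published per-pathway counts are exactly the sums of these per-gene counts.

Two printed cells are internally inconsistent: the peroxisome-pathway rows
for EHHADH and PEX7 show 1 case variant at gnomAD <= 0.1%, yet the same
gene's tryptophan-metabolism row, the ExAC columns, and the published
per-pathway total (6) all imply 2.  Both cells are flagged and resolved to 2
by default; ``resolve_inconsistent=False`` keeps the printed 1s.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .burden import GeneCount
from .pathways import GeneSet, GeneSetCollection

N_CASES = 38
N_CONTROLS = {"gnomad": 56_885, "exac": 33_370}
ARMS = [
    ("gnomad", 0.01),
    ("gnomad", 0.001),
    ("exac", 0.01),
    ("exac", 0.001),
]

# per-gene qualifying-variant counts; '.' = gene absent from that arm
# columns: case/control pairs for gnomad<=1%, gnomad<=0.1%, exac<=1%, exac<=0.1%
_GENE_COUNTS_TSV = """\
gene	g1_case	g1_ctrl	g01_case	g01_ctrl	e1_case	e1_ctrl	e01_case	e01_ctrl	inconsistent
BLK	1	33	1	33	.	.	.	.	0
IGLV3-25	1	27	1	27	.	.	.	.	0
IGLV7-43	1	48	1	48	.	.	.	.	0
SYK	1	2	1	2	.	.	.	.	0
GRAP2	1	13	1	13	.	.	.	.	0
AMBN	.	.	1	53	.	.	1	24	0
CP	.	.	1	34	.	.	1	22	0
PENK	.	.	1	29	.	.	1	25	0
AOX1	.	.	1	85	.	.	.	.	0
CYP2B6	.	.	1	45	.	.	.	.	0
FMO3	.	.	1	113	.	.	.	.	0
GSTK1	1	67	1	67	1	51	1	51	0
OR1N2	1	41	1	41	1	58	1	58	0
OR2AG2	1	61	1	61	1	39	1	39	0
OR52B2	1	54	1	54	1	29	1	29	0
OR52M1	1	488	1	119	1	287	1	54	0
OR6V1	2	245	1	22	1	52	1	52	0
OR6C6	1	52	.	.	1	51	1	51	0
OR6C4	1	138	1	52	1	32	.	.	0
GUCA1C	2	937	.	.	2	425	.	.	0
OR10C1	2	664	.	.	2	388	.	.	0
OR51E1	1	164	.	.	1	109	.	.	0
OR51G1	1	1458	.	.	1	835	.	.	0
OR6C70	1	470	.	.	1	259	.	.	0
CROT	1	317	1	317	1	160	1	159	0
EHHADH	2	119	2	119	2	58	2	58	1
PEX7	2	106	2	106	2	47	2	47	1
AMPD1	.	.	1	52	.	.	1	25	0
ATIC	.	.	1	73	.	.	1	47	0
NUDT2	.	.	1	34	.	.	1	14	0
PDE11A	.	.	1	115	.	.	1	65	0
CYP1A1	.	.	1	62	.	.	.	.	0
DGAT2	.	.	1	116	.	.	.	.	0
RPE65	.	.	1	52	.	.	.	.	0
"""

# printed-but-inconsistent gnomAD <= 0.1% case cells (peroxisome rows)
_PRINTED_GNOMAD01_CASES = {"EHHADH": 1, "PEX7": 1}

_ARM_COLUMNS = {
    ("gnomad", 0.01): ("g1_case", "g1_ctrl"),
    ("gnomad", 0.001): ("g01_case", "g01_ctrl"),
    ("exac", 0.01): ("e1_case", "e1_ctrl"),
    ("exac", 0.001): ("e01_case", "e01_ctrl"),
}

# pathway -> (database, high-level hierarchy label, member genes with counts)
_PATHWAYS: dict[str, tuple[str, str, tuple[str, ...]]] = {
    "Antigen activates B Cell Receptor (BCR) leading to generation of second messengers": (
        "Reactome",
        "Adaptive Immune System",
        ("BLK", "IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "DAP12 signaling": ("Reactome", "Innate Immune System", ("GRAP2", "SYK")),
    "FCERI mediated Ca+2 mobilization": (
        "Reactome",
        "Innate Immune System",
        ("GRAP2", "IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "FCERI mediated MAPK activation": (
        "Reactome",
        "Innate Immune System",
        ("GRAP2", "IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "FCGR activation": (
        "Reactome",
        "Innate Immune System",
        ("IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "Regulation of actin dynamics for phagocytic cup formation": (
        "Reactome",
        "Innate Immune System",
        ("IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "Role of LAT2/NTAL/LAB on calcium mobilization": (
        "Reactome",
        "Innate Immune System",
        ("IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "Role of phospholipids in phagocytosis": (
        "Reactome",
        "Innate Immune System",
        ("IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "FCGR3A-mediated IL10 synthesis": (
        "Reactome",
        "Leishmania infection",
        ("IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "FCGR3A-mediated phagocytosis": (
        "Reactome",
        "Leishmania infection",
        ("IGLV3-25", "IGLV7-43", "SYK"),
    ),
    "Post-translational protein phosphorylation": (
        "Reactome",
        "Metabolism of proteins",
        ("AMBN", "CP", "PENK"),
    ),
    "Regulation of Insulin-like Growth Factor (IGF) transport and uptake by "
    "Insulin-like Growth Factor Binding Proteins (IGFBPs)": (
        "Reactome",
        "Metabolism of proteins",
        ("AMBN", "CP", "PENK"),
    ),
    "Drug metabolism cytochrome p450": (
        "KEGG",
        "",
        ("AOX1", "CYP2B6", "FMO3", "GSTK1"),
    ),
    "Olfactory transduction": (
        "KEGG",
        "",
        (
            "OR1N2",
            "OR2AG2",
            "OR52B2",
            "OR52M1",
            "OR6V1",
            "OR6C6",
            "OR6C4",
            "GUCA1C",
            "OR10C1",
            "OR51E1",
            "OR51G1",
            "OR6C70",
        ),
    ),
    "Peroxisome": ("KEGG", "", ("CROT", "GSTK1", "EHHADH", "PEX7")),
    "Purine metabolism": ("KEGG", "", ("AMPD1", "ATIC", "NUDT2", "PDE11A")),
    "Retinol metabolism": ("KEGG", "", ("CYP1A1", "CYP2B6", "DGAT2", "RPE65")),
    "Tryptophan metabolism": ("KEGG", "", ("AOX1", "CYP1A1", "EHHADH")),
}


def counts_frame(resolve_inconsistent: bool = True) -> pd.DataFrame:
    """The full per-gene count table, one row per gene, '.' cells as NA."""
    frame = pd.read_csv(
        _io.StringIO(_GENE_COUNTS_TSV), sep="\t", na_values=".", dtype={"gene": str}
    )
    if not resolve_inconsistent:
        for gene, printed in _PRINTED_GNOMAD01_CASES.items():
            frame.loc[frame["gene"] == gene, "g01_case"] = printed
    return frame


def gene_counts(
    control_set: str = "gnomad",
    af_max: float = 0.01,
    resolve_inconsistent: bool = True,
) -> dict[str, GeneCount]:
    """Per-gene counts for one analysis arm, keyed by gene symbol.

    Only genes with qualifying case variants in that arm are present (that is
    the published SNP-map restriction); the printed case numbers are variant
    counts, used for both the carrier and allele slots.
    """
    case_col, ctrl_col = _ARM_COLUMNS[(control_set, af_max)]
    n_controls = N_CONTROLS[control_set]
    out: dict[str, GeneCount] = {}
    for row in counts_frame(resolve_inconsistent).itertuples(index=False):
        case = getattr(row, case_col)
        ctrl = getattr(row, ctrl_col)
        if pd.isna(case) or pd.isna(ctrl):
            continue
        out[row.gene] = GeneCount(
            gene=row.gene,
            case_carriers=int(case),
            case_alleles=int(case),
            control_count=int(ctrl),
            n_cases=N_CASES,
            n_controls=n_controls,
        )
    return out


def pathway_sets() -> GeneSetCollection:
    """The associated pathways as a gene-set collection with hierarchy labels."""
    sets = {
        name: GeneSet(name=name, database=db, genes=frozenset(genes))
        for name, (db, _, genes) in _PATHWAYS.items()
    }
    parents = {
        name: parent for name, (_, parent, _) in _PATHWAYS.items() if parent
    }
    return GeneSetCollection(sets=sets, parents=parents)


def write_fixture(out_dir: str | Path) -> dict[str, Path]:
    """Write the bundled counts (one count file per arm) and the pathway GMT."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for control_set, af_max in ARMS:
        label = f"{control_set}_af{af_max:g}".replace("0.", "")
        rows = [
            {
                "gene": c.gene,
                "case_carriers": c.case_carriers,
                "case_alleles": c.case_alleles,
                "control_count": c.control_count,
                "n_cases": c.n_cases,
                "n_controls": c.n_controls,
            }
            for c in gene_counts(control_set, af_max).values()
        ]
        path = out / f"counts_{label}.tsv"
        pd.DataFrame(rows).sort_values("gene").to_csv(path, sep="\t", index=False)
        paths[label] = path
    gmt_lines = []
    collection = pathway_sets()
    for name in sorted(collection.sets):
        gene_set = collection.sets[name]
        desc = gene_set.database
        if name in collection.parents:
            desc += "|" + collection.parents[name]
        gmt_lines.append("\t".join([name, desc] + sorted(gene_set.genes)))
    gmt_path = out / "pathways.gmt"
    gmt_path.write_text("\n".join(gmt_lines) + "\n", encoding="utf-8")
    paths["gmt"] = gmt_path
    return paths
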
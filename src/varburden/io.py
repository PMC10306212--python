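"""Readers and writers for every external format the pipeline touches.

Inputs: a jointly-called multi-sample VCF for cases, tab-separated allele
count summaries for public controls, tab-separated coverage tracks, a
tab-separated variant annotation table, and GMT gene-set files.  Outputs: the
three tabular burden-analysis files (SNP map, counts, burden results) plus QQ
data, all tab-delimited with deterministic lexicographic row order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .coverage import CoverageProfile
from .variants import AnnotatedVariant, VariantKey, normalize_variant, split_multiallelic


# ---------------------------------------------------------------------------
# in-memory containers


@dataclass
class CaseCohort:
    """Case samples with per-variant alternate-allele dosages.

    ``dosage[key]`` is an int8 array aligned to ``sample_ids`` with values in
    {0, 1, 2}.  Missing genotypes (./.) are recorded as dosage 0: with a
    handful of cases, dropping a carrier is conservative for case counts.
    """

    sample_ids: list[str]
    dosage: dict[VariantKey, np.ndarray] = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.sample_ids)

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("cohort must contain at least one sample")


@dataclass
class ControlSummary:
    """Per-variant allele-count summary for a public control cohort.

    Only PASS sites are stored.  A variant absent from the summary is read as
    allele count 0: public summaries omit unobserved alleles, and the joint
    coverage gate has already guaranteed the region was callable in controls.
    """

    n_controls: int
    records: dict[VariantKey, tuple[int, int, int]] = field(default_factory=dict)
    # records[key] = (ac, an, n_hom)

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValueError("control cohort size must be positive")

    def add(self, key: VariantKey, ac: int, an: int, n_hom: int) -> None:
        if not 0 <= ac <= an:
            raise ValueError(f"{key}: allele count {ac} exceeds allele number {an}")
        if an > 2 * self.n_controls:
            raise ValueError(f"{key}: allele number {an} exceeds 2 x cohort size")
        if 2 * n_hom > ac:
            raise ValueError(f"{key}: homozygote count {n_hom} inconsistent with ac {ac}")
        self.records[key] = (ac, an, n_hom)

    def ac(self, key: VariantKey) -> int:
        return self.records.get(key, (0, 0, 0))[0]

    def n_hom(self, key: VariantKey) -> int:
        return self.records.get(key, (0, 0, 0))[2]


# ---------------------------------------------------------------------------
# readers


def read_case_vcf(
    path: str | os.PathLike,
    keep_filter: frozenset[str] | set[str] = frozenset({"PASS"}),
) -> tuple[CaseCohort, list[tuple[VariantKey, str]]]:
    """Read a jointly-called multi-sample VCF into a :class:`CaseCohort`.

    Multiallelic records are split into biallelic keys and normalized before
    the FILTER rule is applied.  Returns the cohort (dosages only for records
    whose FILTER is in ``keep_filter``) and the full list of (key, filter
    status) pairs seen, excluded records included.  A record with no FILTER
    entry ('.') is treated as PASS, matching common joint-calling output.
    """
    if not keep_filter:
        raise ValueError("keep_filter must be non-empty")
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains zero samples")
    cohort = CaseCohort(sample_ids=samples)
    seen: list[tuple[VariantKey, str]] = []
    for rec in vcf:
        filt = ";".join(rec.filter.keys()) or "PASS"
        keep = filt in keep_filter
        if rec.alts is None:
            continue
        for alt_index, key in split_multiallelic(
            rec.chrom, rec.pos, rec.ref, tuple(rec.alts)
        ):
            seen.append((key, filt))
            if not keep:
                continue
            dos = np.zeros(len(samples), dtype=np.int8)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT") or ()
                dos[i] = sum(1 for allele in gt if allele == alt_index)
            if key in cohort.dosage:
                # the same normalized key can arise from two input records
                dos = np.minimum(cohort.dosage[key] + dos, 2).astype(np.int8)
            cohort.dosage[key] = dos
    vcf.close()
    return cohort, seen


def read_control_summary(path: str | os.PathLike, n_controls: int) -> ControlSummary:
    """Read a tab-separated control site table into a :class:`ControlSummary`.

    Expected columns: chrom, pos, ref, alt, ac, an, n_hom, filter.
    Multiallelic rows may carry comma-separated alt / ac / n_hom fields and
    are split with the same normalization as case variants.  Only PASS rows
    are retained; invariant violations raise with the 1-based data row number.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt", "ac", "an", "n_hom", "filter"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"control summary missing columns: {sorted(missing)}")
    summary = ControlSummary(n_controls=n_controls)
    for row_number, row in enumerate(table.itertuples(index=False), start=1):
        if row.filter != "PASS":
            continue
        alts = str(row.alt).split(",")
        acs = str(row.ac).split(",")
        homs = str(row.n_hom).split(",")
        if not len(alts) == len(acs) == len(homs):
            raise ValueError(
                f"row {row_number}: alt/ac/n_hom arity mismatch in {path}"
            )
        an = int(row.an)
        for split_index, key in split_multiallelic(
            str(row.chrom), int(row.pos), str(row.ref), tuple(alts)
        ):
            try:
                summary.add(
                    key, int(acs[split_index - 1]), an, int(homs[split_index - 1])
                )
            except ValueError as exc:
                raise ValueError(f"row {row_number}: {exc}") from exc
    return summary


def read_coverage(path: str | os.PathLike) -> CoverageProfile:
    """Read a chrom/start/end/fraction coverage track (0-based half-open)."""
    return CoverageProfile.from_frame(pd.read_csv(path, sep="\t"))


def read_annotations(path: str | os.PathLike) -> list[AnnotatedVariant]:
    """Read the variant annotation table.

    Expected columns: chrom, pos, ref, alt, gene, consequence, cadd_phred and
    any number of allele-frequency columns prefixed ``af_``; empty AF cells
    mean the variant is absent from that source.  A variant mapping to more
    than one gene appears as one row per gene.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "cadd_phred"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    af_cols = [c for c in table.columns if c.startswith("af_")]
    out: list[AnnotatedVariant] = []
    for row in table.itertuples(index=False):
        key = normalize_variant(
            VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        )
        afs = {
            c: float(getattr(row, c))
            for c in af_cols
            if pd.notna(getattr(row, c))
        }
        out.append(
            AnnotatedVariant(
                key=key,
                gene=str(row.gene),
                consequence=str(row.consequence),
                cadd_phred=float(row.cadd_phred),
                af_by_source=afs,
                filter_status=str(getattr(row, "filter", "PASS")),
            )
        )
    return out


def read_gmt(path: str | os.PathLike, database: str | None = None):
    """Read a GMT gene-set file into a :class:`~varburden.pathways.GeneSetCollection`.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    gene symbols within a line are collapsed.  When ``database`` is not given
    it is inferred from a KEGG_/REACTOME_/BIOCARTA_ name prefix.
    """
    from .pathways import GeneSet, GeneSetCollection

    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_number}: GMT line has fewer than 3 fields"
                )
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{line_number}: gene set {name!r} is empty")
            db = database
            if db is None:
                prefix = name.split("_", 1)[0].upper()
                db = prefix if prefix in {"KEGG", "REACTOME", "BIOCARTA"} else "other"
            if name in sets:
                raise ValueError(f"{path}:{line_number}: duplicate set name {name!r}")
            sets[name] = GeneSet(name=name, database=db, genes=genes)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# writers

SNP_FILE = "snp.tsv"
COUNT_FILE = "counts.tsv"
BURDEN_FILE = "burden.tsv"
QQ_FILE = "qq.tsv"


def write_outputs(
    snp_map: Mapping[str, Sequence[VariantKey]],
    counts: Iterable,
    results: Iterable,
    out_dir: str | os.PathLike,
    qq: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the SNP, count and burden files (plus optional QQ data).

    Row order is lexicographic by unit name everywhere so repeated runs are
    byte-identical and diffs are meaningful.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    snp_rows = [
        {"gene": gene, "variants": ",".join(str(k) for k in snp_map[gene])}
        for gene in sorted(snp_map)
    ]
    snp_frame = pd.DataFrame(snp_rows, columns=["gene", "variants"])

    count_rows = sorted(
        (
            {
                "gene": c.gene,
                "case_carriers": c.case_carriers,
                "case_alleles": c.case_alleles,
                "control_count": c.control_count,
                "n_cases": c.n_cases,
                "n_controls": c.n_controls,
            }
            for c in counts
        ),
        key=lambda r: r["gene"],
    )
    count_frame = pd.DataFrame(
        count_rows,
        columns=[
            "gene",
            "case_carriers",
            "case_alleles",
            "control_count",
            "n_cases",
            "n_controls",
        ],
    )

    burden_rows = sorted(
        (
            {
                "unit": r.unit,
                "database": r.database,
                "case_count": r.table[0],
                "case_noncarriers": r.table[1],
                "control_count": r.table[2],
                "control_noncarriers": r.table[3],
                "odds_ratio": r.odds_ratio,
                "p_raw": r.p_raw,
                "p_lambda": r.p_lambda,
                "p_final": r.p_final,
                "n_tests": r.n_tests,
                "contributing_genes": ",".join(r.contributing_genes),
                "warning": r.warning,
            }
            for r in results
        ),
        key=lambda r: r["unit"],
    )
    burden_frame = pd.DataFrame(
        burden_rows,
        columns=[
            "unit",
            "database",
            "case_count",
            "case_noncarriers",
            "control_count",
            "control_noncarriers",
            "odds_ratio",
            "p_raw",
            "p_lambda",
            "p_final",
            "n_tests",
            "contributing_genes",
            "warning",
        ],
    )

    paths = {
        "snp": out / SNP_FILE,
        "counts": out / COUNT_FILE,
        "burden": out / BURDEN_FILE,
    }
    snp_frame.to_csv(paths["snp"], sep="\t", index=False)
    count_frame.to_csv(paths["counts"], sep="\t", index=False)
    burden_frame.to_csv(paths["burden"], sep="\t", index=False)
    if qq is not None:
        paths["qq"] = out / QQ_FILE
        qq.to_csv(paths["qq"], sep="\t", index=False)
    return paths


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a count file back (round-trip companion to :func:`write_outputs`)."""
    return pd.read_csv(path, sep="\t")
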
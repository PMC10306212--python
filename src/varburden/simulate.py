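"""Synthetic cohort generator with known ground truth.

Emulates the study design the pipeline targets: a few dozen jointly-called
exome cases versus a public control cohort of tens of thousands known only
through per-variant allele-count summaries.  Case genotypes are drawn under
Hardy-Weinberg from each variant's true allele frequency; control allele
counts are drawn independently (the cohorts do not overlap).  Risk genes
raise the case-side allele frequency by an enrichment factor while controls
stay at the null, so spiked genes have a known expected excess of carriers.
Coverage dropout is placed in contiguous blocks to exercise the interval
logic of the joint gate, and a configurable share of variants is withheld
from every allele-frequency source (novel variants).

Ground truth is kept beside the outputs and is never read by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .io import CaseCohort, ControlSummary
from .pathways import GeneSet, GeneSetCollection
from .variants import HIGH_IMPACT_CONSEQUENCES, AnnotatedVariant, VariantKey

_BASES = np.array(list("ACGT"))
_GENE_SPAN = 5_000
_GENE_STRIDE = 10_000
_NONPASS_FILTER = "VQSRTrancheSNP99.90to100.00"
_NON_IMPACT = ("missense_variant", "synonymous_variant", "splice_region_variant")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the target design: 38 cases against 56,885 summary
    controls, a log-uniform rare allele-frequency spectrum on (1e-6, 0.01],
    and gene panels dense enough that burden tables are informative (about
    ten variants per gene of which ~40% are high-impact with CADD >= 20).
    ``risk_genes`` maps gene names to case-side enrichment factors (>= 1);
    ``risk_gene_sum_af`` optionally rescales a risk gene's qualifying allele
    frequencies to a fixed total so the spiked signal size is exact.
    """

    seed: int = 0
    n_cases: int = 38
    n_controls: int = 56_885
    n_genes: int = 400
    mean_variants_per_gene: float = 10.0
    af_range: tuple[float, float] = (1e-6, 0.01)
    qualifying_fraction: float = 0.4
    risk_genes: Mapping[str, float] = field(default_factory=dict)
    risk_gene_sum_af: float | None = None
    coverage_dropout: float = 0.05
    missing_af_fraction: float = 0.05
    filter_fail_fraction: float = 0.02
    control_label: str = "gnomad"
    n_gene_sets: int = 20

    def __post_init__(self) -> None:
        for name in (
            "qualifying_fraction",
            "coverage_dropout",
            "missing_af_fraction",
            "filter_fail_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_cases < 1 or self.n_controls < 1 or self.n_genes < 1:
            raise ValueError("cohort and panel sizes must be positive")
        if not 0.0 < self.af_range[0] <= self.af_range[1] <= 1.0:
            raise ValueError("af_range must satisfy 0 < low <= high <= 1")
        for gene, enrichment in self.risk_genes.items():
            if enrichment < 1.0:
                raise ValueError(f"enrichment for {gene} must be >= 1")


def gene_name(index: int) -> str:
    return f"G{index:04d}"


def _sample_case_dosages(
    rng: np.random.Generator, f: np.ndarray, n_cases: int, enrichment: float = 1.0
) -> np.ndarray:
    """Hardy-Weinberg dosages, with the allele frequency scaled by enrichment.

    At enrichment 1 this is exactly the null draw, so an enrichment-1 "risk"
    gene is byte-identical to a null gene under the same random stream.
    """
    f_case = enrichment * f
    if (f_case > 1.0).any():
        warnings.warn("enrichment pushes a case allele frequency past 1; capped")
        f_case = np.minimum(f_case, 1.0)
    return rng.binomial(2, np.broadcast_to(f_case[:, None], (f.size, n_cases))).astype(
        np.int8
    )


def _sample_control_counts(
    rng: np.random.Generator, f: np.ndarray, n_controls: int
) -> tuple[np.ndarray, np.ndarray]:
    """(ac, n_hom) per variant under Hardy-Weinberg genotype sampling."""
    n_hom = rng.binomial(n_controls, f**2)
    n_het = rng.binomial(n_controls - n_hom, 2 * f * (1 - f))
    return 2 * n_hom + n_het, n_hom


@dataclass
class SimBundle:
    """One synthetic analysis input set, in memory, plus its ground truth."""

    config: SimConfig
    cohort: CaseCohort
    annotations: list[AnnotatedVariant]
    control: ControlSummary
    case_coverage: CoverageProfile
    control_coverage: CoverageProfile
    gene_sets: GeneSetCollection
    truth: pd.DataFrame
    _vcf_rows: list[tuple] = field(default_factory=list, repr=False)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit every pipeline input format plus the ground-truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "case_vcf": out / "cases.vcf",
            "control_summary": out / "controls.tsv",
            "case_coverage": out / "case_coverage.tsv",
            "control_coverage": out / "control_coverage.tsv",
            "annotations": out / "annotations.tsv",
            "gene_sets": out / "gene_sets.gmt",
            "truth": out / "truth.tsv",
        }
        self._write_vcf(paths["case_vcf"])
        self._write_controls(paths["control_summary"])
        self.case_coverage.to_frame().to_csv(
            paths["case_coverage"], sep="\t", index=False, float_format="%.6g"
        )
        self.control_coverage.to_frame().to_csv(
            paths["control_coverage"], sep="\t", index=False, float_format="%.6g"
        )
        self._write_annotations(paths["annotations"])
        self._write_gmt(paths["gene_sets"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
        return paths

    def _write_vcf(self, path: Path) -> None:
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=300000000>",
            '##FILTER=<ID=PASS,Description="All filters passed">',
            f'##FILTER=<ID={_NONPASS_FILTER},Description="Failed quality recalibration">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.cohort.sample_ids),
        ]
        gt_text = {0: "0/0", 1: "0/1", 2: "1/1"}
        for chrom, pos, ref, alt, filt, dosages in self._vcf_rows:
            gts = "\t".join(gt_text[int(d)] for d in dosages)
            lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT\t{gts}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    def _write_controls(self, path: Path) -> None:
        rows = [
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "ac": ac,
                "an": an,
                "n_hom": n_hom,
                "filter": "PASS",
            }
            for key, (ac, an, n_hom) in sorted(self.control.records.items())
        ]
        pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "ac", "an", "n_hom", "filter"]
        ).to_csv(path, sep="\t", index=False)

    def _write_annotations(self, path: Path) -> None:
        af_sources = sorted({s for v in self.annotations for s in v.af_by_source})
        rows = []
        for v in sorted(self.annotations, key=lambda v: (v.key, v.gene)):
            row = {
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "gene": v.gene,
                "consequence": v.consequence,
                "cadd_phred": v.cadd_phred,
                "filter": v.filter_status,
            }
            for s in af_sources:
                row[s] = v.af_by_source.get(s, np.nan)
            rows.append(row)
        cols = ["chrom", "pos", "ref", "alt", "gene", "consequence", "cadd_phred", "filter"]
        pd.DataFrame(rows, columns=cols + af_sources).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    def _write_gmt(self, path: Path) -> None:
        lines = [
            "\t".join([name, self.gene_sets.sets[name].database]
                      + sorted(self.gene_sets.sets[name].genes))
            for name in sorted(self.gene_sets.sets)
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def simulate(cfg: SimConfig) -> SimBundle:
    """Generate a full synthetic input bundle (null or alternative).

    Identical configurations produce byte-identical outputs: a single seeded
    generator is consumed in a fixed order.
    """
    rng = np.random.default_rng(cfg.seed)
    unknown = set(cfg.risk_genes) - {gene_name(i) for i in range(cfg.n_genes)}
    if unknown:
        raise ValueError(f"risk genes absent from simulated panel: {sorted(unknown)}")

    cohort = CaseCohort(sample_ids=[f"case{i:03d}" for i in range(cfg.n_cases)])
    control = ControlSummary(n_controls=cfg.n_controls)
    annotations: list[AnnotatedVariant] = []
    truth_rows: list[dict] = []
    vcf_rows: list[tuple] = []
    case_cov_rows: list[tuple] = []
    control_cov_rows: list[tuple] = []
    af_source = f"af_{cfg.control_label}_nfe"

    for g in range(cfg.n_genes):
        gene = gene_name(g)
        enrichment = float(cfg.risk_genes.get(gene, 1.0))
        start0 = g * _GENE_STRIDE  # 0-based gene block start
        end0 = start0 + _GENE_SPAN

        # contiguous control-coverage dropout block in the middle of the gene
        dropped = rng.random() < cfg.coverage_dropout
        case_cov_rows.append(("chr1", start0, end0, 0.97))
        if dropped:
            q1, q3 = start0 + _GENE_SPAN // 4, start0 + 3 * _GENE_SPAN // 4
            control_cov_rows += [
                ("chr1", start0, q1, 0.97),
                ("chr1", q1, q3, 0.50),
                ("chr1", q3, end0, 0.97),
            ]
        else:
            control_cov_rows.append(("chr1", start0, end0, 0.97))

        n_var = max(1, int(rng.poisson(cfg.mean_variants_per_gene)))
        pos0 = rng.choice(_GENE_SPAN, size=n_var, replace=False)
        pos0.sort()
        f = np.exp(
            rng.uniform(np.log(cfg.af_range[0]), np.log(cfg.af_range[1]), n_var)
        )
        qualifying = rng.random(n_var) < cfg.qualifying_fraction
        if enrichment > 1.0 and cfg.risk_gene_sum_af is not None:
            total = f[qualifying].sum()
            if total > 0:
                f[qualifying] *= cfg.risk_gene_sum_af / total
        consequences = np.where(
            qualifying,
            rng.choice(sorted(HIGH_IMPACT_CONSEQUENCES), n_var),
            rng.choice(_NON_IMPACT, n_var),
        )
        cadd = np.where(
            qualifying, rng.uniform(20.0, 45.0, n_var), rng.uniform(0.0, 19.0, n_var)
        )
        missing_af = rng.random(n_var) < cfg.missing_af_fraction
        filter_fail = rng.random(n_var) < cfg.filter_fail_fraction

        dosages = _sample_case_dosages(rng, f, cfg.n_cases, enrichment)
        ac, n_hom = _sample_control_counts(rng, f, cfg.n_controls)

        ref_idx = rng.integers(0, 4, n_var)
        alt_shift = rng.integers(1, 4, n_var)

        for j in range(n_var):
            pos = start0 + int(pos0[j]) + 1  # 1-based
            ref = str(_BASES[ref_idx[j]])
            alt = str(_BASES[(ref_idx[j] + alt_shift[j]) % 4])
            key = VariantKey("chr1", pos, ref, alt)
            filt = _NONPASS_FILTER if filter_fail[j] else "PASS"
            vcf_rows.append(("chr1", pos, ref, alt, filt, dosages[j]))
            afs = {} if missing_af[j] else {af_source: float(f[j])}
            annotations.append(
                AnnotatedVariant(
                    key=key,
                    gene=gene,
                    consequence=str(consequences[j]),
                    cadd_phred=float(round(cadd[j], 2)),
                    af_by_source=afs,
                    filter_status=filt,
                )
            )
            if filt == "PASS":
                cohort.dosage[key] = dosages[j]
                control.add(key, int(ac[j]), 2 * cfg.n_controls, int(n_hom[j]))
            q1, q3 = _GENE_SPAN // 4, 3 * _GENE_SPAN // 4
            covered = not (dropped and q1 <= int(pos0[j]) < q3)
            truth_rows.append(
                {
                    "chrom": "chr1",
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "true_af": float(f[j]),
                    "consequence": str(consequences[j]),
                    "cadd_phred": float(round(cadd[j], 2)),
                    "qualifying": bool(qualifying[j]),
                    "enrichment": enrichment,
                    "filter": filt,
                    "covered": covered,
                    "missing_af": bool(missing_af[j]),
                }
            )

    sets: dict[str, GeneSet] = {}
    databases = ("KEGG", "REACTOME", "BIOCARTA")
    for s in range(cfg.n_gene_sets):
        genes = frozenset(
            gene_name(i) for i in range(s, cfg.n_genes, cfg.n_gene_sets)
        )
        if genes:
            name = f"SIMSET_{s:03d}"
            sets[name] = GeneSet(name=name, database=databases[s % 3], genes=genes)

    return SimBundle(
        config=cfg,
        cohort=cohort,
        annotations=annotations,
        control=control,
        case_coverage=CoverageProfile.from_frame(
            pd.DataFrame(case_cov_rows, columns=["chrom", "start", "end", "fraction"])
        ),
        control_coverage=CoverageProfile.from_frame(
            pd.DataFrame(control_cov_rows, columns=["chrom", "start", "end", "fraction"])
        ),
        gene_sets=GeneSetCollection(sets=sets),
        truth=pd.DataFrame(truth_rows),
        _vcf_rows=vcf_rows,
    )


def simulate_null(cfg: SimConfig) -> SimBundle:
    """Null bundle: no gene is enriched in cases."""
    if cfg.risk_genes:
        raise ValueError("null simulation requires an empty risk_genes map")
    return simulate(cfg)


def simulate_alternative(cfg: SimConfig) -> SimBundle:
    """Alternative bundle: the configured risk genes are enriched in cases."""
    if not cfg.risk_genes:
        raise ValueError("alternative simulation requires at least one risk gene")
    return simulate(cfg)


def simulate_pvalues(
    n: int, seed: int | np.random.Generator = 0, log10_scale: float = 1.0
) -> np.ndarray:
    """P-values under the exact null (uniform), optionally mean-shifted.

    ``log10_scale`` scales every -log10(p) by a constant factor, the
    stylized inflation scenario used to exercise the lambda estimator:
    the inflation factor of the output equals ``log10_scale`` exactly in
    expectation.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if log10_scale <= 0:
        raise ValueError("log10_scale must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    u = rng.uniform(size=n)
    return u**log10_scale


def expected_carrier_probability(f: np.ndarray) -> float:
    """Closed-form P(an individual carries >= 1 alternate allele) under HW."""
    return float(1.0 - np.prod((1.0 - np.asarray(f, dtype=float)) ** 2))


def null_config(**overrides) -> SimConfig:
    """Convenience constructor for a null-study configuration."""
    return replace(SimConfig(), **overrides)
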
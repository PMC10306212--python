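"""Gene-level collapsing burden test against summary-statistic controls.

Each gene contributes one 2x2 table: case carriers vs. non-carriers against a
control carrier count approximated by the summed alternate allele count
(capped at the cohort size — at frequencies of 1% or below, double-carrier
controls are negligible).  The test is a two-sided Fisher's exact test; the
two-sided p sums hypergeometric point probabilities no larger than that of
the observed table, with a small relative tie tolerance because symmetric
tables produce floating-point ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CaseCohort, ControlSummary
from .qualify import SnpMap
from .variants import VariantKey

#: relative tolerance for point-probability ties in the two-sided sum
TIE_REL_TOL = 1e-7


@dataclass(frozen=True)
class GeneCount:
    """Dominant-model qualifying-variant counts for one gene."""

    gene: str
    case_carriers: int
    case_alleles: int
    control_count: int
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not 0 <= self.case_carriers <= self.n_cases:
            raise ValueError(f"{self.gene}: carrier count outside [0, n_cases]")
        if not self.case_carriers <= self.case_alleles <= 2 * self.n_cases:
            raise ValueError(f"{self.gene}: allele count inconsistent with carriers")
        if not 0 <= self.control_count <= self.n_controls:
            raise ValueError(f"{self.gene}: control count outside [0, n_controls]")


@dataclass
class BurdenResult:
    """One tested unit (gene or pathway): 2x2 table, odds ratio, p-values."""

    unit: str
    table: tuple[int, int, int, int]  # (a, n_cases - a, c, n_controls - c)
    odds_ratio: float
    p_raw: float
    p_lambda: float = math.nan
    p_final: float = math.nan
    n_tests: int = 0
    database: str = ""
    contributing_genes: tuple[str, ...] = field(default_factory=tuple)
    warning: str = ""


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Descriptive (a*d)/(b*c); infinite or undefined (nan) on zero cells."""
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def _hypergeom_weights(n: int, row1: int, col1: int, lo: int, hi: int) -> np.ndarray:
    """Hypergeometric point masses over [lo, hi], scaled so the mode is 1.

    Built outward from the distribution's mode with the exact term ratio
    pmf(k+1)/pmf(k) = (row1-k)(col1-k) / ((k+1)(row2-col1+k+1)); every factor
    is an exact small-integer product, so each weight carries only a few ulp
    of rounding however large the margins are.  Far tails may underflow to
    zero, which is harmless at double precision.
    """
    row2 = n - row1
    mode = min(max(((row1 + 1) * (col1 + 1)) // (n + 2), lo), hi)
    weights = np.empty(hi - lo + 1)
    weights[mode - lo] = 1.0
    for k in range(mode, lo, -1):
        weights[k - 1 - lo] = (
            weights[k - lo] * (k * (row2 - col1 + k)) / ((row1 - k + 1) * (col1 - k + 1))
        )
    for k in range(mode, hi):
        weights[k + 1 - lo] = (
            weights[k - lo] * ((row1 - k) * (col1 - k)) / ((k + 1) * (row2 - col1 + k + 1))
        )
    return weights


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the 2x2 table [[a, b], [c, d]].

    Conditional on the margins, sums the hypergeometric probabilities of all
    tables whose point probability is at most that of the observed table
    (within ``TIE_REL_TOL`` relative, to absorb floating-point ties).
    """
    for name, value in (("a", a), ("b", b), ("c", c), ("d", d)):
        if value < 0 or value != int(value):
            raise ValueError(f"table entry {name}={value} must be a non-negative integer")
    if a + b < 1 or c + d < 1:
        raise ValueError("both table rows must have positive totals")
    total = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    weights = _hypergeom_weights(total, row1, col1, lo, hi)
    w_obs = weights[a - lo]
    numerator = math.fsum(weights[weights <= w_obs * (1.0 + TIE_REL_TOL)])
    p = numerator / math.fsum(weights)
    return min(1.0, p)


def count_case_dominant(
    cohort: CaseCohort, variants: list[VariantKey]
) -> tuple[int, int]:
    """(carriers, alleles): samples with total gene dosage >= 1, and dosage sum."""
    if not variants:
        return 0, 0
    total = np.zeros(cohort.n_cases, dtype=np.int64)
    for key in variants:
        dos = cohort.dosage.get(key)
        if dos is not None:
            total += dos
    return int((total >= 1).sum()), int(total.sum())


def count_control_dominant(ctrl: ControlSummary, variants: list[VariantKey]) -> int:
    """Summed control allele counts, capped at the cohort size.

    Summary statistics carry no per-individual genotypes, so the summed
    allele count stands in for the carrier count; variants absent from the
    summary contribute 0.
    """
    return min(sum(ctrl.ac(key) for key in variants), ctrl.n_controls)


def count_recessive(
    cohort: CaseCohort, ctrl: ControlSummary, variants: list[VariantKey]
) -> tuple[int, int]:
    """Recessive-model counts: cases need total gene dosage >= 2.

    The control side uses the summed homozygote count only; a compound-
    heterozygote proxy from pooled allele counts would need phase information
    the summaries do not carry, so it is not attempted.
    """
    if not variants:
        return 0, 0
    total = np.zeros(cohort.n_cases, dtype=np.int64)
    for key in variants:
        dos = cohort.dosage.get(key)
        if dos is not None:
            total += dos
    case_count = int((total >= 2).sum())
    control_count = min(sum(ctrl.n_hom(key) for key in variants), ctrl.n_controls)
    return case_count, control_count


def gene_counts(
    snp_map: SnpMap, cohort: CaseCohort, ctrl: ControlSummary
) -> dict[str, GeneCount]:
    """Dominant-model count table for every gene in the SNP map."""
    out: dict[str, GeneCount] = {}
    for gene, variants in snp_map.items():
        carriers, alleles = count_case_dominant(cohort, variants)
        out[gene] = GeneCount(
            gene=gene,
            case_carriers=carriers,
            case_alleles=alleles,
            control_count=count_control_dominant(ctrl, variants),
            n_cases=cohort.n_cases,
            n_controls=ctrl.n_controls,
        )
    return out


def gene_burden(
    snp_map: SnpMap,
    cohort: CaseCohort,
    ctrl: ControlSummary,
    min_case_count: int = 1,
    model: str = "dominant",
) -> list[BurdenResult]:
    """Per-gene burden tests (raw p-values only; corrections come later).

    ``min_case_count`` restricts the tested genes by case allele count: the
    "two or more variant counts" subset uses 2, which covers both a single
    homozygous case and two heterozygous carriers.  ``n_tests`` on every
    result is the number of genes actually tested in this arm.
    """
    if model not in ("dominant", "recessive"):
        raise ValueError("model must be 'dominant' or 'recessive'")
    results: list[BurdenResult] = []
    for gene in sorted(snp_map):
        variants = snp_map[gene]
        if model == "dominant":
            a, alleles = count_case_dominant(cohort, variants)
            c = count_control_dominant(ctrl, variants)
            if alleles < min_case_count:
                continue
        else:
            a, c = count_recessive(cohort, ctrl, variants)
            if a < min_case_count:
                continue
        b = cohort.n_cases - a
        d = ctrl.n_controls - c
        results.append(
            BurdenResult(
                unit=gene,
                table=(a, b, c, d),
                odds_ratio=odds_ratio(a, b, c, d),
                p_raw=fisher_two_sided(a, b, c, d),
                contributing_genes=(gene,),
            )
        )
    if not results:
        warnings.warn("no genes left to test after filtering", stacklevel=2)
    for result in results:
        result.n_tests = len(results)
    return results
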
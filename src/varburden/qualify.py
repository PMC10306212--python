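"""Qualifying-variant selection: the filters between raw calls and counting.

A variant qualifies for burden testing when it (1) lies on a base retained by
the joint coverage gate, (2) passed quality filtering, (3) is rare under the
analysis arm's allele-frequency threshold, and (4) is predicted deleterious:
CADD Phred at or above the cutoff combined with a high-impact (predicted
loss-of-function) consequence.  The gene -> variant SNP map keeps only
variants carried by at least one case, and only genes with at least one such
variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .intervals import GenomicIntervals
from .io import CaseCohort
from .variants import (
    CONSEQUENCE_VOCABULARY,
    HIGH_IMPACT_CONSEQUENCES,
    AnnotatedVariant,
    VariantKey,
)

#: gene -> qualifying variants with at least one case alternate allele
SnpMap = dict[str, list[VariantKey]]


@dataclass(frozen=True)
class QualifyConfig:
    """All thresholds of one analysis arm's qualifying-variant definition.

    ``af_source_order`` lists allele-frequency sources by precedence, the
    control-matched European frequency first and the aggregator (ALFA
    European) as fallback; a variant absent everywhere counts as frequency 0.
    ``combine_rule`` is 'and' (default: deleterious means CADD >= cutoff AND a
    high-impact consequence) or 'or'.
    """

    cadd_min: float = 20.0
    impact_terms: frozenset[str] = HIGH_IMPACT_CONSEQUENCES
    af_max: float = 0.01
    af_source_order: tuple[str, ...] = ("af_gnomad_nfe", "af_alfa_eur")
    combine_rule: str = "and"
    depth_min: int = 10
    coverage_frac_min: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.af_max <= 1.0:
            raise ValueError("af_max must lie in (0, 1]")
        if not 0.0 < self.coverage_frac_min <= 1.0:
            raise ValueError("coverage_frac_min must lie in (0, 1]")
        if not self.af_source_order:
            raise ValueError("af_source_order must be non-empty")
        if self.combine_rule not in ("and", "or"):
            raise ValueError("combine_rule must be 'and' or 'or'")

    def with_af_max(self, af_max: float) -> "QualifyConfig":
        return replace(self, af_max=af_max)


def effective_af(variant: AnnotatedVariant, cfg: QualifyConfig) -> float:
    """Allele frequency under the configured source precedence.

    The first source present in the variant's AF map wins; a variant absent
    from every source is novel and scores 0.
    """
    for source in cfg.af_source_order:
        if source in variant.af_by_source:
            return variant.af_by_source[source]
    return 0.0


def qualify(
    variant: AnnotatedVariant, cfg: QualifyConfig, retained: GenomicIntervals
) -> bool:
    """Pure predicate: does this variant qualify for burden counting?"""
    if not retained.contains(variant.key.chrom, variant.key.pos):
        return False
    if variant.filter_status != "PASS":
        return False
    if effective_af(variant, cfg) > cfg.af_max:
        return False
    if variant.consequence not in CONSEQUENCE_VOCABULARY:
        warnings.warn(
            f"unknown consequence {variant.consequence!r} for {variant.key}; "
            "treated as non-impact",
            stacklevel=2,
        )
    is_impact = variant.consequence in cfg.impact_terms
    is_deleterious = variant.cadd_phred >= cfg.cadd_min
    if cfg.combine_rule == "and":
        return is_deleterious and is_impact
    return is_deleterious or is_impact


def build_snp_map(
    cohort: CaseCohort,
    annotations: list[AnnotatedVariant],
    cfg: QualifyConfig,
    retained: GenomicIntervals,
) -> SnpMap:
    """Gene -> qualifying variants observed in at least one case.

    A variant annotated to several genes appears under each of them; genes
    whose qualifying variants have no case carriers are omitted entirely
    (only genes with case variants are tested).  Output lists are sorted and
    deduplicated, so the map is invariant to annotation input order.
    """
    snp_map: dict[str, set[VariantKey]] = {}
    for variant in annotations:
        dosages = cohort.dosage.get(variant.key)
        if dosages is None or int(dosages.sum()) == 0:
            continue
        if not qualify(variant, cfg, retained):
            continue
        snp_map.setdefault(variant.gene, set()).add(variant.key)
    return {gene: sorted(keys) for gene, keys in sorted(snp_map.items()) if keys}
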
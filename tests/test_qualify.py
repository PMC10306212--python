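import dataclasses

import numpy as np
import pytest

from varburden import (
    AnnotatedVariant,
    GenomicIntervals,
    QualifyConfig,
    VariantKey,
    build_snp_map,
    effective_af,
    joint_coverage_gate,
    qualify,
)
from varburden.io import CaseCohort

EVERYWHERE = GenomicIntervals.from_tuples([("chr1", 0, 10**9)])


def _variant(consequence="stop_gained", cadd=35.0, afs=None, filt="PASS", pos=1000):
    return AnnotatedVariant(
        key=VariantKey("chr1", pos, "A", "T"),
        gene="PEX7",
        consequence=consequence,
        cadd_phred=cadd,
        af_by_source=afs or {},
        filter_status=filt,
    )


class TestEffectiveAf:
    def test_single_source(self):
        cfg = QualifyConfig()
        assert effective_af(_variant(afs={"af_gnomad_nfe": 0.0007}), cfg) == 0.0007

    def test_absent_everywhere_is_novel(self):
        assert effective_af(_variant(afs={}), QualifyConfig()) == 0.0

    def test_source_precedence(self):
        cfg = QualifyConfig(af_source_order=("af_gnomad_nfe", "af_alfa_eur"))
        v = _variant(afs={"af_gnomad_nfe": 0.002, "af_alfa_eur": 0.0001})
        assert effective_af(v, cfg) == 0.002

    def test_fallback_source_used_when_primary_missing(self):
        cfg = QualifyConfig(af_source_order=("af_gnomad_nfe", "af_alfa_eur"))
        assert effective_af(_variant(afs={"af_alfa_eur": 0.0001}), cfg) == 0.0001


class TestQualify:
    def test_rare_lof_qualifies(self):
        cfg = QualifyConfig(af_max=0.001)
        v = _variant(afs={"af_gnomad_nfe": 0.0007})
        assert qualify(v, cfg, EVERYWHERE)

    def test_af_threshold_boundary_is_inclusive(self):
        v = _variant(afs={"af_gnomad_nfe": 0.01})
        assert qualify(v, QualifyConfig(af_max=0.01), EVERYWHERE)
        assert not qualify(v, QualifyConfig(af_max=0.001), EVERYWHERE)

    def test_high_cadd_missense_fails_under_and_rule(self):
        v = _variant(consequence="missense_variant", cadd=28.0)
        assert not qualify(v, QualifyConfig(), EVERYWHERE)
        assert qualify(v, QualifyConfig(combine_rule="or"), EVERYWHERE)

    def test_low_cadd_lof_fails_under_and_rule(self):
        assert not qualify(_variant(cadd=12.0), QualifyConfig(), EVERYWHERE)

    def test_uncovered_position_never_qualifies(self):
        gate = GenomicIntervals.from_tuples([("chr1", 0, 100)])
        assert not qualify(_variant(pos=1000), QualifyConfig(), gate)

    def test_non_pass_variant_never_qualifies(self):
        assert not qualify(_variant(filt="RF"), QualifyConfig(), EVERYWHERE)

    def test_unknown_consequence_warns_and_is_non_impact(self):
        with pytest.warns(UserWarning, match="unknown consequence"):
            v = _variant(consequence="regulatory_mystery")
        with pytest.warns(UserWarning):
            assert not qualify(v, QualifyConfig(), EVERYWHERE)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            QualifyConfig(af_max=0.0)
        with pytest.raises(ValueError):
            QualifyConfig(af_source_order=())
        with pytest.raises(ValueError):
            QualifyConfig(combine_rule="xor")


class TestBuildSnpMap:
    def _cohort(self, dosages):
        cohort = CaseCohort(sample_ids=["s1", "s2"])
        for key, d in dosages.items():
            cohort.dosage[key] = np.array(d, dtype=np.int8)
        return cohort

    def test_carrier_gene_included_noncarrier_gene_omitted(self):
        k1, k2 = VariantKey("chr1", 10, "A", "T"), VariantKey("chr1", 20, "G", "C")
        cohort = self._cohort({k1: [1, 0], k2: [0, 0]})
        annos = [
            AnnotatedVariant(k1, "GENEA", "stop_gained", 30.0),
            AnnotatedVariant(k2, "GENEB", "stop_gained", 30.0),
        ]
        snp_map = build_snp_map(cohort, annos, QualifyConfig(), EVERYWHERE)
        assert snp_map == {"GENEA": [k1]}

    def test_variant_annotated_to_two_genes_appears_under_both(self):
        k = VariantKey("chr1", 10, "A", "T")
        cohort = self._cohort({k: [0, 1]})
        annos = [
            AnnotatedVariant(k, "GENEA", "stop_gained", 30.0),
            AnnotatedVariant(k, "GENEB", "frameshift_variant", 30.0),
        ]
        snp_map = build_snp_map(cohort, annos, QualifyConfig(), EVERYWHERE)
        assert set(snp_map) == {"GENEA", "GENEB"}

    def test_map_invariant_to_annotation_order(self, small_bundle, base_qualify_config):
        gate = joint_coverage_gate(
            small_bundle.case_coverage, small_bundle.control_coverage
        )
        forward = build_snp_map(
            small_bundle.cohort, small_bundle.annotations, base_qualify_config, gate
        )
        backward = build_snp_map(
            small_bundle.cohort,
            list(reversed(small_bundle.annotations)),
            base_qualify_config,
            gate,
        )
        assert forward == backward


class TestFilterMonotonicity:
    def test_tighter_af_threshold_shrinks_the_map(self, small_bundle):
        gate = joint_coverage_gate(
            small_bundle.case_coverage, small_bundle.control_coverage
        )
        loose = build_snp_map(
            small_bundle.cohort,
            small_bundle.annotations,
            QualifyConfig(af_max=0.01),
            gate,
        )
        tight = build_snp_map(
            small_bundle.cohort,
            small_bundle.annotations,
            QualifyConfig(af_max=0.001),
            gate,
        )
        for gene, keys in tight.items():
            assert set(keys) <= set(loose.get(gene, []))

    def test_tighter_coverage_gate_never_adds_variants(self, small_bundle):
        maps = {}
        for frac in (0.99, 0.90, 0.40):
            cfg = dataclasses.replace(QualifyConfig(), coverage_frac_min=frac)
            gate = joint_coverage_gate(
                small_bundle.case_coverage, small_bundle.control_coverage, frac
            )
            maps[frac] = build_snp_map(
                small_bundle.cohort, small_bundle.annotations, cfg, gate
            )
        for tight, loose in [(0.99, 0.90), (0.90, 0.40)]:
            for gene, keys in maps[tight].items():
                assert set(keys) <= set(maps[loose].get(gene, []))
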
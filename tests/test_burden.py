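import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from varburden import (
    ControlSummary,
    VariantKey,
    count_case_dominant,
    count_control_dominant,
    count_recessive,
    fisher_two_sided,
    gene_burden,
    odds_ratio,
)
from varburden.io import CaseCohort

from ._oracles import two_sided_exact, two_sided_exact_all


def _cohort(dosage_rows):
    """dosage_rows: mapping key -> per-sample dosages."""
    n = len(next(iter(dosage_rows.values())))
    cohort = CaseCohort(sample_ids=[f"s{i}" for i in range(n)])
    for key, d in dosage_rows.items():
        cohort.dosage[key] = np.array(d, dtype=np.int8)
    return cohort


K1 = VariantKey("chr1", 100, "A", "T")
K2 = VariantKey("chr1", 200, "G", "C")


class TestFisherTwoSided:
    def test_degenerate_empty_column_gives_one(self):
        assert fisher_two_sided(0, 38, 0, 56_885) == 1.0

    def test_all_tables_tied_gives_one(self):
        # margins (10,10) x (5,15): every point probability is at most the
        # observed one, so the two-sided sum is the whole distribution
        assert fisher_two_sided(3, 7, 2, 8) == pytest.approx(1.0, abs=1e-12)

    def test_matches_exact_enumeration_on_sparse_case_control_table(self):
        assert fisher_two_sided(2, 36, 15, 56_870) == pytest.approx(
            two_sided_exact(2, 36, 15, 56_870), rel=1e-12
        )

    def test_exhaustive_small_tables_match_exact_oracle(self):
        """Every 2x2 table with total <= 25 agrees with rational enumeration."""
        for n in range(2, 26):
            for r1 in range(1, n):
                for c1 in range(0, n + 1):
                    oracle = two_sided_exact_all(n, r1, c1)
                    for a, expected in oracle.items():
                        b, c = r1 - a, c1 - a
                        d = n - r1 - c
                        got = fisher_two_sided(a, b, c, d)
                        assert got == pytest.approx(expected, rel=1e-12), (a, b, c, d)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a = int(rng.integers(0, 10))
            b = int(rng.integers(1, 60))
            c = int(rng.integers(0, 3000))
            d = int(rng.integers(1, 80_000))
            ours = fisher_two_sided(a, b, c, d)
            theirs = fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-300)

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(max_examples=150, deadline=None)
    def test_group_label_symmetry(self, a, b, c, d):
        if a + b < 1 or c + d < 1:
            return
        assert fisher_two_sided(a, b, c, d) == pytest.approx(
            fisher_two_sided(c, d, a, b), rel=1e-12
        )

    def test_p_decreases_with_enrichment_above_expectation(self):
        """With margins fixed, more case carriers above the expected count
        means a smaller two-sided p."""
        n_cases, n_controls, col1 = 38, 5_000, 40
        expectation = n_cases * col1 / (n_cases + n_controls)
        previous = None
        for a in range(math.ceil(expectation) + 1, min(n_cases, col1) + 1):
            p = fisher_two_sided(a, n_cases - a, col1 - a, n_controls - col1 + a)
            if previous is not None:
                assert p < previous
            previous = p

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 2, 3, 4)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(0, 0, 3, 4)


class TestOddsRatio:
    def test_plain_ratio(self):
        assert odds_ratio(2, 36, 15, 56_870) == pytest.approx((2 * 56_870) / (36 * 15))

    def test_zero_cells(self):
        assert odds_ratio(1, 37, 0, 100) == math.inf
        assert math.isnan(odds_ratio(0, 38, 0, 100))


class TestCounting:
    def test_two_carriers_of_different_variants(self):
        cohort = _cohort({K1: [1, 0, 0], K2: [0, 1, 0]})
        assert count_case_dominant(cohort, [K1, K2]) == (2, 2)

    def test_individual_with_two_variants_counted_once(self):
        cohort = _cohort({K1: [1, 0], K2: [1, 0]})
        assert count_case_dominant(cohort, [K1, K2]) == (1, 2)

    def test_no_alt_dosages(self):
        cohort = _cohort({K1: [0, 0]})
        assert count_case_dominant(cohort, [K1]) == (0, 0)

    def test_control_sum_and_cap(self):
        ctrl = ControlSummary(n_controls=56_885)
        ctrl.add(K1, 317, 113_770, 0)
        ctrl.add(K2, 67, 113_770, 0)
        assert count_control_dominant(ctrl, [K1, K2]) == 384
        small = ControlSummary(n_controls=100)
        small.add(K1, 150, 200, 50)
        assert count_control_dominant(small, [K1]) == 100

    def test_absent_control_variant_contributes_zero(self):
        ctrl = ControlSummary(n_controls=56_885)
        assert count_control_dominant(ctrl, [K1]) == 0

    def test_recessive_counts_homozygote_and_compound_het(self):
        ctrl = ControlSummary(n_controls=1000)
        ctrl.add(K1, 10, 2000, 0)
        hom = _cohort({K1: [2, 0]})
        assert count_recessive(hom, ctrl, [K1]) == (1, 0)
        compound = _cohort({K1: [1, 0], K2: [1, 0]})
        assert count_recessive(compound, ctrl, [K1, K2]) == (1, 0)


class TestGeneBurden:
    def _inputs(self):
        cohort = _cohort({K1: [1, 0, 0, 0], K2: [0, 1, 0, 0]})
        ctrl = ControlSummary(n_controls=56_885)
        ctrl.add(K1, 10, 113_770, 0)
        ctrl.add(K2, 5, 113_770, 0)
        snp_map = {"GENEA": [K1], "GENEB": [K2]}
        return snp_map, cohort, ctrl

    def test_every_result_carries_the_arm_test_count(self):
        snp_map, cohort, ctrl = self._inputs()
        results = gene_burden(snp_map, cohort, ctrl)
        assert [r.n_tests for r in results] == [2, 2]

    def test_min_case_count_two_uses_allele_counts(self):
        snp_map, cohort, ctrl = self._inputs()
        assert gene_burden(snp_map, cohort, ctrl, min_case_count=2) == []
        cohort.dosage[K1][1] = 1  # second carrier in GENEA
        kept = gene_burden(snp_map, cohort, ctrl, min_case_count=2)
        assert [r.unit for r in kept] == ["GENEA"]

    def test_excluding_a_gene_leaves_other_p_values_unchanged(self):
        snp_map, cohort, ctrl = self._inputs()
        full = {r.unit: r.p_raw for r in gene_burden(snp_map, cohort, ctrl)}
        only_a = gene_burden({"GENEA": [K1]}, cohort, ctrl)
        assert only_a[0].p_raw == full["GENEA"]

    def test_empty_map_warns(self):
        _, cohort, ctrl = self._inputs()
        with pytest.warns(UserWarning, match="no genes"):
            assert gene_burden({}, cohort, ctrl) == []
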
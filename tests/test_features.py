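"""Region feature statistics: exact tails, enrichments, indicator, table."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ashmscan._stats import binom_upper_tail, cap_at_half
from ashmscan.annotations import SHMTarget, region_sequence_stats
from ashmscan.features import (
    RegionMutationProfile,
    benjamini_adjust,
    build_feature_table,
    cg_at_enrichment,
    count_region_mutations,
    motif_enrichment,
    mutation_density,
    region_burden_test,
    shm_indicator,
    titv_stats,
)
from ashmscan.somatic import SomaticSNV


def brute_binom_tail(k, n, p):
    """Independent oracle: full enumeration of the binomial upper tail."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(max(k, 0), n + 1))


def _snv(pos, sample="S1", ref="C", alt="T"):
    subst = "transition" if (ref, alt) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")} else "transversion"
    site = "CG_site" if ref in "CG" else "AT_site"
    return SomaticSNV(sample, "chr1", pos, ref, alt, 40.0, 0.5, subst, site)


def _profile(**kw):
    base = dict(gene_symbol="G", n_snvs_total=0, n_samples_mutated=0, n_transitions=0,
                n_transversions=0, n_at_cg_sites=0, n_at_at_sites=0, n_in_motif=0,
                per_sample_counts={})
    base.update(kw)
    return RegionMutationProfile(**base)


def _stats(seq):
    target = SHMTarget("G", "chr1", "+", 0, len(seq), len(seq))
    return target, region_sequence_stats(target, {"chr1": seq})


class TestCounting:
    def test_counts_and_spill(self):
        seq = "TACT" + "G" * 96  # motif covers first four bases
        target, stats = _stats(seq)
        snvs = [_snv(1, "S1"), _snv(50, "S1", ref="G", alt="C"), _snv(60, "S2", ref="A", alt="G"),
                _snv(200, "S3")]  # outside the window
        profile, spilled = count_region_mutations(target, stats, snvs)
        assert profile.n_snvs_total == 3 and profile.n_samples_mutated == 2
        assert profile.n_in_motif == 1
        assert profile.n_transitions == 2 and profile.n_transversions == 1
        assert profile.n_at_cg_sites == 2 and profile.n_at_at_sites == 1
        assert [s.pos for s in spilled] == [200]

    def test_empty_input_gives_zero_profile(self):
        target, stats = _stats("ACGT" * 10)
        profile, spilled = count_region_mutations(target, stats, [])
        assert profile.n_snvs_total == 0 and spilled == []


class TestDensity:
    def test_mean_over_all_cohort_samples(self):
        profile = _profile(per_sample_counts={"s1": 5, "s2": 0})
        assert mutation_density(profile, 2000, 2) == pytest.approx(1.25e-3)

    def test_zero_count_samples_dilute_the_mean(self):
        profile = _profile(per_sample_counts={"s1": 4})
        assert mutation_density(profile, 2000, 40) == pytest.approx(5e-5)

    def test_all_zero(self):
        assert mutation_density(_profile(), 2000, 10) == 0.0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            mutation_density(_profile(), 0, 10)


class TestEnrichmentTests:
    def test_motif_enrichment_against_enumerated_tail(self):
        # frac_motif = 0.2: TACT covered in a 20-base window
        target, stats = _stats("TACT" + "G" * 16)
        assert stats.frac_motif == pytest.approx(0.2)
        profile = _profile(n_snvs_total=10, n_in_motif=6)
        enr, p = motif_enrichment(profile, stats, cap=False)
        assert enr == pytest.approx(3.0)
        assert p == pytest.approx(brute_binom_tail(6, 10, 0.2), abs=1e-12)

    def test_no_snvs_is_missing_with_p_one(self):
        _, stats = _stats("TACT" + "G" * 16)
        enr, p = motif_enrichment(_profile(), stats)
        assert math.isnan(enr) and p == 1.0

    def test_cg_enrichment_matches_composition_expectation(self):
        # frac_cg = 0.4
        target, stats = _stats("CCGG" + "AT" * 3)
        profile = _profile(n_snvs_total=10, n_at_cg_sites=4)
        enr, _ = cg_at_enrichment(profile, stats)
        assert enr == pytest.approx(1.0)
        enr8, p8 = cg_at_enrichment(_profile(n_snvs_total=10, n_at_cg_sites=8), stats, cap=False)
        assert enr8 == pytest.approx(2.0)
        assert p8 == pytest.approx(brute_binom_tail(8, 10, 0.4), abs=1e-12)

    def test_titv_ratio_and_exact_tail(self):
        ratio, _ = titv_stats(_profile(n_snvs_total=15, n_transitions=5, n_transversions=10))
        assert ratio == pytest.approx(0.5)
        _, p = titv_stats(_profile(n_snvs_total=13, n_transitions=11, n_transversions=2), cap=False)
        assert p == pytest.approx(brute_binom_tail(11, 13, 1 / 3), abs=1e-12)

    def test_titv_degenerate_counts(self):
        ratio, p = titv_stats(_profile())
        assert math.isnan(ratio) and p == 1.0
        ratio, _ = titv_stats(_profile(n_snvs_total=3, n_transitions=3, n_transversions=0))
        assert math.isinf(ratio)

    def test_reported_p_capped_at_half(self):
        # depleted region: raw upper-tail p near 1 prints as 0.5
        _, stats = _stats("CCGG" + "AT" * 3)
        _, p = cg_at_enrichment(_profile(n_snvs_total=10, n_at_cg_sites=0), stats, cap=True)
        assert p == 0.5


class TestBurden:
    def test_matches_enumeration(self):
        profile = _profile(n_snvs_total=10)
        p = region_burden_test(profile, 100, 1_000_000, 2000)
        assert p == pytest.approx(brute_binom_tail(10, 100, 0.002), abs=1e-12)

    def test_empty_region_and_whole_genome_window(self):
        assert region_burden_test(_profile(), 100, 1_000_000, 2000) == 1.0
        assert region_burden_test(_profile(n_snvs_total=7), 50, 2000, 2000) == 1.0

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            region_burden_test(_profile(n_snvs_total=10), 5, 1_000_000, 2000)


class TestBenjamini:
    def test_hand_applied_step_up(self):
        assert benjamini_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_tied_inputs_unchanged(self):
        assert benjamini_adjust([0.2]) == [0.2]
        assert benjamini_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_order_preserving(self):
        p = [0.04, 0.001, 0.3, 0.02]
        q = benjamini_adjust(p)
        assert all(q[i] <= q[j] for i in range(4) for j in range(4) if p[i] <= p[j])


class TestIndicator:
    def test_all_half_inputs(self):
        assert shm_indicator(0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_identity_at_one(self):
        assert shm_indicator(1, 1, 1) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=3, max_size=3))
    def test_symmetric_under_permutation(self, ps):
        a, b, c = ps
        reference = shm_indicator(a, b, c)
        for perm in [(a, c, b), (b, a, c), (c, b, a)]:
            assert shm_indicator(*perm) == pytest.approx(reference, rel=1e-12)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            shm_indicator(0.0, 0.5, 0.5)


class TestFeatureTable:
    def _inputs(self):
        seq = ("TACT" + "G" * 16) * 5  # 100 bp windows
        genome = {"chr1": seq * 3}
        targets = [
            SHMTarget("GENEA", "chr1", "+", 0, 100, 100),
            SHMTarget("GENEB", "chr1", "+", 100, 200, 100),
            SHMTarget("GENEC", "chr1", "+", 200, 300, 100),
        ]
        stats = {t.gene_symbol: region_sequence_stats(t, genome) for t in targets}
        snvs = (
            [_snv(5, "S1"), _snv(10, "S2"), _snv(15, "S1"), _snv(20, "S3"), _snv(25, "S1")]
            + [_snv(105, "S1"), _snv(110, "S2"), _snv(115, "S3")]
        )
        return targets, stats, snvs

    def test_sorted_by_count_then_gene_and_zero_rows_absent(self):
        targets, stats, snvs = self._inputs()
        table = build_feature_table(targets, stats, snvs, n_samples=4, genome_bp=300)
        assert list(table["gene"]) == ["GENEA", "GENEB"]  # GENEC has no SNVs
        assert list(table["total_snvs"]) == [5, 3]

    def test_tied_counts_break_lexicographically(self):
        targets, stats, snvs = self._inputs()
        extra = [_snv(205, "S4"), _snv(210, "S4"), _snv(215, "S2")]
        table = build_feature_table(targets, stats, snvs[:3] + extra, n_samples=4, genome_bp=300)
        assert list(table["gene"]) == ["GENEA", "GENEC"]
        assert list(table["total_snvs"]) == [3, 3]

    def test_indicator_consistent_with_columns(self):
        targets, stats, snvs = self._inputs()
        table = build_feature_table(targets, stats, snvs, n_samples=4, genome_bp=300)
        for row in table.itertuples(index=False):
            assert row.shm_indicator == pytest.approx(
                (row.motif_p * row.cg_at_p * row.titv_p) ** (1 / 3)
            )

    def test_burden_q_is_bh_adjusted_over_all_regions(self):
        targets, stats, snvs = self._inputs()
        table = build_feature_table(targets, stats, snvs, n_samples=4, genome_bp=300)
        assert ((table["burden_q"] >= table["burden_p"] - 1e-15) | table["burden_q"].isna()).all()
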
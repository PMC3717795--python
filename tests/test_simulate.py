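"""Synthetic-cohort generator: determinism, realized statistics, round trips."""

import numpy as np
import pytest

from ashmscan.expression import read_expression_tsv
from ashmscan.annotations import load_gene_models
from ashmscan.rearrangements import read_rearrangements
from ashmscan.simulate import (
    SyntheticCohortConfig,
    generate,
    generate_reference,
    simulate_cohort,
    simulate_expression,
    simulate_rearrangements,
    write_cohort,
)
from ashmscan.somatic import read_site_set, read_vcf_calls

SMALL = SyntheticCohortConfig(seed=0, n_samples=6, n_genes=30, genes_per_contig=10)


class TestReference:
    def test_deterministic_under_seed(self):
        a = generate_reference(SMALL)
        b = generate_reference(SMALL)
        assert a.sequences == b.sequences
        assert a.models == b.models
        c = generate_reference(SyntheticCohortConfig(seed=1, n_samples=6, n_genes=30, genes_per_contig=10))
        assert c.sequences != a.sequences

    def test_gc_content_within_binomial_bound(self):
        ref = generate_reference(SyntheticCohortConfig(seed=0, n_genes=20, gc_content=0.5))
        seq = "".join(ref.sequences.values())
        n = len(seq)
        gc = sum(seq.count(b) for b in "GC") / n
        assert abs(gc - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_gene_layout(self):
        ref = generate_reference(SMALL)
        assert len(ref.models) == 30
        strands = {m.strand for m in ref.models}
        assert strands == {"+", "-"}
        # genes non-overlapping per contig
        by_chrom = {}
        for gene, (chrom, start, end, _s) in ref.tx_bounds.items():
            by_chrom.setdefault(chrom, []).append((start, end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))


class TestCohortProcess:
    def test_deterministic_under_seed(self):
        ref = generate_reference(SMALL)
        expr = simulate_expression(SMALL, [m.gene_symbol for m in ref.models])
        t1, n1, p1, truth1 = simulate_cohort(SMALL, ref, expr)
        t2, n2, p2, truth2 = simulate_cohort(SMALL, ref, expr)
        assert t1 == t2 and n1 == n2 and p1 == p2
        assert truth1["ashm_genes"] == truth2["ashm_genes"]

    def test_background_total_within_poisson_bound(self):
        config = SyntheticCohortConfig(
            seed=3, n_samples=20, n_genes=40, frac_ashm_genes=0.0,
            germline_rate=0.0, population_site_rate=0.0, artifact_rate=0.0,
            rearrangement_rate=0.0,
        )
        cohort = generate(config)
        total = sum(len(v) for v in cohort.tumor_calls.values())
        lam = cohort.reference.genome_bp * config.background_rate * config.n_samples
        assert abs(total - lam) <= 4 * np.sqrt(lam)

    def test_ashm_genes_concentrate_mutations(self):
        cohort = generate(SyntheticCohortConfig(seed=0, n_samples=10, n_genes=40, genes_per_contig=20))
        truth = cohort.truth
        ashm = set(truth["ashm_genes"])
        dens = truth["realized_density"]
        mean_ashm = np.mean([dens[g] for g in ashm])
        mean_bg = np.mean([dens[g] for g in dens if g not in ashm])
        assert mean_ashm > 10 * max(mean_bg, 1e-9)

    def test_constant_expression_equals_no_coupling(self):
        import pandas as pd
        from ashmscan.expression import ExpressionTable

        config = SyntheticCohortConfig(seed=4, n_samples=5, n_genes=20, genes_per_contig=10)
        ref = generate_reference(config)
        genes = [m.gene_symbol for m in ref.models]
        flat = ExpressionTable(pd.DataFrame(7.0, index=config.sample_ids, columns=genes))
        with_flat = simulate_cohort(config, ref, flat)
        without = simulate_cohort(config, ref, None)
        assert with_flat[0] == without[0]


class TestRearrangements:
    def test_rate_zero_gives_no_events(self):
        config = SyntheticCohortConfig(seed=0, n_samples=5, n_genes=20, genes_per_contig=10,
                                       rearrangement_rate=0.0)
        cohort = generate(config)
        assert cohort.rearrangements == []

    def test_full_preference_places_breakpoints_at_ashm_windows(self):
        config = SyntheticCohortConfig(seed=1, n_samples=10, n_genes=40, genes_per_contig=20,
                                       rearrangement_rate=2.0, rearrangement_ashm_preference=1.0)
        cohort = generate(config)
        assert cohort.rearrangements
        windows = {t.gene_symbol: t for t in cohort.targets if t.gene_symbol in set(cohort.truth["ashm_genes"])}
        for event in cohort.rearrangements:
            assert any(
                t.chrom == event.chrom_a and t.start <= event.pos_a < t.end for t in windows.values()
            )


class TestRoundTrip:
    def test_written_cohort_reads_back_losslessly(self, tmp_path):
        cohort = generate(SMALL)
        write_cohort(cohort, tmp_path)

        import pyfaidx

        fasta = pyfaidx.Fasta(str(tmp_path / "reference.fa"))
        for chrom, seq in cohort.reference.sequences.items():
            assert str(fasta[chrom][:]) == seq

        models = load_gene_models(tmp_path / "genes.bed")
        assert {(m.gene_symbol, m.chrom, m.strand, m.tss) for m in models} == {
            (m.gene_symbol, m.chrom, m.strand, m.tss) for m in cohort.reference.models
        }

        sample = SMALL.sample_ids[0]
        calls = read_vcf_calls(tmp_path / "vcf" / f"{sample}.vcf", sample)
        original = cohort.tumor_calls[sample]
        assert [(c.chrom, c.pos, c.ref, c.alt) for c in calls] == [
            (c.chrom, c.pos, c.ref, c.alt) for c in original
        ]
        assert calls[0].alt_fraction_highqual == pytest.approx(
            original[0].alt_fraction_highqual, abs=1e-4
        )

        normal = read_site_set(tmp_path / "vcf" / f"{sample}.normal.tsv")
        assert normal == cohort.matched_normal[sample]
        population = read_site_set(tmp_path / "population_sites.tsv")
        assert population == cohort.population

        expr = read_expression_tsv(tmp_path / "expression.tsv")
        assert np.allclose(
            expr.rpkm.loc[cohort.expression.samples, cohort.expression.genes].values,
            cohort.expression.rpkm.values,
        )

        events = read_rearrangements(tmp_path / "rearrangements.tsv")
        assert events == cohort.rearrangements
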
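"""Gene-model reading, window derivation, and motif/composition scanning."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ashmscan.annotations import (
    SHMTarget,
    TranscriptModel,
    derive_shm_targets,
    load_gene_models,
    region_sequence_stats,
    scan_motif_mask,
    write_targets_bed,
)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_mask(seq: str) -> np.ndarray:
    """Independent oracle: enumerate every 4-mer against both templates."""
    W, R, Y = set("AT"), set("AG"), set("CT")
    seq = seq.upper()
    covered = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - 3):
        a, b, c, d = seq[i : i + 4]
        wrcy = a in W and b in R and c == "C" and d in Y
        rgyw = a in R and b == "G" and c in Y and d in W
        if wrcy or rgyw:
            covered[i : i + 4] = True
    return covered


class TestGeneModelReaders:
    def _write(self, tmp_path, name, text):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_bed_plus_strand_tss_is_leftmost(self, tmp_path):
        path = self._write(tmp_path, "g.bed", "chr1\t1000\t5000\tGENEA\t0\t+\n")
        (model,) = load_gene_models(path)
        assert model == TranscriptModel("GENEA", "GENEA", "chr1", "+", 1000)

    def test_bed_minus_strand_tss_is_rightmost(self, tmp_path):
        path = self._write(tmp_path, "g.bed", "chr1\t1000\t5000\tGENEB\t0\t-\n")
        (model,) = load_gene_models(path)
        assert model.tss == 5000 and model.strand == "-"

    def test_gtf_and_flat_table_agree_with_bed(self, tmp_path):
        bed = self._write(tmp_path, "g.bed", "chr1\t1000\t5000\tGENEA\t0\t+\nchr1\t1000\t5000\tGENEB\t0\t-\n")
        gtf = self._write(
            tmp_path, "g.gtf",
            'chr1\tsrc\ttranscript\t1001\t5000\t.\t+\t.\tgene_name "GENEA"; transcript_id "GENEA";\n'
            'chr1\tsrc\ttranscript\t1001\t5000\t.\t-\t.\tgene_name "GENEB"; transcript_id "GENEB";\n',
        )
        flat = self._write(
            tmp_path, "g.txt",
            "name\tchrom\tstrand\ttxStart\ttxEnd\tgeneSymbol\n"
            "GENEA\tchr1\t+\t1000\t5000\tGENEA\nGENEB\tchr1\t-\t1000\t5000\tGENEB\n",
        )
        expected = {(m.gene_symbol, m.chrom, m.strand, m.tss) for m in load_gene_models(bed)}
        for path in (gtf, flat):
            got = {(m.gene_symbol, m.chrom, m.strand, m.tss) for m in load_gene_models(path)}
            assert got == expected

    def test_malformed_bed_names_problem(self, tmp_path):
        path = self._write(tmp_path, "bad.bed", "chr1\t100\t200\tG\t0\n")
        with pytest.raises(ValueError, match="strand"):
            load_gene_models(path)


class TestDeriveTargets:
    def test_forward_and_reverse_windows(self):
        targets = derive_shm_targets(
            [
                TranscriptModel("A", "A.1", "chr1", "+", 1000),
                TranscriptModel("B", "B.1", "chr1", "-", 5000),
            ],
            window_bp=2000,
        )
        by_gene = {t.gene_symbol: t for t in targets}
        assert (by_gene["A"].start, by_gene["A"].end) == (1000, 3000)
        assert (by_gene["B"].start, by_gene["B"].end) == (3000, 5000)

    def test_per_gene_collapse_uses_most_upstream_tss(self):
        models = [
            TranscriptModel("A", "A.2", "chr1", "+", 1200),
            TranscriptModel("A", "A.1", "chr1", "+", 1000),
        ]
        (target,) = derive_shm_targets(models, window_bp=2000, collapse="per_gene")
        assert (target.start, target.end) == (1000, 3000)
        # for '-' genes, upstream means the largest coordinate
        models = [
            TranscriptModel("B", "B.1", "chr1", "-", 4000),
            TranscriptModel("B", "B.2", "chr1", "-", 5000),
        ]
        (target,) = derive_shm_targets(models, window_bp=2000)
        assert (target.start, target.end) == (3000, 5000)

    def test_conflicting_strands_warn_and_skip(self):
        models = [
            TranscriptModel("A", "A.1", "chr1", "+", 1000),
            TranscriptModel("A", "A.2", "chr1", "-", 5000),
        ]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert derive_shm_targets(models) == []
        assert any("conflicting strands" in str(w.message) for w in caught)

    def test_truncation_flagged_at_contig_edges(self):
        models = [
            TranscriptModel("A", "A.1", "chr1", "-", 500),
            TranscriptModel("B", "B.1", "chr1", "+", 9500),
        ]
        targets = derive_shm_targets(models, 2000, contig_lengths={"chr1": 10_000})
        by_gene = {t.gene_symbol: t for t in targets}
        assert by_gene["A"].truncated and by_gene["A"].start == 0
        assert by_gene["B"].truncated and by_gene["B"].end == 10_000

    def test_per_transcript_length_conservation(self):
        models = [TranscriptModel(f"G{i}", f"G{i}.1", "chr1", "+", 10_000 + 100 * i) for i in range(7)]
        targets = derive_shm_targets(models, window_bp=1500, collapse="per_transcript")
        assert sum(t.length for t in targets) == 7 * 1500

    def test_bed6_round_trip(self, tmp_path):
        models = [TranscriptModel("A", "A.1", "chr1", "+", 1000)]
        targets = derive_shm_targets(models, 2000)
        path = tmp_path / "targets.bed"
        write_targets_bed(targets, path)
        assert path.read_text() == "chr1\t1000\t3000\tA\t0\t+\n"


class TestMotifMask:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("TACT", [True] * 4),    # WRCY: T in W, A in R, C, T in Y
            ("AGTA", [True] * 4),    # RGYW: A in R, G, T in Y, A in W
            ("GGGG", [False] * 4),
            ("", []),
            ("NNNN", [False] * 4),
        ],
    )
    def test_known_fourmers(self, seq, expected):
        assert scan_motif_mask(seq).tolist() == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=400))
    def test_matches_brute_force_enumeration(self, seq):
        assert np.array_equal(scan_motif_mask(seq), brute_force_mask(seq))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=300))
    def test_motif_coverage_is_strand_symmetric(self, seq):
        assert scan_motif_mask(seq).sum() == scan_motif_mask(revcomp(seq)).sum()


class TestRegionSequenceStats:
    def _target(self, length, strand="+"):
        return SHMTarget("G", "chr1", strand, 0, length, length)

    def test_hand_enumerated_window(self):
        stats = region_sequence_stats(self._target(8), {"chr1": "TACTGGGG"})
        assert stats.frac_motif == pytest.approx(0.5)  # TACT covered, GGGG not
        assert stats.frac_cg == pytest.approx(5 / 8)   # C + GGGG
        assert stats.frac_at == pytest.approx(3 / 8)

    def test_all_ambiguous_window(self):
        stats = region_sequence_stats(self._target(6), {"chr1": "N" * 6})
        assert stats.frac_cg == 0 and stats.frac_at == 0 and stats.frac_motif == 0
        assert stats.frac_other == 1

    def test_missing_contig_raises(self):
        with pytest.raises(KeyError, match="chr2"):
            region_sequence_stats(SHMTarget("G", "chr2", "+", 0, 4, 4), {"chr1": "ACGT"})

    def test_reverse_complement_leaves_frac_motif_unchanged(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            fwd = region_sequence_stats(self._target(300, "+"), {"chr1": seq})
            rev = region_sequence_stats(self._target(300, "-"), {"chr1": revcomp(seq)})
            assert fwd.frac_motif == pytest.approx(rev.frac_motif)
            assert fwd.frac_cg == pytest.approx(rev.frac_cg)
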
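"""Gene models, SHM-target windows, and window sequence composition.

Somatic hypermutation acts in a narrow band downstream of the transcription
start site (TSS), so the unit of analysis is a fixed-width window — the
"SHM-target" — extending ``window_bp`` bases (default 2000) from each gene's
TSS in the transcription direction.  For every window we cache the base
composition and the per-position coverage by the AID hotspot motif WRCY
(W = A/T, R = A/G, Y = C/T) or its reverse complement RGYW; these fractions
are the success rates of the composition-corrected exact tests downstream.

Coordinates are 0-based half-open throughout.  BED input is consumed as-is;
GTF and knownGene-style tables are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TranscriptModel",
    "SHMTarget",
    "BaseCompositionStats",
    "load_gene_models",
    "derive_shm_targets",
    "scan_motif_mask",
    "region_sequence_stats",
    "write_targets_bed",
]

_VALID_STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript with its strand-aware transcription start site."""

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


@dataclass(frozen=True)
class SHMTarget:
    """A per-gene window downstream of the TSS in transcription direction.

    For '+' genes the window is [tss, tss + window_bp); for '-' genes it is
    [tss - window_bp, tss).  ``truncated`` flags windows clipped at a contig
    edge, in which case end - start < window_bp.
    """

    gene_symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    window_bp: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")
        if (self.end - self.start != self.window_bp) and not self.truncated:
            raise ValueError("window length differs from window_bp but truncated is False")

    @property
    def length(self) -> int:
        return self.end - self.start

    def tss_distance(self, pos: int) -> int:
        """Transcription-direction offset of a genomic position from the TSS."""
        return pos - self.start if self.strand == "+" else self.end - pos


@dataclass
class BaseCompositionStats:
    """Reference-base composition and hotspot-motif coverage of one window."""

    n_bases: int
    frac_cg: float
    frac_at: float
    frac_other: float
    frac_motif: float
    motif_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.motif_mask) != self.n_bases:
            raise ValueError("motif_mask length must equal n_bases")
        if abs((self.frac_cg + self.frac_at + self.frac_other) - 1.0) > 1e-9 and self.n_bases:
            raise ValueError("base fractions must sum to 1")


# ---------------------------------------------------------------------------
# gene-model readers


def _models_from_bed(path: Path) -> list[TranscriptModel]:
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED record needs >= 6 columns (strand required)")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in _VALID_STRANDS:
                raise ValueError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            tss = start_i if strand == "+" else end_i
            models.append(TranscriptModel(name, name, chrom, strand, tss))
    return models


def _models_from_gtf(path: Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    models: list[TranscriptModel] = []
    for feat in db.all_features():
        if feat.featuretype not in ("transcript", "mRNA"):
            continue
        if feat.strand not in _VALID_STRANDS:
            raise ValueError(f"{path}: transcript {feat.id} lacks a strand")
        gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [feat.id])[0]
        tx_id = (feat.attributes.get("transcript_id") or [feat.id])[0]
        # GTF is 1-based inclusive: leftmost 0-based coord is start-1, the
        # half-open right edge is simply `end`.
        tss = feat.start - 1 if feat.strand == "+" else feat.end
        models.append(TranscriptModel(gene, tx_id, feat.seqid, feat.strand, tss))
    return models


def _models_from_flat_table(path: Path) -> list[TranscriptModel]:
    """knownGene-style TSV: name, chrom, strand, txStart, txEnd, geneSymbol."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "chrom", "strand", "txStart", "txEnd", "geneSymbol"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: flat table missing columns {sorted(missing)}")
    models = []
    for row in table.itertuples(index=False):
        if row.strand not in _VALID_STRANDS:
            raise ValueError(f"{path}: record {row.name!r} has invalid strand {row.strand!r}")
        tss = int(row.txStart) if row.strand == "+" else int(row.txEnd)
        models.append(TranscriptModel(row.geneSymbol, row.name, row.chrom, row.strand, tss))
    return models


def load_gene_models(path: str | Path, format: str | None = None) -> list[TranscriptModel]:
    """Read transcript models from BED(6/12), GTF, or a knownGene-style table.

    The TSS respects strand: leftmost coordinate for '+', rightmost for '-'.
    ``format`` is one of ``bed12``/``gtf``/``flat_table``; when omitted it is
    inferred from the file suffix.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"bed": "bed12", "gtf": "gtf", "gff": "gtf"}.get(suffix.lstrip("."), "flat_table")
    if format == "bed12":
        return _models_from_bed(path)
    if format == "gtf":
        return _models_from_gtf(path)
    if format == "flat_table":
        return _models_from_flat_table(path)
    raise ValueError(f"unknown gene-model format {format!r}")


# ---------------------------------------------------------------------------
# window derivation


def derive_shm_targets(
    models: Sequence[TranscriptModel],
    window_bp: int = 2000,
    collapse: str = "per_gene",
    contig_lengths: Mapping[str, int] | None = None,
) -> list[SHMTarget]:
    """Derive the [TSS, TSS + window_bp) windows in transcription direction.

    ``per_gene`` emits one window per gene symbol, anchored at the most
    upstream TSS in transcription direction (minimum TSS for '+', maximum for
    '-'); ties break lexicographically on transcript_id.  ``per_transcript``
    emits one window per transcript.  Genes whose transcripts disagree on
    strand are skipped with a warning.  Windows are clipped at contig edges
    when ``contig_lengths`` is supplied, and flagged as truncated.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if collapse not in ("per_gene", "per_transcript"):
        raise ValueError(f"unknown collapse mode {collapse!r}")

    if collapse == "per_gene":
        by_gene: dict[str, list[TranscriptModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_symbol, []).append(m)
        chosen: list[TranscriptModel] = []
        for gene in sorted(by_gene):
            txs = by_gene[gene]
            strands = {t.strand for t in txs}
            if len(strands) > 1:
                warnings.warn(f"gene {gene}: transcripts on conflicting strands; skipped")
                continue
            strand = strands.pop()
            key = (lambda t: (t.tss, t.transcript_id)) if strand == "+" else (lambda t: (-t.tss, t.transcript_id))
            chosen.append(min(txs, key=key))
    else:
        chosen = list(models)

    targets: list[SHMTarget] = []
    for m in chosen:
        if m.strand == "+":
            start, end = m.tss, m.tss + window_bp
        else:
            start, end = m.tss - window_bp, m.tss
        truncated = False
        if start < 0:
            start, truncated = 0, True
        if contig_lengths is not None:
            limit = contig_lengths.get(m.chrom)
            if limit is not None and end > limit:
                end, truncated = limit, True
        targets.append(SHMTarget(m.gene_symbol, m.chrom, m.strand, start, end, window_bp, truncated))
    return targets


# ---------------------------------------------------------------------------
# motif scanning and composition


_BASE_CODE = np.zeros(256, dtype=np.uint8)  # 0 = other/ambiguous
for i, base in enumerate("ACGT", start=1):
    _BASE_CODE[ord(base)] = i
    _BASE_CODE[ord(base.lower())] = i
_A, _C, _G, _T = 1, 2, 3, 4


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_motif_mask(seq: str) -> np.ndarray:
    """Boolean per-position coverage by WRCY (given strand) or RGYW matches.

    A position is covered iff it lies inside any 4-mer matching either
    template on the scanned strand; scanning both templates on one strand is
    equivalent to scanning WRCY on both strands.  Ambiguity codes never match.
    """
    code = _encode(seq)
    n = len(code)
    covered = np.zeros(n, dtype=bool)
    if n < 4:
        return covered
    w = (code == _A) | (code == _T)
    r = (code == _A) | (code == _G)
    y = (code == _C) | (code == _T)
    c = code == _C
    g = code == _G
    wrcy = w[:-3] & r[1:-2] & c[2:-1] & y[3:]
    rgyw = r[:-3] & g[1:-2] & y[2:-1] & w[3:]
    hits = np.flatnonzero(wrcy | rgyw)
    for offset in range(4):
        covered[hits + offset] = True
    return covered


def region_sequence_stats(target: SHMTarget, genome: Mapping[str, object]) -> BaseCompositionStats:
    """Base composition and motif coverage of one window's reference sequence.

    ``genome`` may be a ``pyfaidx.Fasta`` or any mapping of contig name to a
    sliceable sequence (plain strings work).
    """
    try:
        record = genome[target.chrom]
    except KeyError as exc:
        raise KeyError(f"contig {target.chrom!r} absent from reference") from exc
    seq = str(record[target.start : target.end]).upper()
    code = _encode(seq)
    n = len(code)
    mask = scan_motif_mask(seq)
    if n == 0:
        return BaseCompositionStats(0, 0.0, 0.0, 0.0, 0.0, mask)
    n_cg = int(np.count_nonzero((code == _C) | (code == _G)))
    n_at = int(np.count_nonzero((code == _A) | (code == _T)))
    return BaseCompositionStats(
        n_bases=n,
        frac_cg=n_cg / n,
        frac_at=n_at / n,
        frac_other=(n - n_cg - n_at) / n,
        frac_motif=float(np.count_nonzero(mask)) / n,
        motif_mask=mask,
    )


def write_targets_bed(targets: Iterable[SHMTarget], path: str | Path) -> None:
    """Write windows as BED6 (name = gene symbol, score = 0)."""
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene_symbol}\t0\t{t.strand}\n")
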
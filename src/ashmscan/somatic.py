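"""Somatic SNV selection and substitution classification.

Tumor variant calls are reduced to putative somatic SNVs by removing sites
seen in the matched normal or in a population-variant panel, and by the
numeric support rules: call quality >= 20 and at least 20% of the
well-mapped reads (mapping quality > 25, base quality > 10) supporting the
alternate allele.  Read-level review is upstream of this module: the
high-quality alternate-allele fraction arrives precomputed on each call.

Each retained SNV is classified as transition/transversion and by the
reference base pair (C:G site vs A:T site); these two labels drive the
signature statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "VariantCall",
    "SomaticSNV",
    "FilterThresholds",
    "classify_substitution",
    "filter_somatic",
    "read_vcf_calls",
    "read_site_set",
    "write_somatic_tsv",
    "write_somatic_vcf",
]

_BASES = frozenset("ACGT")
_PURINES = frozenset("AG")
TRANSITION = "transition"
TRANSVERSION = "transversion"
CG_SITE = "CG_site"
AT_SITE = "AT_site"


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Classify a substitution: transition iff A<->G or C<->T; CG_site iff ref is C/G."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    subst = TRANSITION if (ref in _PURINES) == (alt in _PURINES) else TRANSVERSION
    site = CG_SITE if ref in "CG" else AT_SITE
    return subst, site


@dataclass(frozen=True)
class VariantCall:
    """One tumor variant call (0-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    call_quality: float
    alt_fraction_highqual: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_fraction_highqual <= 1.0:
            raise ValueError("alt_fraction_highqual must be in [0, 1]")

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class SomaticSNV(VariantCall):
    subst_class: str = ""
    site_class: str = ""


@dataclass(frozen=True)
class FilterThresholds:
    """Numeric somatic-selection rules.

    ``mapq_min``/``baseq_min`` document the read-filter under which
    ``alt_fraction_highqual`` was computed upstream; the fraction itself is
    compared against ``min_alt_fraction`` here.
    """

    min_quality: float = 20.0
    min_alt_fraction: float = 0.20
    mapq_min: int = 25
    baseq_min: int = 10


def filter_somatic(
    tumor: Iterable[VariantCall],
    matched_normal: set[tuple[str, int, str]] | frozenset = frozenset(),
    population: set[tuple[str, int, str]] | frozenset = frozenset(),
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SomaticSNV]:
    """Select and classify putative somatic SNVs.

    Retains biallelic single-base calls absent from both site sets, with
    call quality >= min_quality and high-quality alternate-read fraction
    >= min_alt_fraction; output sorted by (chrom, pos, sample_id).
    """
    out: list[SomaticSNV] = []
    for call in tumor:
        if len(call.ref) != 1 or len(call.alt) != 1:
            continue
        if call.ref.upper() not in _BASES or call.alt.upper() not in _BASES:
            continue
        if call.ref.upper() == call.alt.upper():
            continue
        if call.call_quality < thresholds.min_quality:
            continue
        if call.alt_fraction_highqual < thresholds.min_alt_fraction:
            continue
        if call.site_key in matched_normal or call.site_key in population:
            continue
        subst, site = classify_substitution(call.ref, call.alt)
        out.append(
            SomaticSNV(
                call.sample_id, call.chrom, call.pos, call.ref.upper(), call.alt.upper(),
                call.call_quality, call.alt_fraction_highqual, subst, site,
            )
        )
    out.sort(key=lambda s: (s.chrom, s.pos, s.sample_id))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_vcf_calls(path: str | Path, sample_id: str | None = None) -> list[VariantCall]:
    """Read one sample's variant calls from a VCF.

    Multi-allelic records are decomposed into biallelic calls.  The
    high-quality alternate-allele fraction is taken from INFO/AFHQ when
    present, else 1.0 (a table that has already been read-validated).
    ``sample_id`` defaults to the file stem.
    """
    import pysam

    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".vcf.gz").removesuffix(".vcf")
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        has_afhq = "AFHQ" in vcf.header.info
        for rec in vcf:
            if rec.ref is None or rec.alts is None:
                continue
            qual = float(rec.qual) if rec.qual is not None else 0.0
            afhq = rec.info.get("AFHQ", 1.0) if has_afhq else 1.0
            if isinstance(afhq, tuple):
                afhq_values = [float(a) for a in afhq]
            else:
                afhq_values = [float(afhq)] * len(rec.alts)
            for alt, frac in zip(rec.alts, afhq_values):
                if alt is None:
                    continue
                calls.append(
                    VariantCall(sample_id, rec.chrom, rec.start, rec.ref, str(alt), qual, frac)
                )
    return calls


def read_site_set(path: str | Path) -> set[tuple[str, int, str]]:
    """Read a site set (chrom, 0-based pos, alt) from a VCF or 3-column TSV."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        sites: set[tuple[str, int, str]] = set()
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if alt is not None:
                        sites.add((rec.chrom, rec.start, str(alt)))
        return sites
    sites = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, alt = line.split("\t")[:3]
            sites.add((chrom, int(pos), alt))
    return sites


def write_somatic_tsv(snvs: Sequence[SomaticSNV], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tcall_quality\talt_fraction_highqual\tsubst_class\tsite_class\n")
        for s in snvs:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t"
                f"{s.call_quality:g}\t{s.alt_fraction_highqual:g}\t{s.subst_class}\t{s.site_class}\n"
            )


def write_somatic_vcf(snvs: Sequence[SomaticSNV], path: str | Path, contigs: dict[str, int] | None = None) -> None:
    """Write a minimal single-purpose VCF with SUBST_CLASS / SITE_CLASS INFO tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample carrying the SNV">\n')
        fh.write('##INFO=<ID=SUBST_CLASS,Number=1,Type=String,Description="transition or transversion">\n')
        fh.write('##INFO=<ID=SITE_CLASS,Number=1,Type=String,Description="CG_site or AT_site">\n')
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snvs:
            info = f"SAMPLE={s.sample_id};SUBST_CLASS={s.subst_class};SITE_CLASS={s.site_class}"
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t{s.call_quality:g}\tPASS\t{info}\n")
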
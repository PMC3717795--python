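"""Self-contained synthetic DLBCL-like cohort generator.

Emulates the AID mutational process on a synthetic genome so the whole
scanner is testable without any external data: a random reference with
non-overlapping genes on both strands; per-sample somatic SNVs made of a
uniform genome-wide background plus, at designated aSHM genes, an extra
process concentrated in the 2 kb window downstream of the TSS with
exponentially decaying positional density, elevated rates at WRCY/RGYW
motif bases and at C:G sites, and a transition excess over the random
1-in-3 expectation; per-sample RPKM with optional coupling between a
sample's expression of a gene and that gene's mutation intensity; and
rearrangement breakpoints placed preferentially at aSHM genes.

Planted germline variants, shared population sites, and low-quality
artifact calls are emitted alongside so the somatic filter is exercised
end-to-end.  Everything is deterministic under (seed, config).

The default parameters are a "dlbcl-like" preset: genome background
2e-6 mutations/bp/sample, a 50x rate multiplier inside aSHM windows
(IGV-locus SHM runs near 1e-3/bp and non-IG targets 50-100x lower),
positional decay mean 700 bp, a per-base motif factor calibrated to an
observed WRCY enrichment of ~3, transition probability 0.5, C:G-site rate
factor 1.5, over 40 samples and 500 genes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import (
    SHMTarget,
    TranscriptModel,
    derive_shm_targets,
    region_sequence_stats,
)
from .expression import ExpressionTable
from .rearrangements import RearrangementEvent
from .somatic import VariantCall

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticReference",
    "SyntheticCohort",
    "generate_reference",
    "simulate_expression",
    "simulate_cohort",
    "simulate_rearrangements",
    "generate",
    "draw_alternate_allele",
    "write_cohort",
]

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterization of the simulated AID process and cohort."""

    seed: int = 0
    n_samples: int = 40
    n_genes: int = 500
    frac_ashm_genes: float = 0.10
    window_bp: int = 2000
    background_rate: float = 2e-6          # mutations / bp / sample
    ashm_rate_multiplier: float = 50.0     # in-window rate over background
    positional_decay_mean: float | None = 700.0  # bp; None = uniform placement
    # Per-base rate factor at motif-covered bases.  7.5 makes the realized
    # cohort-level WRCY enrichment in aSHM windows ~= 3, the observed
    # group-I value in the DLBCL cohort being emulated (the observed
    # enrichment r*f/(r*f + 1 - f)/f saturates well below the per-base
    # factor r at motif base fraction f ~= 0.22).
    motif_multiplier: float = 7.5
    transition_bias: float = 0.5           # P(mutation is a transition); null 1/3
    cg_bias: float = 1.5                   # relative per-base rate at C:G sites
    expression_coupling: float = 1.0       # exponent linking sample RPKM to intensity
    rearrangement_rate: float = 0.3        # events per sample
    rearrangement_ashm_preference: float = 0.9
    gc_content: float = 0.42
    # genome geometry
    gene_length_bp: int = 6000
    gene_slot_bp: int = 16000
    genes_per_contig: int = 50
    contig_margin_bp: int = 2000
    # expression model (lognormal baseline, mean RPKM ~= 50)
    rpkm_log_median: float = 30.0
    rpkm_gene_sigma: float = 1.0
    rpkm_sample_sigma: float = 0.5
    # nuisance processes feeding the somatic filter
    germline_rate: float = 5e-6
    population_site_rate: float = 2e-5
    population_carrier_prob: float = 0.3
    artifact_rate: float = 2e-7

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_ashm_genes <= 1.0:
            raise ValueError("frac_ashm_genes must be in [0, 1]")
        if not 0.0 < self.transition_bias < 1.0:
            raise ValueError("transition_bias must be in (0, 1)")
        if min(self.background_rate, self.motif_multiplier, self.cg_bias) < 0:
            raise ValueError("rates must be non-negative")
        if self.ashm_rate_multiplier < 1.0:
            raise ValueError("ashm_rate_multiplier must be >= 1")
        if self.gene_slot_bp < self.gene_length_bp + 2 * self.contig_margin_bp // 2:
            raise ValueError("gene_slot_bp too small for the gene length")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(1, self.n_samples + 1)]


@dataclass
class SyntheticReference:
    sequences: dict[str, str]
    models: list[TranscriptModel]
    tx_bounds: dict[str, tuple[str, int, int, str]]  # gene -> (chrom, txStart, txEnd, strand)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def genome_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class SyntheticCohort:
    """A full simulated cohort plus its truth labels."""

    config: SyntheticCohortConfig
    reference: SyntheticReference
    targets: list[SHMTarget]
    expression: ExpressionTable
    tumor_calls: dict[str, list[VariantCall]]
    matched_normal: dict[str, set[tuple[str, int, str]]]
    population: set[tuple[str, int, str]]
    rearrangements: list[RearrangementEvent]
    truth: dict = field(default_factory=dict)


def _rng(config: SyntheticCohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_reference(config: SyntheticCohortConfig) -> SyntheticReference:
    """I.i.d. reference with the configured GC content and non-overlapping genes.

    Genes sit in fixed slots (both strands drawn at random) on contigs of
    ``genes_per_contig`` slots, so each 12 kb downstream profile window stays
    clear of the next gene's TSS cluster.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(config, 1)
    p_cg = config.gc_content / 2.0
    p_at = (1.0 - config.gc_content) / 2.0
    probs = [p_at, p_cg, p_cg, p_at]
    bases = np.array(list("ACGT"))

    sequences: dict[str, str] = {}
    models: list[TranscriptModel] = []
    tx_bounds: dict[str, tuple[str, int, int, str]] = {}
    n_contigs = int(np.ceil(config.n_genes / config.genes_per_contig))
    for ci in range(n_contigs):
        genes_here = min(config.genes_per_contig, config.n_genes - ci * config.genes_per_contig)
        length = genes_here * config.gene_slot_bp + 2 * config.contig_margin_bp
        chrom = f"chr{ci + 1}"
        sequences[chrom] = "".join(rng.choice(bases, size=length, p=probs))
        for gi in range(genes_here):
            idx = ci * config.genes_per_contig + gi
            gene = f"G{idx:04d}"
            slot = config.contig_margin_bp + gi * config.gene_slot_bp
            tx_start = slot + (config.gene_slot_bp - config.gene_length_bp) // 2
            tx_end = tx_start + config.gene_length_bp
            strand = "+" if rng.random() < 0.5 else "-"
            tss = tx_start if strand == "+" else tx_end
            models.append(TranscriptModel(gene, f"{gene}.t1", chrom, strand, tss))
            tx_bounds[gene] = (chrom, tx_start, tx_end, strand)
    return SyntheticReference(sequences, models, tx_bounds)


def simulate_expression(
    config: SyntheticCohortConfig,
    genes: Sequence[str],
) -> ExpressionTable:
    """Log-normal RPKM: gene baseline (median 30, sigma 1) x mean-one sample noise."""
    rng = _rng(config, 2)
    mu = np.log(config.rpkm_log_median)
    base = rng.lognormal(mu, config.rpkm_gene_sigma, size=len(genes))
    s = config.rpkm_sample_sigma
    noise = rng.lognormal(-0.5 * s * s, s, size=(config.n_samples, len(genes)))
    rpkm = pd.DataFrame(base[None, :] * noise, index=config.sample_ids, columns=list(genes))
    return ExpressionTable(rpkm, provenance="given_rpkm")


def draw_alternate_allele(ref: str, rng: np.random.Generator, transition_bias: float) -> str:
    """Transition with probability ``transition_bias``, else a uniform transversion."""
    if rng.random() < transition_bias:
        return _TRANSITION_OF[ref]
    tv = _TRANSVERSIONS_OF[ref]
    return tv[int(rng.integers(2))]


def _genome_offsets(reference: SyntheticReference) -> tuple[list[str], np.ndarray]:
    chroms = list(reference.sequences)
    lengths = np.array([len(reference.sequences[c]) for c in chroms], dtype=np.int64)
    return chroms, np.concatenate([[0], np.cumsum(lengths)])


def simulate_cohort(
    config: SyntheticCohortConfig,
    reference: SyntheticReference,
    expression: ExpressionTable | None = None,
) -> tuple[dict[str, list[VariantCall]], dict[str, set], set, dict]:
    """Place somatic, germline, population, and artifact calls for every sample.

    Returns (tumor calls per sample, matched-normal site set per sample,
    population site set, truth table).  Somatic mutations are a genome-wide
    Poisson background plus, at aSHM genes, a categorical draw over window
    positions with unnormalized weights decay(d) x motif factor x site
    factor; intensity per (sample, gene) is scaled by a mean-one power of
    the sample's RPKM when expression coupling is on.
    """
    rng = _rng(config, 3)
    targets = derive_shm_targets(reference.models, config.window_bp, "per_gene", reference.contig_lengths)
    target_of = {t.gene_symbol: t for t in targets}
    genes = [m.gene_symbol for m in reference.models]

    n_ashm = int(round(config.n_genes * config.frac_ashm_genes))
    ashm_genes = sorted(rng.choice(genes, size=n_ashm, replace=False)) if n_ashm else []
    ashm_set = set(ashm_genes)

    chroms, offsets = _genome_offsets(reference)
    genome_bp = int(offsets[-1])
    samples = config.sample_ids

    # Per-(sample, gene) coupling factors, normalized to mean one per gene so
    # the cohort-level intensity is independent of the coupling strength.
    couple = np.ones((config.n_samples, len(ashm_genes)))
    if expression is not None and config.expression_coupling > 0 and ashm_genes:
        rel = expression.rpkm[ashm_genes].to_numpy()
        rel = rel / rel.mean(axis=0, keepdims=True)
        couple = rel ** config.expression_coupling
        couple = couple / couple.mean(axis=0, keepdims=True)

    tumor: dict[str, list[VariantCall]] = {s: [] for s in samples}
    normals: dict[str, set] = {s: set() for s in samples}
    truth_counts: dict[str, dict[str, int]] = {g: {} for g in genes}

    def _ref_base(chrom: str, pos: int) -> str:
        return reference.sequences[chrom][pos]

    def _add_somatic(sample: str, chrom: str, pos: int, gene_hint: str | None) -> None:
        ref = _ref_base(chrom, pos)
        if ref not in "ACGT":
            return
        alt = draw_alternate_allele(ref, rng, config.transition_bias)
        qual = float(rng.uniform(25.0, 60.0))
        frac = float(rng.beta(8.0, 4.0))
        tumor[sample].append(VariantCall(sample, chrom, pos, ref, alt, qual, frac))
        gene = gene_hint
        if gene is None:
            t = _locate_target(targets, chrom, pos)
            gene = t.gene_symbol if t else None
        if gene is not None:
            counts = truth_counts[gene]
            counts[sample] = counts.get(sample, 0) + 1

    # window weights per aSHM gene (shared across samples)
    window_weights: dict[str, np.ndarray] = {}
    window_stats = {}
    for g in ashm_genes:
        t = target_of[g]
        st = region_sequence_stats(t, reference.sequences)
        window_stats[g] = st
        pos_idx = np.arange(t.length)
        d = pos_idx if t.strand == "+" else (t.length - pos_idx)
        if config.positional_decay_mean:
            w = np.exp(-d / float(config.positional_decay_mean))
        else:
            w = np.ones(t.length, dtype=float)
        w = w * np.where(st.motif_mask, config.motif_multiplier, 1.0)
        seq = reference.sequences[t.chrom][t.start : t.end].upper()
        code = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_cg = (code == ord("C")) | (code == ord("G"))
        is_acgt = np.isin(code, np.frombuffer(b"ACGT", dtype=np.uint8))
        w = w * np.where(is_cg, config.cg_bias, 1.0) * is_acgt
        window_weights[g] = w / w.sum()

    extra_rate = config.background_rate * (config.ashm_rate_multiplier - 1.0)
    for si, sample in enumerate(samples):
        # genome-wide background
        n_bg = rng.poisson(genome_bp * config.background_rate)
        flat = rng.integers(0, genome_bp, size=n_bg)
        for fp in flat:
            ci = int(np.searchsorted(offsets, fp, side="right")) - 1
            _add_somatic(sample, chroms[ci], int(fp - offsets[ci]), None)
        # AID process at aSHM genes
        for gi, g in enumerate(ashm_genes):
            t = target_of[g]
            lam = extra_rate * t.length * couple[si, gi]
            n_extra = rng.poisson(lam)
            if n_extra == 0:
                continue
            picks = rng.choice(t.length, size=n_extra, replace=True, p=window_weights[g])
            for off in sorted(set(int(x) for x in picks)):
                _add_somatic(sample, t.chrom, t.start + off, g)

    # germline variants: in the tumor calls and in the matched normal set
    for sample in samples:
        n_germ = rng.poisson(genome_bp * config.germline_rate)
        flat = rng.integers(0, genome_bp, size=n_germ)
        for fp in flat:
            ci = int(np.searchsorted(offsets, fp, side="right")) - 1
            chrom, pos = chroms[ci], int(fp - offsets[ci])
            ref = _ref_base(chrom, pos)
            if ref not in "ACGT":
                continue
            alt = draw_alternate_allele(ref, rng, 2.0 / 3.0)  # germline Ti:Tv ~ 2:1
            normals[sample].add((chrom, pos, alt))
            tumor[sample].append(
                VariantCall(sample, chrom, pos, ref, alt, float(rng.uniform(30, 70)), float(rng.beta(14, 14)))
            )

    # shared population sites, carried by a fraction of tumors
    population: set = set()
    n_pop = rng.poisson(genome_bp * config.population_site_rate)
    flat = rng.integers(0, genome_bp, size=n_pop)
    for fp in flat:
        ci = int(np.searchsorted(offsets, fp, side="right")) - 1
        chrom, pos = chroms[ci], int(fp - offsets[ci])
        ref = _ref_base(chrom, pos)
        if ref not in "ACGT":
            continue
        alt = draw_alternate_allele(ref, rng, 2.0 / 3.0)
        population.add((chrom, pos, alt))
        for sample in samples:
            if rng.random() < config.population_carrier_prob:
                tumor[sample].append(
                    VariantCall(sample, chrom, pos, ref, alt, float(rng.uniform(30, 70)), float(rng.beta(14, 14)))
                )

    # artifact calls that must fall to the quality / support thresholds
    for sample in samples:
        n_art = rng.poisson(genome_bp * config.artifact_rate)
        flat = rng.integers(0, genome_bp, size=n_art)
        for fp in flat:
            ci = int(np.searchsorted(offsets, fp, side="right")) - 1
            chrom, pos = chroms[ci], int(fp - offsets[ci])
            ref = _ref_base(chrom, pos)
            if ref not in "ACGT":
                continue
            alt = draw_alternate_allele(ref, rng, 1.0 / 3.0)
            if rng.random() < 0.5:
                qual, frac = float(rng.uniform(2.0, 19.5)), float(rng.beta(8, 4))
            else:
                qual, frac = float(rng.uniform(25.0, 60.0)), float(rng.uniform(0.0, 0.19))
            tumor[sample].append(VariantCall(sample, chrom, pos, ref, alt, qual, frac))

    for sample in samples:
        tumor[sample].sort(key=lambda c: (c.chrom, c.pos, c.alt))

    realized_density = {
        g: sum(truth_counts[g].values()) / target_of[g].length / config.n_samples for g in genes
    }
    truth = {
        "ashm_genes": list(ashm_genes),
        "is_ashm": {g: (g in ashm_set) for g in genes},
        "per_sample_counts": truth_counts,
        "realized_density": realized_density,
        "genome_bp": genome_bp,
        "config": dataclasses.asdict(config),
    }
    return tumor, normals, population, truth


def _locate_target(targets: Sequence[SHMTarget], chrom: str, pos: int) -> SHMTarget | None:
    for t in targets:
        if t.chrom == chrom and t.start <= pos < t.end:
            return t
    return None


def simulate_rearrangements(
    config: SyntheticCohortConfig,
    truth: dict,
    reference: SyntheticReference,
    targets: Sequence[SHMTarget],
) -> list[RearrangementEvent]:
    """Breakpoints placed preferentially inside aSHM windows, partner elsewhere."""
    rng = _rng(config, 4)
    target_of = {t.gene_symbol: t for t in targets}
    ashm = [g for g in truth["ashm_genes"] if g in target_of]
    chroms, offsets = _genome_offsets(reference)
    genome_bp = int(offsets[-1])
    n_events = rng.poisson(config.rearrangement_rate * config.n_samples)
    samples = config.sample_ids
    events: list[RearrangementEvent] = []
    for _ in range(n_events):
        sample = samples[int(rng.integers(len(samples)))]
        if ashm and rng.random() < config.rearrangement_ashm_preference:
            t = target_of[ashm[int(rng.integers(len(ashm)))]]
            chrom_a = t.chrom
            pos_a = int(rng.integers(t.start, t.end))
        else:
            fp = int(rng.integers(genome_bp))
            ci = int(np.searchsorted(offsets, fp, side="right")) - 1
            chrom_a, pos_a = chroms[ci], int(fp - offsets[ci])
        if len(chroms) > 1 and rng.random() < 0.8:
            other = [c for c in chroms if c != chrom_a]
            chrom_b = other[int(rng.integers(len(other)))]
            pos_b = int(rng.integers(len(reference.sequences[chrom_b])))
            cls = "translocation"
        else:
            chrom_b = chrom_a
            pos_b = min(int(pos_a + rng.integers(5_000, 50_000)), len(reference.sequences[chrom_a]) - 1)
            if pos_b == pos_a:
                pos_b += 1
            cls = "inversion"
        events.append(RearrangementEvent(sample, chrom_a, pos_a, chrom_b, pos_b, cls))
    return events


def generate(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Run every simulation stage and bundle the results."""
    reference = generate_reference(config)
    genes = [m.gene_symbol for m in reference.models]
    expression = simulate_expression(config, genes)
    tumor, normals, population, truth = simulate_cohort(config, reference, expression)
    targets = derive_shm_targets(reference.models, config.window_bp, "per_gene", reference.contig_lengths)
    events = simulate_rearrangements(config, truth, reference, targets)
    return SyntheticCohort(config, reference, targets, expression, tumor, normals, population, events, truth)


# ---------------------------------------------------------------------------
# on-disk serialization (plain-text formats only)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write FASTA, BED12, per-sample VCFs, site sets, expression, BEDPE, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = cohort.reference
    with open(outdir / "reference.fa", "w") as fh:
        for chrom, seq in ref.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(outdir / "genes.bed", "w") as fh:
        for gene, (chrom, start, end, strand) in ref.tx_bounds.items():
            size = end - start
            fh.write(
                f"{chrom}\t{start}\t{end}\t{gene}\t0\t{strand}\t{start}\t{end}\t0\t1\t{size},\t0,\n"
            )
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    contigs = ref.contig_lengths
    for sample, calls in cohort.tumor_calls.items():
        _write_calls_vcf(calls, vcf_dir / f"{sample}.vcf", contigs)
        with open(vcf_dir / f"{sample}.normal.tsv", "w") as fh:
            for chrom, pos, alt in sorted(cohort.matched_normal[sample]):
                fh.write(f"{chrom}\t{pos}\t{alt}\n")
    with open(outdir / "population_sites.tsv", "w") as fh:
        for chrom, pos, alt in sorted(cohort.population):
            fh.write(f"{chrom}\t{pos}\t{alt}\n")
    cohort.expression.rpkm.T.rename_axis("gene").to_csv(outdir / "expression.tsv", sep="\t")
    with open(outdir / "rearrangements.tsv", "w") as fh:
        fh.write("sample\tchromA\tposA\tchromB\tposB\tclass\n")
        for e in cohort.rearrangements:
            fh.write(f"{e.sample_id}\t{e.chrom_a}\t{e.pos_a}\t{e.chrom_b}\t{e.pos_b}\t{e.event_class}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=1)


def _write_calls_vcf(calls: Sequence[VariantCall], path: Path, contigs: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AFHQ,Number=1,Type=Float,Description="Alt fraction among high-quality reads">\n')
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t{c.call_quality:.2f}\t.\tAFHQ={c.alt_fraction_highqual:.4f}\n"
            )
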
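"""End-to-end cohort scan shared by the CLI, the analysis drivers, and tests."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations import (
    SHMTarget,
    derive_shm_targets,
    load_gene_models,
    region_sequence_stats,
)
from .expression import ExpressionTable, expression_fold_change
from .features import build_feature_table, write_feature_table, FEATURE_COLUMNS
from .rearrangements import assign_events_to_genes, mutation_rearrangement_table
from .somatic import FilterThresholds, SomaticSNV, filter_somatic, read_site_set, read_vcf_calls
from .stratify import assign_groups, compare_distance_distributions, tss_distance_profile

__all__ = ["ScanResult", "scan_cohort", "scan_directory", "write_scan_outputs"]


@dataclass
class ScanResult:
    feature_table: pd.DataFrame
    groups: pd.DataFrame
    profiles: dict
    ks_tests: dict[str, tuple[float, float]]
    xtab: pd.DataFrame | None = None
    snvs: list = field(default_factory=list, repr=False)
    n_samples: int = 0
    genome_bp: int = 0


def scan_cohort(
    targets: Sequence[SHMTarget],
    genome: Mapping[str, object],
    snvs: Sequence[SomaticSNV],
    n_samples: int,
    genome_bp: int,
    expression: ExpressionTable | None = None,
    rearrangements=None,
    ig_genes: Sequence[str] = (),
    min_rpkm: float = 5.0,
    flank_bp: int = 100_000,
    profile_window: int = 12000,
    cap_at_half: bool = True,
) -> ScanResult:
    """Run the signature scan over already-filtered somatic SNVs.

    Computes window composition, the per-region feature table (with
    expression linkage when an RPKM table is supplied), mutation-rate
    groups, TSS-distance profiles with pairwise KS comparisons, and the
    mutation x rearrangement cross-tab when events are supplied.
    """
    stats = {t.gene_symbol: region_sequence_stats(t, genome) for t in targets}

    # per-gene mutated-sample sets (window membership)
    mutated: dict[str, set[str]] = {t.gene_symbol: set() for t in targets}
    by_chrom: dict[str, list[SHMTarget]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.start)
    for s in snvs:
        for t in by_chrom.get(s.chrom, ()):
            if t.start <= s.pos < t.end:
                mutated[t.gene_symbol].add(s.sample_id)
                break

    expr_rows = None
    if expression is not None:
        expr_rows = {}
        for t in targets:
            if t.gene_symbol not in expression.rpkm.columns:
                continue
            row = expression_fold_change(expression, t.gene_symbol, mutated[t.gene_symbol], min_rpkm)
            expr_rows[t.gene_symbol] = (row.fold_change, row.mean_rpkm_mutated, row.mean_rpkm_unmutated)

    table = build_feature_table(
        targets, stats, list(snvs), n_samples,
        genome_bp=genome_bp, expression_rows=expr_rows, cap_at_half=cap_at_half,
    )

    groups = assign_groups(table, ig_genes=ig_genes)
    groups_df = pd.DataFrame(
        [(g.gene_symbol, g.group, g.mutation_density, g.n_snvs_total) for g in groups],
        columns=["gene", "group", "mutation_density", "total_snvs"],
    )
    profiles = tss_distance_profile(list(snvs), targets, groups, profile_window=profile_window)
    ks: dict[str, tuple[float, float]] = {}
    names = sorted(profiles)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            try:
                ks[f"{a}_vs_{b}"] = compare_distance_distributions(profiles[a], profiles[b])
            except ValueError:
                continue

    xtab = None
    if rearrangements is not None:
        samples = sorted({s.sample_id for s in snvs}) if n_samples == 0 else None
        cohort_samples = samples or [f"S{i:03d}" for i in range(1, n_samples + 1)]
        rearr = assign_events_to_genes(rearrangements, list(targets), flank_bp)
        xtab = mutation_rearrangement_table(mutated, rearr, cohort_samples)

    return ScanResult(table, groups_df, profiles, ks, xtab, list(snvs), n_samples, genome_bp)


def simulate_and_scan(config, use_expression: bool = True, use_rearrangements: bool = True, **scan_kwargs):
    """Generate a synthetic cohort, somatic-filter it, and scan it.

    Returns (cohort, ScanResult); the canonical in-memory end-to-end path
    used by the analysis drivers and the test suite.
    """
    from .simulate import generate

    cohort = generate(config)
    snvs: list[SomaticSNV] = []
    for sample in config.sample_ids:
        snvs.extend(
            filter_somatic(cohort.tumor_calls[sample], cohort.matched_normal[sample], cohort.population)
        )
    snvs.sort(key=lambda s: (s.chrom, s.pos, s.sample_id))
    result = scan_cohort(
        cohort.targets,
        cohort.reference.sequences,
        snvs,
        config.n_samples,
        cohort.reference.genome_bp,
        expression=cohort.expression if use_expression else None,
        rearrangements=cohort.rearrangements if use_rearrangements else None,
        **scan_kwargs,
    )
    return cohort, result


def scan_directory(
    vcf_dir: str | Path,
    genes_path: str | Path,
    reference_path: str | Path,
    population_path: str | Path | None = None,
    expression_path: str | Path | None = None,
    rearrangements_path: str | Path | None = None,
    ig_genes_path: str | Path | None = None,
    window_bp: int = 2000,
    thresholds: FilterThresholds = FilterThresholds(),
    **scan_kwargs,
) -> ScanResult:
    """File-based front end: read inputs, filter to somatic SNVs, scan.

    ``vcf_dir`` holds one ``<sample>.vcf`` per tumor with an optional
    ``<sample>.normal.tsv`` (or ``.normal.vcf``) matched-normal site file.
    """
    import pyfaidx

    from .expression import read_expression_tsv
    from .rearrangements import read_rearrangements

    vcf_dir = Path(vcf_dir)
    genome = pyfaidx.Fasta(str(reference_path))
    contig_lengths = {name: len(rec) for name, rec in genome.records.items()}
    genome_bp = sum(contig_lengths.values())
    models = load_gene_models(genes_path)
    targets = derive_shm_targets(models, window_bp, "per_gene", contig_lengths)

    population = read_site_set(population_path) if population_path else set()
    snvs: list[SomaticSNV] = []
    sample_ids = []
    for vcf_path in sorted(vcf_dir.glob("*.vcf")):
        if vcf_path.name.endswith(".normal.vcf"):
            continue
        sample = vcf_path.name.removesuffix(".vcf")
        sample_ids.append(sample)
        calls = read_vcf_calls(vcf_path, sample)
        normal: set = set()
        for suffix in (".normal.tsv", ".normal.vcf"):
            cand = vcf_dir / f"{sample}{suffix}"
            if cand.exists():
                normal = read_site_set(cand)
                break
        snvs.extend(filter_somatic(calls, normal, population, thresholds))
    snvs.sort(key=lambda s: (s.chrom, s.pos, s.sample_id))

    expression = read_expression_tsv(expression_path) if expression_path else None
    events = read_rearrangements(rearrangements_path) if rearrangements_path else None
    ig_genes: list[str] = []
    if ig_genes_path:
        ig_genes = [l.strip() for l in open(ig_genes_path) if l.strip()]

    return scan_cohort(
        targets, genome, snvs, len(sample_ids), genome_bp,
        expression=expression, rearrangements=events, ig_genes=ig_genes, **scan_kwargs,
    )


def write_scan_outputs(result: ScanResult, outdir: str | Path, manifest: dict | None = None) -> None:
    """Write the report set: TSVs round to 4 decimals, JSON keeps full precision."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(result.feature_table, outdir / "feature_table.tsv")
    result.feature_table.to_json(outdir / "feature_table.json", orient="records", indent=1)
    result.groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    for grp, prof in result.profiles.items():
        pd.DataFrame({"distance": prof.distances}).to_csv(
            outdir / f"distances_{grp}.tsv", sep="\t", index=False
        )
    ks = {k: {"statistic": v[0], "p": v[1]} for k, v in result.ks_tests.items()}
    medians = {g: p.median_distance for g, p in result.profiles.items()}
    with open(outdir / "distance_tests.json", "w") as fh:
        json.dump({"ks": ks, "median_distance": medians}, fh, indent=1)
    if result.xtab is not None:
        result.xtab.to_csv(outdir / "mutation_rearrangement.tsv", sep="\t", index=False)
    payload = dict(manifest or {})
    payload.setdefault("n_samples", result.n_samples)
    payload.setdefault("genome_bp", result.genome_bp)
    payload.setdefault("n_regions_reported", int(len(result.feature_table)))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
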
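"""Per-region SHM signature statistics and the composite SHM indicator.

For each SHM-target the cohort's somatic SNVs are pooled and scored against
three hallmarks of AID activity, each corrected for the window's base
composition by using the relevant composition fraction as the success rate
of an exact one-sided binomial test:

* hotspot-motif bias — SNVs at WRCY/RGYW-covered bases vs the covered
  fraction of the window;
* C:G-site bias — SNVs whose reference base is C or G vs the window's C+G
  fraction;
* transition bias — transitions vs the 1-in-3 random expectation (a uniform
  substitution has one transition among three possible alternate alleles,
  independent of composition).

The SHM indicator of a region is the geometric mean of the three p-values;
low values flag regions whose mutations look AID-made.  Region mutation
burden gets its own exact test (window length over genome length as the
success rate, genome-wide somatic SNV count as the trial count), corrected
across regions by Benjamini–Hochberg.

aSHM predicts excess in every tested direction, so upper tails are used
throughout; reported p-values are capped at 0.5 by default, the convention
used for depleted regions in published feature tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import binom_upper_tail, cap_at_half, geometric_mean_p, hypergeom_upper_tail
from .annotations import BaseCompositionStats, SHMTarget
from .somatic import SomaticSNV, TRANSITION, CG_SITE

__all__ = [
    "RegionMutationProfile",
    "count_region_mutations",
    "mutation_density",
    "motif_enrichment",
    "cg_at_enrichment",
    "titv_stats",
    "region_burden_test",
    "benjamini_adjust",
    "shm_indicator",
    "build_feature_table",
    "FEATURE_COLUMNS",
    "write_feature_table",
]


@dataclass
class RegionMutationProfile:
    """Cohort-aggregated mutation counts for one SHM-target."""

    gene_symbol: str
    n_snvs_total: int = 0
    n_samples_mutated: int = 0
    n_transitions: int = 0
    n_transversions: int = 0
    n_at_cg_sites: int = 0
    n_at_at_sites: int = 0
    n_in_motif: int = 0
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_transitions + self.n_transversions != self.n_snvs_total:
            raise ValueError("transition/transversion counts do not partition the SNVs")
        if self.n_at_cg_sites + self.n_at_at_sites != self.n_snvs_total:
            raise ValueError("site-class counts do not partition the SNVs")
        if self.n_in_motif > self.n_snvs_total:
            raise ValueError("n_in_motif exceeds n_snvs_total")


def count_region_mutations(
    target: SHMTarget,
    stats: BaseCompositionStats,
    snvs: Iterable[SomaticSNV],
) -> tuple[RegionMutationProfile, list[SomaticSNV]]:
    """Aggregate a cohort's SNVs over one window.

    SNVs outside the window (or on another contig) are excluded and returned
    as the spill list.  An SNV is "in motif" iff the motif mask is set at its
    offset within the window.
    """
    profile = RegionMutationProfile(gene_symbol=target.gene_symbol)
    spilled: list[SomaticSNV] = []
    for snv in snvs:
        if snv.chrom != target.chrom or not (target.start <= snv.pos < target.end):
            spilled.append(snv)
            continue
        profile.n_snvs_total += 1
        if snv.subst_class == TRANSITION:
            profile.n_transitions += 1
        else:
            profile.n_transversions += 1
        if snv.site_class == CG_SITE:
            profile.n_at_cg_sites += 1
        else:
            profile.n_at_at_sites += 1
        if stats.motif_mask[snv.pos - target.start]:
            profile.n_in_motif += 1
        profile.per_sample_counts[snv.sample_id] = profile.per_sample_counts.get(snv.sample_id, 0) + 1
    profile.n_samples_mutated = len(profile.per_sample_counts)
    profile.validate()
    return profile, spilled


def mutation_density(profile: RegionMutationProfile, window_bp: int, n_samples: int) -> float:
    """Cohort mutation density: mean over all samples of count / window length.

    Samples without any SNV in the window contribute zero to the mean.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    total = sum(profile.per_sample_counts.values())
    return total / window_bp / n_samples


def motif_enrichment(
    profile: RegionMutationProfile,
    stats: BaseCompositionStats,
    cap: bool = True,
) -> tuple[float, float]:
    """Hotspot-motif enrichment and its exact one-sided p-value.

    enrichment = observed / (frac_motif * n); p = P(X >= observed) for
    X ~ Binomial(n, frac_motif).  With no SNVs the enrichment is undefined
    (NaN) and p = 1.
    """
    return _composition_test(profile.n_in_motif, profile.n_snvs_total, stats.frac_motif, cap)


def cg_at_enrichment(
    profile: RegionMutationProfile,
    stats: BaseCompositionStats,
    cap: bool = True,
) -> tuple[float, float]:
    """C:G-site enrichment against the window's C+G composition."""
    return _composition_test(profile.n_at_cg_sites, profile.n_snvs_total, stats.frac_cg, cap)


def _composition_test(k: int, n: int, rate: float, cap: bool) -> tuple[float, float]:
    if n == 0:
        return math.nan, 1.0
    expected = rate * n
    enrichment = k / expected if expected > 0 else 0.0
    p = binom_upper_tail(k, n, rate)
    return enrichment, cap_at_half(p) if cap else p


def titv_stats(
    profile: RegionMutationProfile,
    null_rate: float = 1.0 / 3.0,
    cap: bool = True,
) -> tuple[float, float]:
    """Transition/transversion ratio and exact test against the 1:2 null.

    Ratio is NaN when both counts are zero and +inf when only transversions
    are absent (reported as "Ti:0").  p = P(X >= n_transitions) for
    X ~ Binomial(n_snvs, null_rate).
    """
    ti, tv = profile.n_transitions, profile.n_transversions
    if ti == 0 and tv == 0:
        return math.nan, 1.0
    if tv == 0:
        ratio = math.inf
    else:
        ratio = ti / tv
    p = binom_upper_tail(ti, ti + tv, null_rate)
    return ratio, cap_at_half(p) if cap else p


def region_burden_test(
    profile: RegionMutationProfile,
    n_snvs_genomewide: int,
    genome_bp: int,
    window_bp: int,
    family: str = "binomial",
) -> float:
    """Exact upper-tail test of the region's mutation burden.

    Success rate is window_bp / genome_bp; the trial count is the cohort's
    genome-wide somatic SNV total.  ``family='hypergeometric'`` conditions on
    the genome-wide total as a fixed draw of positions instead.
    """
    if not (0 < window_bp <= genome_bp):
        raise ValueError("need 0 < window_bp <= genome_bp")
    if profile.n_snvs_total > n_snvs_genomewide:
        raise ValueError("region SNVs exceed genome-wide total")
    if family == "binomial":
        return binom_upper_tail(profile.n_snvs_total, n_snvs_genomewide, window_bp / genome_bp)
    if family == "hypergeometric":
        return hypergeom_upper_tail(profile.n_snvs_total, genome_bp, window_bp, n_snvs_genomewide)
    raise ValueError(f"unknown test family {family!r}")


def benjamini_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    if len(pvalues) == 0:
        return []
    for p in pvalues:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(list(pvalues), method="fdr_bh")[1])


def shm_indicator(p_motif: float, p_cg: float, p_titv: float) -> float:
    """Composite SHM indicator: geometric mean of the three signature p-values."""
    return geometric_mean_p(p_motif, p_cg, p_titv)


FEATURE_COLUMNS = [
    "gene", "shm_indicator", "total_snvs", "mutated_samples",
    "titv_ratio", "titv_p", "motif_enrichment", "motif_p",
    "cg_at_enrichment", "cg_at_p", "burden_p", "burden_q",
    "rpkm_fold_change", "mean_rpkm_mutated", "mean_rpkm_unmutated",
]


def build_feature_table(
    targets: Sequence[SHMTarget],
    stats: Mapping[str, BaseCompositionStats],
    snvs: Sequence[SomaticSNV],
    n_samples: int,
    genome_bp: int | None = None,
    n_snvs_genomewide: int | None = None,
    expression_rows: Mapping[str, tuple[float, float, float]] | None = None,
    cap_at_half: bool = True,
    titv_null_rate: float = 1.0 / 3.0,
    burden_family: str = "binomial",
) -> pd.DataFrame:
    """Assemble the per-region feature table.

    One row per target with at least one SNV, sorted by total SNVs
    descending (ties broken by gene symbol).  Burden p-values are computed
    for every target and Benjamini–Hochberg–adjusted across all of them
    before rows without SNVs are dropped.  ``expression_rows`` maps gene to
    (fold_change, mean_rpkm_mutated, mean_rpkm_unmutated); genes absent from
    it get missing expression columns.
    """
    by_target: dict[str, list[SomaticSNV]] = {t.gene_symbol: [] for t in targets}
    index = {}
    for t in targets:
        index.setdefault(t.chrom, []).append(t)
    for chrom_targets in index.values():
        chrom_targets.sort(key=lambda t: t.start)
    starts = {c: np.array([t.start for t in ts]) for c, ts in index.items()}
    for snv in snvs:
        ts = index.get(snv.chrom)
        if not ts:
            continue
        i = int(np.searchsorted(starts[snv.chrom], snv.pos, side="right")) - 1
        if i >= 0 and ts[i].start <= snv.pos < ts[i].end:
            by_target[ts[i].gene_symbol].append(snv)

    if n_snvs_genomewide is None:
        n_snvs_genomewide = len(snvs)

    rows = []
    burden_ps = []
    for t in targets:
        st = stats[t.gene_symbol]
        profile, _ = count_region_mutations(t, st, by_target[t.gene_symbol])
        dens = mutation_density(profile, t.length, n_samples)
        m_enr, m_p = motif_enrichment(profile, st, cap=cap_at_half)
        c_enr, c_p = cg_at_enrichment(profile, st, cap=cap_at_half)
        ratio, t_p = titv_stats(profile, null_rate=titv_null_rate, cap=cap_at_half)
        if genome_bp is not None:
            b_p = region_burden_test(profile, n_snvs_genomewide, genome_bp, t.length, family=burden_family)
        else:
            b_p = math.nan
        indicator = shm_indicator(m_p, c_p, t_p)
        expr = (expression_rows or {}).get(t.gene_symbol, (math.nan, math.nan, math.nan))
        rows.append(
            dict(
                gene=t.gene_symbol, shm_indicator=indicator,
                total_snvs=profile.n_snvs_total, mutated_samples=profile.n_samples_mutated,
                titv_ratio=ratio, titv_p=t_p,
                motif_enrichment=m_enr, motif_p=m_p,
                cg_at_enrichment=c_enr, cg_at_p=c_p,
                burden_p=b_p, burden_q=math.nan,
                rpkm_fold_change=expr[0], mean_rpkm_mutated=expr[1], mean_rpkm_unmutated=expr[2],
                mutation_density=dens,
            )
        )
        burden_ps.append(b_p)

    table = pd.DataFrame(rows)
    if genome_bp is not None and len(table):
        table["burden_q"] = benjamini_adjust(burden_ps)
    table = table[table["total_snvs"] >= 1]
    table = table.sort_values(
        ["total_snvs", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def write_feature_table(table: pd.DataFrame, path, decimals: int = 4) -> None:
    """Write the report TSV with 4-decimal rounding (full precision lives in JSON)."""
    out = table[FEATURE_COLUMNS].copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(decimals)
    out.to_csv(path, sep="\t", index=False)
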
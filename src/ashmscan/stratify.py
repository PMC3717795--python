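"""Mutation-rate stratification and TSS-distance density profiles.

Regions are split into mutation-rate groups (I: density > 8e-5 per base per
sample, II: > 4e-5, III: remaining regions with at least two SNVs), with
immunoglobulin loci set aside as a positive control.  For each group the
SNV offsets from the TSS (transcription direction, out to 12 kb) are pooled
into a distance profile; AID-driven groups show an exponentially decaying
profile hugging the TSS while background groups look uniform, and the
profiles are compared with a two-sample Kolmogorov–Smirnov test.

Smoothing (lowess over the binned histogram) affects plots only, never the
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .annotations import SHMTarget
from .somatic import SomaticSNV

__all__ = [
    "GroupAssignment",
    "DistanceProfile",
    "GROUP_IG", "GROUP_I", "GROUP_II", "GROUP_III", "GROUP_UNASSIGNED",
    "assign_groups",
    "tss_distance_profile",
    "compare_distance_distributions",
    "plot_distance_profiles",
]

GROUP_IG = "IG_control"
GROUP_I = "I"
GROUP_II = "II"
GROUP_III = "III"
GROUP_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GroupAssignment:
    gene_symbol: str
    group: str
    mutation_density: float
    n_snvs_total: int


@dataclass
class DistanceProfile:
    """Pooled SNV distances from the TSS for one group."""

    group: str
    distances: np.ndarray
    median_distance: float
    smoothed_density: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)


def assign_groups(
    rows: pd.DataFrame,
    high_threshold: float = 8e-5,
    mid_threshold: float = 4e-5,
    ig_genes: Iterable[str] = (),
    count_thresholds: tuple[int, int] | None = None,
) -> list[GroupAssignment]:
    """Partition regions into IG control / I / II / III / unassigned.

    ``rows`` is a feature table with ``gene``, ``mutation_density`` and
    ``total_snvs`` columns.  Density thresholds are the primary rule;
    ``count_thresholds=(lo, hi)`` switches group II to the SNV-count variant
    (lo..hi SNVs).  IG genes are always IG_control regardless of density.
    Group III requires at least two distinct SNVs; the rest is unassigned.
    """
    if not high_threshold > mid_threshold > 0:
        raise ValueError("need high_threshold > mid_threshold > 0")
    ig = set(ig_genes)
    out = []
    for row in rows.itertuples(index=False):
        dens = float(row.mutation_density)
        n = int(row.total_snvs)
        if row.gene in ig:
            grp = GROUP_IG
        elif count_thresholds is not None:
            lo, hi = count_thresholds
            if dens > high_threshold:
                grp = GROUP_I
            elif lo <= n <= hi:
                grp = GROUP_II
            elif n >= 2:
                grp = GROUP_III
            else:
                grp = GROUP_UNASSIGNED
        elif dens > high_threshold:
            grp = GROUP_I
        elif dens > mid_threshold:
            grp = GROUP_II
        elif n >= 2:
            grp = GROUP_III
        else:
            grp = GROUP_UNASSIGNED
        out.append(GroupAssignment(row.gene, grp, dens, n))
    return out


def tss_distance_profile(
    snvs: Sequence[SomaticSNV],
    targets: Sequence[SHMTarget],
    groups: Sequence[GroupAssignment],
    profile_window: int = 12000,
    bin_bp: int = 250,
    span: float = 0.3,
) -> dict[str, DistanceProfile]:
    """Pool per-group SNV distances to the TSS over ``profile_window`` bases.

    Distances are transcription-direction offsets (downstream positive) from
    each group gene's TSS; an SNV on the gene's contig within the window
    contributes one distance.  The smoothed density is a lowess fit over the
    binned histogram and is for display only.
    """
    group_of = {g.gene_symbol: g.group for g in groups}
    by_chrom: dict[str, list[SomaticSNV]] = {}
    for s in snvs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.pos)
    positions = {c: np.array([s.pos for s in lst]) for c, lst in by_chrom.items()}

    pooled: dict[str, list[int]] = {}
    for t in targets:
        grp = group_of.get(t.gene_symbol)
        if grp is None:
            continue
        tss = t.start if t.strand == "+" else t.end
        lo, hi = (tss, tss + profile_window) if t.strand == "+" else (tss - profile_window, tss)
        pos = positions.get(t.chrom)
        if pos is None:
            continue
        i0, i1 = np.searchsorted(pos, [lo, hi])
        for p in pos[i0:i1]:
            d = p - tss if t.strand == "+" else tss - p
            if 0 <= d <= profile_window:
                pooled.setdefault(grp, []).append(int(d))

    profiles: dict[str, DistanceProfile] = {}
    for grp, dists in pooled.items():
        arr = np.asarray(sorted(dists), dtype=float)
        smoothed = _smooth_histogram(arr, profile_window, bin_bp, span)
        profiles[grp] = DistanceProfile(grp, arr, float(np.median(arr)), smoothed)
    return profiles


def _smooth_histogram(distances: np.ndarray, window: int, bin_bp: int, span: float):
    edges = np.arange(0, window + bin_bp, bin_bp)
    counts, _ = np.histogram(distances, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    density = counts / max(len(distances), 1) / bin_bp
    if len(centers) < 5 or len(distances) == 0:
        return centers, density
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(density, centers, frac=span, return_sorted=False)
    return centers, np.clip(fitted, 0.0, None)


def compare_distance_distributions(a: DistanceProfile, b: DistanceProfile):
    """Two-sample KS statistic and p-value between two distance profiles.

    Exact small-sample p when both groups have <= 100 distances, else the
    asymptotic p.
    """
    if len(a.distances) == 0 or len(b.distances) == 0:
        raise ValueError("both profiles must be non-empty")
    method = "exact" if (len(a.distances) <= 100 and len(b.distances) <= 100) else "asymp"
    res = _sps.ks_2samp(a.distances, b.distances, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def plot_distance_profiles(profiles: Mapping[str, DistanceProfile], path) -> None:
    """Small-multiple density plot with a median marker per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [g for g in (GROUP_IG, GROUP_I, GROUP_II, GROUP_III, GROUP_UNASSIGNED) if g in profiles]
    fig, axes = plt.subplots(len(order), 1, figsize=(7, 2.2 * max(len(order), 1)), sharex=True)
    if len(order) == 1:
        axes = [axes]
    for ax, grp in zip(axes, order):
        prof = profiles[grp]
        grid, dens = prof.smoothed_density
        ax.fill_between(grid, dens, color="#4878a8", alpha=0.5, step=None)
        ax.axvline(prof.median_distance, color="red", lw=2)
        ax.set_ylabel(f"group {grp}\n(n={len(prof.distances)})", fontsize=8)
    axes[-1].set_xlabel("distance downstream of TSS (bp)")
    fig.suptitle("SNV density vs distance to TSS (red bar: median)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
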
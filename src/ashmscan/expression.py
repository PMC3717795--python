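"""Linking mutation status to mRNA abundance.

SHM requires transcription, so mutated regions are expected to be the more
expressed ones.  Two views are computed: a per-gene normalized fold change
between samples with and without mutations in the gene's SHM-target,

    fold = (mean_RPKM_mutated - mean_RPKM_unmutated)
           / (mean_RPKM_mutated + mean_RPKM_unmutated)   in [-1, 1],

zeroed for genes expressed below an RPKM floor in both groups; and a
cohort-level resampling test comparing the candidate genes' average RPKM
against the averages of equally sized random gene sets drawn from the
expressed universe (RPKM > 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ExpressionTable",
    "ExpressionLinkRow",
    "RandomSetTestResult",
    "read_expression_tsv",
    "compute_rpkm",
    "expression_fold_change",
    "random_set_expression_test",
]


@dataclass
class ExpressionTable:
    """Sample x gene RPKM matrix."""

    rpkm: pd.DataFrame  # rows = samples, columns = genes
    provenance: str = "given_rpkm"

    def __post_init__(self) -> None:
        if (self.rpkm.values < 0).any():
            raise ValueError("RPKM values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.columns)

    def gene_means(self) -> pd.Series:
        return self.rpkm.mean(axis=0)


@dataclass(frozen=True)
class ExpressionLinkRow:
    gene_symbol: str
    mean_rpkm_mutated: float
    mean_rpkm_unmutated: float
    fold_change: float


@dataclass
class RandomSetTestResult:
    candidate_mean: float
    null_means: np.ndarray
    p: float
    p_empirical: float
    effect_size: float
    degenerate: bool = False


def read_expression_tsv(path: str | Path, orientation: str = "auto") -> ExpressionTable:
    """Read an RPKM matrix; orientation auto-detected from the header.

    A first header field naming genes (gene/gene_symbol/symbol) means rows
    are genes; naming samples (sample/sample_id) means rows are samples.
    Unrecognized headers default to rows-are-genes, the common layout.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    first = (table.index.name or "").strip().lower()
    if orientation == "auto":
        if first in ("sample", "sample_id"):
            orientation = "samples_by_genes"
        else:
            orientation = "genes_by_samples"
    if orientation == "genes_by_samples":
        table = table.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionTable(table.astype(float))


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
) -> ExpressionTable:
    """RPKM = count / (gene length in kb x mapped reads in millions).

    ``counts`` is samples x genes; lengths in bases, library sizes in reads.
    """
    lengths = gene_lengths.reindex(counts.columns)
    libs = library_sizes.reindex(counts.index)
    if lengths.isna().any() or libs.isna().any():
        raise ValueError("gene lengths / library sizes do not cover the count matrix")
    if (lengths <= 0).any() or (libs <= 0).any():
        raise ValueError("gene lengths and library sizes must be positive")
    rpkm = counts.div(lengths / 1e3, axis=1).div(libs / 1e6, axis=0)
    return ExpressionTable(rpkm, provenance="computed_from_counts")


def expression_fold_change(
    expr: ExpressionTable,
    gene: str,
    mutated_samples: Iterable[str],
    min_rpkm: float = 5.0,
) -> ExpressionLinkRow:
    """Normalized expression difference between mutated and unmutated samples.

    Zeroed when both group means fall below ``min_rpkm`` (low-expression
    rule) and when either group is empty (means reported missing).
    """
    if gene not in expr.rpkm.columns:
        raise KeyError(f"gene {gene!r} absent from expression table")
    mutated = set(mutated_samples)
    values = expr.rpkm[gene]
    in_mut = values.index.isin(mutated)
    mean_mut = float(values[in_mut].mean()) if in_mut.any() else float("nan")
    mean_unmut = float(values[~in_mut].mean()) if (~in_mut).any() else float("nan")
    if np.isnan(mean_mut) or np.isnan(mean_unmut):
        fold = 0.0
    elif mean_mut < min_rpkm and mean_unmut < min_rpkm:
        fold = 0.0
    elif mean_mut + mean_unmut == 0:
        fold = 0.0
    else:
        fold = (mean_mut - mean_unmut) / (mean_mut + mean_unmut)
    return ExpressionLinkRow(gene, mean_mut, mean_unmut, fold)


def random_set_expression_test(
    candidate_genes: Iterable[str],
    expr: ExpressionTable,
    min_rpkm_universe: float = 1.0,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RandomSetTestResult:
    """Resampling test: is the candidate genes' average RPKM unusually high?

    Null sets of size k = |candidates| are drawn without replacement from
    the genes with mean RPKM above ``min_rpkm_universe``.  ``p`` is the
    one-sided (greater) location test of the candidate mean against the
    null-draw means (one-sample t construction on the null distribution);
    ``p_empirical`` is the add-one resampling p.  ``effect_size`` is the
    candidate mean minus the null mean in null standard deviations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = sorted(set(candidate_genes))
    means = expr.gene_means()
    universe = means[means > min_rpkm_universe]
    k = len(candidates)
    if k == 0:
        raise ValueError("empty candidate set")
    if len(universe) <= k:
        raise ValueError("expressed universe is not larger than the candidate set")
    missing = [g for g in candidates if g not in means.index]
    if missing:
        raise KeyError(f"candidate genes absent from expression table: {missing[:5]}")
    candidate_mean = float(means[candidates].mean())
    names = universe.index.to_numpy()
    null_means = np.empty(n_draws)
    for i in range(n_draws):
        draw = rng.choice(names, size=k, replace=False)
        null_means[i] = float(universe[draw].mean())
    degenerate = n_draws < 2
    if degenerate:
        p = float("nan")
    else:
        # Candidate mean above the null distribution => small p.
        p = float(_sps.ttest_1samp(null_means, candidate_mean, alternative="less").pvalue)
    p_emp = (1.0 + float(np.sum(null_means >= candidate_mean))) / (n_draws + 1.0)
    sd = float(null_means.std(ddof=1)) if n_draws > 1 else float("nan")
    effect = (candidate_mean - float(null_means.mean())) / sd if sd and sd > 0 else float("nan")
    return RandomSetTestResult(candidate_mean, null_means, p, p_emp, effect, degenerate)
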
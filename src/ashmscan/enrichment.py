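"""Gene-set overlap enrichment and molecular-subtype association.

Candidate aSHM targets are screened against user-supplied gene lists
(cancer genes, lymphoma genes, ...) with a hypergeometric upper-tail test
over an explicit universe, and each gene's mutated-sample set is tested for
association with cohort subtype labels (e.g. ABC vs GCB) with Fisher's
exact test on the 2x2 mutated x subtype table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as _sps

from ._stats import hypergeom_upper_tail
from .features import benjamini_adjust

__all__ = [
    "GeneSetTest",
    "SubtypeAssociation",
    "gene_set_overlap_test",
    "subtype_association",
    "subtype_association_table",
]


@dataclass(frozen=True)
class GeneSetTest:
    n_candidates: int
    n_set: int
    n_universe: int
    n_overlap: int
    p: float


def gene_set_overlap_test(
    candidates: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> GeneSetTest:
    """Hypergeometric upper-tail test of candidate / gene-set overlap.

    Candidates or set members outside the universe are dropped with a
    warning before testing.
    """
    uni = set(universe)
    cand = set(candidates)
    gset = set(gene_set)
    dropped = (cand - uni) | (gset - uni)
    if dropped:
        warnings.warn(f"{len(dropped)} genes outside the universe dropped from overlap test")
    cand &= uni
    gset &= uni
    overlap = len(cand & gset)
    p = hypergeom_upper_tail(overlap, len(uni), len(gset), len(cand))
    return GeneSetTest(len(cand), len(gset), len(uni), overlap, p)


@dataclass(frozen=True)
class SubtypeAssociation:
    gene_symbol: str
    mutated_by_subtype: dict
    unmutated_by_subtype: dict
    p_one_sided: float
    p_two_sided: float


def subtype_association(
    gene: str,
    mutated_samples: Iterable[str],
    subtype_labels: Mapping[str, str],
    subtypes: tuple[str, str] = ("ABC", "GCB"),
) -> SubtypeAssociation:
    """Fisher's exact test of mutation status against a two-level subtype.

    Samples with labels outside ``subtypes`` (e.g. unknown) are excluded
    from the 2x2.  One-sided p tests enrichment of mutations in the second
    subtype level; the two-sided p is reported alongside.
    """
    a, b = subtypes
    mutated = set(mutated_samples)
    cells = {a: [0, 0], b: [0, 0]}  # [mutated, unmutated]
    for sample, label in subtype_labels.items():
        if label not in cells:
            continue
        cells[label][0 if sample in mutated else 1] += 1
    table = [[cells[b][0], cells[b][1]], [cells[a][0], cells[a][1]]]
    _, p_two = _sps.fisher_exact(table, alternative="two-sided")
    _, p_one = _sps.fisher_exact(table, alternative="greater")
    return SubtypeAssociation(
        gene,
        {a: cells[a][0], b: cells[b][0]},
        {a: cells[a][1], b: cells[b][1]},
        float(p_one),
        float(p_two),
    )


def subtype_association_table(
    mutated_by_gene: Mapping[str, Iterable[str]],
    subtype_labels: Mapping[str, str],
    subtypes: tuple[str, str] = ("ABC", "GCB"),
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-gene subtype association with optional Benjamini adjustment."""
    rows = []
    for gene in sorted(mutated_by_gene):
        assoc = subtype_association(gene, mutated_by_gene[gene], subtype_labels, subtypes)
        rows.append(
            dict(
                gene=gene,
                **{f"mutated_{k}": v for k, v in assoc.mutated_by_subtype.items()},
                **{f"unmutated_{k}": v for k, v in assoc.unmutated_by_subtype.items()},
                p_one_sided=assoc.p_one_sided,
                p_two_sided=assoc.p_two_sided,
            )
        )
    table = pd.DataFrame(rows)
    if adjust and len(table):
        table["q_two_sided"] = benjamini_adjust(list(table["p_two_sided"]))
    return table
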
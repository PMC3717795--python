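"""Co-occurrence of SHM-target mutations and genomic rearrangements.

Rearrangement events (translocations, inversions) arrive as BEDPE-like
records; an event touches a gene when either breakpoint falls within the
gene's SHM-target window extended by a flank (default 100 kb, capturing
promoter-region translocation partners).  Per gene, the cohort is
cross-tabulated into samples with both mutations and rearrangements,
mutations only, and neither — the published presentation omits the
rearrangement-only cell, and so does this table (the counts still
partition the cohort when that cell is added back).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import SHMTarget

__all__ = [
    "RearrangementEvent",
    "GeneRearrangementRow",
    "read_rearrangements",
    "assign_events_to_genes",
    "mutation_rearrangement_table",
]

_EVENT_CLASSES = ("translocation", "inversion", "other")


@dataclass(frozen=True)
class RearrangementEvent:
    sample_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    event_class: str = "translocation"

    def __post_init__(self) -> None:
        if self.event_class not in _EVENT_CLASSES:
            raise ValueError(f"event_class must be one of {_EVENT_CLASSES}")
        if self.chrom_a == self.chrom_b and self.pos_a == self.pos_b:
            raise ValueError("breakpoints coincide")


def read_rearrangements(path: str | Path) -> list[RearrangementEvent]:
    """Read events from BEDPE (6+ cols, sample in col 7) or a headered TSV.

    TSV columns: sample, chromA, posA, chromB, posB[, class].
    """
    path = Path(path)
    events: list[RearrangementEvent] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if fields and fields[0].lower() in ("sample", "sample_id"):
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5 or not parts[0]:
                    continue
                cls = parts[5] if len(parts) > 5 and parts[5] else "translocation"
                events.append(RearrangementEvent(parts[0], parts[1], int(parts[2]), parts[3], int(parts[4]), cls))
        else:
            lines = ([header] if header and not header.startswith("#") else []) + [l.rstrip("\n") for l in fh]
            for line in lines:
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 7:
                    raise ValueError(f"{path}: BEDPE record needs >= 7 columns (name column carries the sample)")
                chrom_a, start_a, _end_a, chrom_b, start_b, _end_b, sample = parts[:7]
                cls = parts[10] if len(parts) > 10 and parts[10] in _EVENT_CLASSES else "translocation"
                events.append(RearrangementEvent(sample, chrom_a, int(start_a), chrom_b, int(start_b), cls))
    return events


def assign_events_to_genes(
    events: Iterable[RearrangementEvent],
    targets: Sequence[SHMTarget],
    flank_bp: int = 100_000,
) -> dict[str, set[str]]:
    """Map gene -> samples with a breakpoint near the gene's SHM-target.

    "Near" is the window extended by ``flank_bp`` on both sides, half-open:
    a breakpoint exactly at end + flank_bp is outside.  Events are
    deduplicated on (sample, breakpoints); an inter-chromosomal event can
    touch genes through either breakpoint.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    seen = set()
    unique: list[RearrangementEvent] = []
    for e in events:
        key = (e.sample_id, e.chrom_a, e.pos_a, e.chrom_b, e.pos_b)
        if key not in seen:
            seen.add(key)
            unique.append(e)
    hits: dict[str, set[str]] = {t.gene_symbol: set() for t in targets}
    for t in targets:
        lo = max(0, t.start - flank_bp)
        hi = t.end + flank_bp
        for e in unique:
            if (e.chrom_a == t.chrom and lo <= e.pos_a < hi) or (e.chrom_b == t.chrom and lo <= e.pos_b < hi):
                hits[t.gene_symbol].add(e.sample_id)
    return hits


@dataclass(frozen=True)
class GeneRearrangementRow:
    gene_symbol: str
    n_mut_and_rearr: int
    n_mut_only: int
    n_neither: int


def mutation_rearrangement_table(
    mutated_samples: Mapping[str, set[str]],
    rearranged_samples: Mapping[str, set[str]],
    cohort: Sequence[str],
) -> pd.DataFrame:
    """Per-gene cross-tab of mutation and rearrangement status.

    For each gene: samples with both, with mutations only, and with neither
    mutation nor rearrangement; the implicit rearrangement-only cell makes
    the four counts sum to the cohort size.
    """
    cohort_set = set(cohort)
    rows = []
    for gene in sorted(mutated_samples):
        mut = set(mutated_samples[gene]) & cohort_set
        rearr = set(rearranged_samples.get(gene, set())) & cohort_set
        both = len(mut & rearr)
        mut_only = len(mut - rearr)
        neither = len(cohort_set - mut - rearr)
        rows.append(GeneRearrangementRow(gene, both, mut_only, neither))
    return pd.DataFrame(
        [(r.gene_symbol, r.n_mut_and_rearr, r.n_mut_only, r.n_neither) for r in rows],
        columns=["gene", "mut_and_rearr", "mut_only", "neither"],
    )
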
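#!/usr/bin/env python
"""Simulate the dlbcl-like synthetic cohort and write it to disk.

40 samples, 500 genes, 10% planted aSHM targets; the full data bundle
(reference FASTA, gene BED12, per-sample tumor VCFs + matched-normal site
lists, population sites, RPKM matrix, rearrangement events, truth labels)
lands under scratch/cohort for the downstream drivers.
"""

import json
from pathlib import Path

from ashmscan.simulate import SyntheticCohortConfig, generate, write_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    config = SyntheticCohortConfig(seed=SEED)
    cohort = generate(config)
    write_cohort(cohort, COHORT_DIR)

    n_calls = sum(len(v) for v in cohort.tumor_calls.values())
    summary = {
        "seed": SEED,
        "n_samples": config.n_samples,
        "n_genes": config.n_genes,
        "genome_bp": cohort.reference.genome_bp,
        "n_ashm_genes": len(cohort.truth["ashm_genes"]),
        "n_tumor_calls": n_calls,
        "n_population_sites": len(cohort.population),
        "n_rearrangements": len(cohort.rearrangements),
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"cohort written to {COHORT_DIR}")
    for key, value in summary.items():
        print(f"  {key}: {value}")


if __name__ == "__main__":
    main()
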
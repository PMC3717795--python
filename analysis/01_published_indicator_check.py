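#!/usr/bin/env python
"""Validate the SHM-indicator arithmetic against the published feature table.

Recomputes every recomputable row's indicator as the geometric mean of its
three printed exact-test p-values and writes the comparison, plus the
census of regions with indicator < 0.1.
"""

import json
from pathlib import Path

from ashmscan.published import indicator_census, recompute_indicators

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = recompute_indicators()
    out = table[["gene", "shm_indicator", "recomputed_indicator", "abs_diff"]]
    out.to_csv(RESULTS / "published_indicator_check.tsv", sep="\t", index=False, float_format="%.6f")

    recomputable = out.dropna(subset=["recomputed_indicator"])
    n_exact = int((recomputable["abs_diff"] <= 5e-4).sum())
    n_below, fraction = indicator_census(threshold=0.1)
    summary = {
        "n_rows": len(out),
        "n_recomputable": len(recomputable),
        "n_within_5e-4_of_printed": n_exact,
        "max_abs_diff": float(recomputable["abs_diff"].max()),
        "n_indicator_below_0.1": n_below,
        "fraction_below_0.1": fraction,
    }
    with open(RESULTS / "published_indicator_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    print(f"{len(recomputable)}/{len(out)} rows have all three p-values recoverable from print;")
    print(f"{n_exact} of them reproduce the printed indicator within 5e-4 "
          f"(max |diff| {summary['max_abs_diff']:.4f}, driven by 2-decimal p rounding).")
    print(f"{n_below}/{len(out)} regions ({fraction:.1%}) have SHM indicator < 0.1.")


if __name__ == "__main__":
    main()
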
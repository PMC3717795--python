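# ashmscan

Genome-wide discovery of **aberrant somatic hypermutation (aSHM) targets**
in B-cell lymphoma cohorts, for researchers working with tumor /
matched-normal variant calls (e.g. DLBCL whole genomes).

AID-driven somatic hypermutation leaves a recognizable signature in the
2 kb downstream of a gene's transcription start site (TSS): an elevated
mutation rate decaying with distance from the TSS, concentration at the
WRCY/RGYW hotspot motif (W = A/T, R = A/G, Y = C/T), excess mutations at
C:G pairs, and a transition fraction above the uniform expectation of 1/3.
`ashmscan` pools a cohort's somatic SNVs over per-gene windows
`[TSS, TSS + 2000)` and scores each window with exact one-sided binomial
tests corrected for the window's base composition:

- motif bias: `k_motif ~ Bin(n, f_motif)` where `f_motif` is the fraction of
  window bases covered by a WRCY/RGYW match,
- C:G bias: `k_CG ~ Bin(n, f_CG)`,
- transition bias: `k_Ti ~ Bin(n, 1/3)`,
- region burden: `n ~ Bin(N_genome, w/G)`, Benjamini–Hochberg corrected
  across regions.

Each region's **SHM indicator** is the geometric mean
`(p_motif · p_CG · p_Ti)^(1/3)` — low values flag windows whose mutations
look AID-made. Around the core statistic the package provides somatic
filtering (matched-normal / population-site subtraction, quality >= 20,
alt-read fraction >= 20%), mutation-rate stratification with 12 kb
TSS-distance profiles and KS comparisons, expression linkage (normalized
RPKM fold change between mutated and unmutated samples, random-gene-set
resampling test), rearrangement cross-tabulation, gene-set overlap and
subtype association tests, and a synthetic-cohort generator that emulates
the AID process end to end.

## Worked example

Simulate a DLBCL-like cohort (40 samples, 500 genes, 10% planted aSHM
targets, seed 0) and scan it:

```sh
python analysis/02_simulate_cohort.py
python analysis/03_scan_features.py
```

which prints:

```
123 regions with >=1 somatic SNV (470 SNVs after filtering)
planted aSHM genes in top 50 of the sort: 100%
median SHM indicator of planted genes: 0.0897
 gene  shm_indicator  total_snvs  mutated_samples  motif_enrichment  motif_p
G0390       0.010433          17               15          3.203262 0.000083
G0148       0.011975          12                9          3.516174 0.000023
...
```

Reading the top row: gene `G0390` accumulated 17 somatic SNVs across 15 of
40 tumors in its 2 kb window; mutations sit at WRCY/RGYW-covered bases 3.2x
more often than the window's base composition predicts (exact p = 8.3e-5),
and the composite SHM indicator 0.010 ranks it among the strongest
candidates. All 50 planted aSHM genes land in the top decile of the sort,
and their median indicator is below 0.1 — the regime reported for true
aSHM targets. The remaining drivers stratify regions by mutation rate and
compare TSS-distance distributions (`04`), link mutation status to
expression (`05`), and cross-tabulate mutations with rearrangements (`06`);
each writes its tables under `results/`.

The same pipeline runs from the shell on any cohort:

```sh
ashmscan scan --vcf-dir vcfs/ --genes genes.bed --ref genome.fa \
    --population 1kg_sites.tsv --expr rpkm.tsv --sv events.tsv --out out/
```

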
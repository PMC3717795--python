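# Methods

## Background and model

Somatic hypermutation (SHM) is the AID-initiated mutagenesis that diversifies
immunoglobulin variable regions in germinal-center B cells. When the process
mis-targets other loci (aberrant SHM, aSHM) it leaves a recognizable scar in
the 2 kb downstream of a gene's transcription start site (TSS): an elevated
point-mutation rate whose per-base probability decays roughly exponentially
with distance from the TSS, concentration at the WRCY hotspot motif and its
reverse complement RGYW (W = A/T, R = A/G, Y = C/T), an excess of mutations at
C:G base pairs, and a transition fraction above the 1/3 expected from uniform
substitution. `ashmscan` scores per-gene windows for exactly these hallmarks
over a cohort of tumor genomes.

The unit of analysis is the **SHM-target**: the half-open window
`[TSS, TSS + w)` in transcription direction, `w` = 2000 bp by default. SHM
activity is sometimes described as starting ~150 nt downstream of the TSS; no
offset is applied because the analyzed region in the cohort literature is the
full 2 kb window. With multiple transcripts per gene, the default `per_gene`
collapse anchors the window at the most upstream TSS in transcription
direction (maximal shared promoter-proximal coverage; ties broken by
transcript id); a `per_transcript` mode is available since the published
region count (~46,000) suggests per-transcript analysis is also meaningful.

## Somatic filtering

Tumor calls are reduced to putative somatic SNVs by exact-site subtraction of
the matched normal and a population panel, call quality >= 20, and an
alternate-allele fraction >= 0.20 among reads with mapping quality > 25 and
base quality > 10. The read-level fraction is consumed as a precomputed
column (`AFHQ` in VCF INFO): alignment-level review is upstream of this
package. Multi-allelic records are decomposed first; only single-base
substitutions are kept.

## Signature statistics

Every test is an exact one-sided binomial upper tail with a
composition-derived success rate — the construction "assign a success rate,
plug in the trial count" that the cohort literature calls a Fisher exact
test:

* **Motif bias** — trials: the region's pooled SNV count `n`; successes: SNVs
  at motif-covered bases; rate: the fraction `f_m` of window bases covered by
  at least one WRCY/RGYW match (coverage is per-base, matching a per-base
  normalization). Enrichment `= k / (f_m n)`.
* **C:G bias** — rate is the window's C+G base fraction `f_cg`; enrichment
  `= k_cg / (f_cg n)`.
* **Transition bias** — rate 1/3: uniform substitution offers one transition
  among three alternate alleles regardless of composition. The ratio Ti/Tv is
  reported raw; the cohort literature's "normalized" printed Ti/Tv values are
  not derivable from any stated recipe and are not reproduced.
* **Region burden** — trials: the cohort's genome-wide somatic SNV count;
  rate: `w / G` (window over genome length); Benjamini–Hochberg corrected
  across all analyzed regions (zero-SNV regions included at p = 1). A
  hypergeometric variant (`family="hypergeometric"`) conditions on the
  genome-wide count as a fixed draw.

Upper tails are used throughout because aSHM predicts excess in every tested
direction. Reported p-values are capped at 0.5 (`cap_at_half`, default on):
depleted regions print 0.5, the convention of the published feature tables.
The cap is presentation only — calibration properties hold for the uncapped
tails, and the cap breaks super-uniformity only above 0.5.

The **SHM indicator** of a region is the geometric mean of the three
signature p-values, computed in log space at full precision (printed tables
round to 4 decimals). Lower is more SHM-like; a region with no evidence in
any direction scores 0.5 under the cap convention.

## Stratification and distance profiles

Regions are grouped by cohort mutation density (mean over all samples of
per-sample count / window length): group I > 8e-5 /bp/sample, group II
> 4e-5, group III the remaining regions with >= 2 SNVs; immunoglobulin loci
from a user list are held out as a positive control. The density thresholds
are the primary rule (they are the quantitative record in the emulated
study); a count-based group II (3–5 SNVs) is available via
`count_thresholds`. Distance profiles pool each group's SNV offsets from the
TSS over 12 kb downstream; groups are compared with the two-sample
Kolmogorov–Smirnov test (exact p when both n <= 100). Lowess smoothing
(span 0.3, 250 bp bins) is applied to plots only.

## Expression linkage

Per gene, the cohort splits into samples with >= 1 somatic SNV in the
gene's window vs the rest; the normalized fold change
`(m_mut - m_unmut) / (m_mut + m_unmut)` lies in [-1, 1] and is set to 0 when
both group means are below 5 RPKM (the low-expression rule; gene-level, both
groups, since the rule is about the gene being expressed at all). The
random-set test draws size-k gene sets from the expressed universe
(mean RPKM > 1), and compares the candidate genes' mean RPKM against the
null-draw means: `p` from a one-sample t construction on the null
distribution (the emulated study reports "a T-test"), `p_empirical` as the
add-one resampling tail. `n_draws = 1` is flagged degenerate.

## Synthetic cohorts

The generator produces the entire data bundle (reference FASTA, gene models,
per-sample tumor VCFs, matched-normal and population site sets, RPKM matrix,
rearrangement events, truth labels), deterministic under `(seed, config)`.

The **dlbcl-like** preset encodes the study conditions being emulated:

| parameter | default | rationale |
|---|---|---|
| `n_samples` / `n_genes` | 40 / 500 | cohort size of the emulated study; 500 regions keep a scan under a minute |
| `background_rate` | 2e-6 /bp/sample | a few thousand somatic SNVs per lymphoma genome |
| `ashm_rate_multiplier` | 50 | in-window rate 1e-4, the group-I regime (IGV SHM ~1e-3, non-IG targets 50–100x lower) |
| `positional_decay_mean` | 700 bp | exponential decay of mutation probability with TSS distance; `None` = uniform |
| `motif_multiplier` | 7.5 | per-base factor at motif-covered bases; calibrated so the *observed* window-level WRCY enrichment is ~3, the group-I value (at motif coverage f ~ 0.22 the observed enrichment r f/(r f + 1 - f)/f saturates well below the per-base factor r) |
| `cg_bias` | 1.5 | realizes observed C:G enrichment ~1.3 |
| `transition_bias` | 0.5 | transition probability per mutation (null 1/3); applied to every simulated substitution, so null cohorts set it to 1/3 |
| `expression_coupling` | 1.0 | per-sample aSHM intensity scales with that sample's RPKM (power law, normalized to mean 1 per gene) |
| `gc_content` | 0.42 | human-like |
| expression baseline | lognormal, median 30, sigma 1.0 | mean RPKM ~= 50, the expressed-gene average of the emulated cohort; sample-level lognormal noise sigma 0.5 |

Genes (6 kb) sit in 16 kb slots, 50 per contig, so the 12 kb profile window
never reaches a neighboring TSS cluster. Placement draws a categorical over
window positions with unnormalized weights `exp(-d/decay) x motif factor x
C:G factor` — simple, exact, auditable. Germline variants (5e-6 /bp, planted
in tumor and matched normal), shared population sites (2e-5 /bp, 30% carrier
rate) and artifact calls below the quality/support thresholds exercise the
somatic filter end to end.

What the generator does **not** emulate: strand asymmetry of A:T mutations,
clonal structure, indels/CNVs, read-level noise, non-uniform genome
composition (CpG islands, replication timing), and any dependence of aSHM
targeting on a gene's *baseline* expression — coupling acts on within-gene,
between-sample variation only. Consequently the random-set expression test
is an expected-null negative control on synthetic cohorts (real group-I
genes are absolutely more expressed than background), and passing tests say
nothing about those axes of real data.

## Numerical and design choices

* Coordinates 0-based half-open everywhere; GTF/VCF converted on read.
* Exact tails via `scipy.stats.binom/hypergeom` survival functions, verified
  against full enumeration to 1e-12 for n <= 25 in the test suite.
* Feature table sorted by total SNVs descending, ties lexicographic by gene;
  only regions with >= 1 SNV are reported (zero rows still enter the BH
  correction of the burden test).
* `n = 0` regions report missing enrichment and p = 1; Ti/Tv with no
  transversions reports an infinite ratio and keeps the exact test defined.
* Rearrangement "vicinity" is the window +- 100 kb (half-open), a default
  wide enough for promoter-partner translocations; configurable.
* The gene-set overlap universe is never defaulted silently in reports; the
  caller must supply it.
* Analysis drivers and the test suite fix seed 0; at the desk scale used
  here (500 regions) group III holds only ~5–13 regions, so the group-I vs
  group-III KS p-value fluctuates across seeds around its typical ~1e-3
  value; the group-size limitation, not the statistic, is the bottleneck.

## Limitations

The scanner consumes variant tables, not alignments; upstream caller
artifacts that survive the numeric filters are indistinguishable from
mutations. The published cohort's headline numbers (44 candidate regions,
group sizes 92/470, KS p < 2.2e-16, RPKM 350 vs 50, 29/44 cancer-gene
overlap) depend on its 40-patient whole-genome dataset and are not
reproducible from simulation; the synthetic checks mirror them
qualitatively at desk scale only.
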
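# ovulemeth

Two-sample whole-genome bisulfite sequencing (WGBS) analysis for plant
methylomes, built around the comparison of a rice female-sterile line
(*fsv1*) with its fertile progenitor (Gui99) during ovule development. The
package takes directional bisulfite reads from FASTQ to context-resolved
methylation calls, genome-element differential methylation, term
enrichment, miRNA-promoter methylation and bisulfite-PCR validation — and
ships a synthetic-study generator that plants known differentially
methylated regions so every stage is testable against ground truth without
any external data.

It is a library first (`import ovulemeth`), with short narrative scripts
under `examples/` and a thin `ovule-methdiff` CLI for running stages from a
shell.

## The model

Sodium bisulfite converts unmethylated cytosine to uracil (read as T) and
leaves 5-methylcytosine intact, so a C in a read over a reference cytosine
is a methylated call and a T an unmethylated call. Every reference
cytosine is classified by the two bases 3′ of it on its own strand into
the three plant contexts **CG**, **CHG**, **CHH** (H = A, T or C). Reads
contribute only to cytosines of their strand of origin.

Per site, with m methylated and u unmethylated calls, the methylation
ratio is m/(m+u); a covered site is *called* methylated by a one-sided
binomial test of m against the conversion-failure rate (estimated from an
unmethylated spike-in control), BH-corrected across sites.

Per genome element (promoter = TSS−2200..+500 with proximal/intermediate/
distal subregions, exon, intron, 1-kb intergenic tile), the read calls of
the two samples are pooled into a 2×2 table and tested with Pearson's
χ² (df = 1, no continuity correction; Fisher's exact test for sparse
tables). With one genome-wide Benjamini–Hochberg family, an element is a
**DMR** iff

```
q ≤ 0.001   and   max(r̃_A/r̃_B, r̃_B/r̃_A) ≥ 2.0,   r̃ = (m + 0.5)/(m + u + 1)
```

hyper when the sample of interest has the larger ratio. A gene with ≥ 1
DMR in its promoter, exon or intron is a **DMG**. DMGs are tested for term
enrichment against the genome background with the hypergeometric upper
tail P(X ≥ k) and clustered by average linkage on 1 − Pearson distance of
log2-transformed ratios. miRNA promoters (same window, anchored at the
pre-miRNA 5′ end) get a two-tier label: `**` for |log2 fold-change| ≥ 1
and P < 0.01, `*` for |log2 fold-change| ≥ 1 and 0.01 < P < 0.05.
Bisulfite-PCR clones are tallied per site as
100 · (#clones reading C)/(#informative clones), pooled per context.

Promoter CpG classes (HCP/ICP/LCP) use 500-bp windows of CpG
observed/expected = (#CpG · L)/(#C · #G); CpG islands use the
Gardiner-Garden–Frommer rule (≥ 200 bp, GC ≥ 0.50, obs/exp ≥ 0.60) with
2-kb shores.

## Worked example

`python examples/05_full_pipeline.py` simulates a 2-chromosome study
(60 kb per chromosome, 12× coverage, 8 planted DMRs) and runs every stage:

```
--- mapping table ---
sample  raw_reads  clean_reads  mapped_reads mapping_rate_pct  unique_reads unique_rate_pct conversion_rate_pct
  fsv1      14400        14400         14119            98.05         14119           98.05               99.48
 Gui99      14400        14400         14086            97.82         14086           97.82               99.52

--- headline counts ---
planted_dmrs: 8
testable_elements: 183
n_dmrs: 22
n_dmgs: 6
```

The mapping table mirrors a WGBS run report: rates are mapped/clean and
unique/clean as percentages (half-up, 2 decimals), and the conversion rate
comes from the unmethylated control (>99%, as a good library should).
The 22 called DMRs comprise the 8 planted elements plus overlapping
elements (e.g. the first exon inside a planted promoter window) that are
genuinely shifted; `examples/02_call_dmrs_against_planted_truth.py` shows
that calls outside any planted window are (near) zero. Other examples
demonstrate methylation calling and Table-style summaries (01), planted
term enrichment and profile clustering (03), and miRNA-promoter labels,
coherence triples and BSP clone analysis (04).

The same run from a shell:

```sh
ovule-methdiff run --outdir run_demo --seed 1
```

Individual stages (`simulate`, `align`, `call`, `annotate`, `dmr`,
`enrich`, `cluster`, `mirna`, `bsp`, `report`) are exposed as subcommands
over the standard formats (FASTA/FASTQ/SAM/GFF3/BED/bedGraph/TSV).

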
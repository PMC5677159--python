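# Methods

This note documents the models, conventions and design choices behind
`ovulemeth`, in the order the pipeline runs them, and states what the
synthetic data do and do not emulate.

## Scope and coordinates

The package analyses a two-sample directional WGBS design (sample of
interest vs reference; defaults named *fsv1* and Gui99 after the rice
ovule study design it follows). All internal coordinates are 0-based
half-open; GFF3 is converted at the boundary (1-based inclusive on disk),
BED/bedGraph are written 0-based half-open. Single-end reads only;
replicates are assumed pooled into one library per sample (the optional
`n_replicates` field exists for bookkeeping but the generator emits one
pooled library, matching the pooled-library design).

## Synthetic study generator (`simdata`)

The generator's defaults define the study conditions, not a tuning
surface:

- **Genome** — 3 chromosomes × 120 kb of i.i.d. sequence at GC 0.44, with
  3 planted CpG-island segments per chromosome (400 bp, CG-dinucleotide
  rate 0.30, GC 0.65) that satisfy the island rule by construction.
  The background is deliberately *not* CpG-depleted: plant genomes show
  little CpG depletion, and an i.i.d. background preserves the observed
  per-chromosome context-count ordering CHH > CG > CHG. The cost is that
  a Gardiner-Garden–Frommer scan also flags short high-GC background
  segments beyond the planted islands; recovery tests therefore assert
  that planted islands are found (reciprocal overlap ≥ 0.8), not that
  nothing else is.
- **Annotation** — 8 genes (3 exons of 200 bp, introns of 150 bp) and 4
  single-exon pre-miRNA loci (120 bp) per chromosome, strands random,
  placed on an evenly strided grid with jitter so gene bodies never
  overlap and every promoter window (−2200..+500) fits inside the
  chromosome. Promoter windows of neighbouring genes may overlap — as in
  real genomes, elements are independent intervals, not a partition.
- **Methylome** — per-site methylation probabilities are
  Beta(μc, (1−μ)c) with c = 0.5 and per-context means μ of
  CG 0.40, CHG 0.32, CHH 0.14 (the whole-genome context levels typical of
  rice ovules). The small concentration gives the U-shaped (bimodal)
  per-site distribution real methylomes show while keeping the
  sample-wide mean exactly μ. Both samples share one baseline; planted
  DMR elements get constant levels (default 0.8 vs 0.2, hyper = interest
  high), so the truth fold-change inside a planted element is exactly 4
  and every unplanted element is a true null. Planted elements are chosen
  disjoint.
- **Reads** — Lister-style directional protocol: reads drawn uniformly
  from both genome strands at 30× default coverage, 100 bp. At each
  cytosine of the read's origin strand the emitted base is C with
  probability p + (1−p)·f (f = conversion failure, default 0.005,
  matching a >99% conversion library) and T otherwise; independent
  substitution errors at 0.001. A 10-kb unmethylated spike-in control
  (the conversion-rate substrate) is simulated at 50×. Read names encode
  the true origin for alignment-recovery tests. Every generator is a
  pure function of (config, seed); one master seed fans out to fixed
  per-stage streams.

What the simulation does **not** emulate: real rice sequence composition
(repeats, transposons, chromosome-scale methylation gradients), quality
score profiles and machine error modes, PCR duplicates, paired ends, or
biological replicate variance. Passing tests therefore demonstrate the
correctness of the algorithms under the stated sampling model, not
performance on real libraries.

## Read QC and alignment (`seqio`)

QC drops reads with N-fraction > 0.10 or mean Phred < 20 and trims an
exact 3′ match (≥ 8 bp) to an adapter prefix. The aligner is a
deliberately simple bisulfite-aware unique mapper standing in for a
production tool: read and both genome strands are reduced to a
three-letter alphabet (C→T on the respective sense), candidates found by
exact match of the first 24 reduced bases, scored by Hamming distance
(≤ 4), and a read is *unique* iff exactly one best locus exists — ties are
kept but flagged non-unique, and only unique alignments flow downstream.
No indels. Because the seed must match exactly, a substitution error in
the first 24 bases drops the read; at the default error rate this costs
~2% of reads, visible in the mapping-rate table. SAM import accepts an
external aligner's output, keeping primary records with MAPQ ≥ 20 as the
uniqueness surrogate. Mapping and unique rates are mapped/clean and
unique/clean; report percents are rounded half-up to 2 decimals.

## Methylation calling (`methcall`)

Context classification follows the strand-local rule (CG; CHG = C-H-G;
CHH = C-H-H; H = A/T/C); a cytosine with an N in its context or fewer
than the needed downstream bases is unclassifiable (a terminal C followed
by G still counts as CG, since CG needs only one downstream base). Pileup
credits C reads as methylated and T reads as unmethylated calls at
cytosines of the read's origin strand; other bases are ignored.

Whether a site *is* methylated is not stated by the upstream study design,
so the rule here is explicit and configurable: coverage ≥ 4, one-sided
binomial test of the methylated count against the conversion-failure rate
(1 − estimated conversion), BH across all tested sites, q < 0.05 ⇒
methylated. The conversion rate is unmethylated calls / all calls on the
control.

The whole-genome summary reproduces the per-chromosome × context layout
with a totals row whose **counts are column sums and whose percents are
unweighted means of the per-chromosome percents** — recomputing the
published reference table confirms this is the convention its totals row
uses (the pooled ratio would give 22.54/40.38 where the table prints
22.56/40.57); the pooled convention is available via
`summarize(..., totals="pooled")`. Note the fraction of sites *called*
methylated generally exceeds the mean site probability: with a U-shaped
probability distribution, intermediate sites with p well below 1 still
reject the conversion-failure null at moderate coverage.

## Genome elements (`elements`)

Promoters span TSS−2200..+500 (2700 bp) with P = −200..+500,
I = −1000..−200, D = −2200..−1000; minus-strand windows mirror the span
([TSS−500, TSS+2200)), keeping subregion lengths 700/800/1200. CpG
classes use 500-bp windows, step 5: HCP if any window has GC ≥ 0.55 and
CpG obs/exp ≥ 0.75; LCP if no window reaches obs/exp 0.48; else ICP
(a Weber-style convention; all four numbers configurable). CpG islands
use Gardiner-Garden–Frommer (200-bp windows, GC ≥ 0.50, obs/exp ≥ 0.60,
overlapping qualifying windows merged); Takai–Jones-like behaviour is a
matter of overriding those thresholds. Shores are ≤ 2-kb flanks clipped
at chromosome ends and neighbouring islands; on double overlap an element
is labelled island, not shore. Intergenic space (outside gene bodies and
promoters) is tiled at 1 kb, final partial tile kept if ≥ 200 bp. Exon
and intron ranks are 1-based in transcription order so first-exon /
first-intron queries work on either strand.

## Differential methylation (`dmr`)

The 2×2 test uses **read-call counts** (methylated vs unmethylated calls
summed over the element's cytosines, both strands, contexts pooled):
read counts carry coverage information that site counts discard; a
site-count mode and per-context aggregation exist behind flags. Elements
need ≥ 5 covered cytosines and ≥ 20 read calls per sample to be testable.
Pearson χ² without continuity correction (df = 1); any expected cell < 5
falls back to two-sided Fisher (flagged); a zero marginal is degenerate
(statistic 0, p 1). One BH family spans all testable elements of all
types. Fold-change uses Haldane-smoothed ratios r̃ = (m+0.5)/(m+u+1) so a
zero ratio stays defined; when *both* samples have zero methylated calls
the smoothed quotient is a pure coverage artifact, so the fold is pinned
to 1 and the element can never be a DMR. DMR ⇔ q ≤ 0.001 and fold ≥ 2.
Gene direction is the majority of its DMR directions, ties = "mixed".

## Enrichment and clustering (`enrich`)

Hypergeometric upper tail P(X ≥ k) per term with K ≥ 1 background
carriers and k ≥ 1 DMG carriers; BH across tested terms; default
significance q ≤ 0.05 (a plain p < 0.05 view is a parameter away, as
GO-style figures often use). Term maps are flat gene→term annotations;
no ontology-graph propagation. Clustering transforms ratios as
log2(r + ε), ε = 0.01 (the transform needs a floor at r = 0; 0.01 is two
decades below typical ratios), distance 1 − Pearson r, average linkage
via scipy with its deterministic index-ordered tie-break; zero-variance
profiles get distance 1 to everything and are flagged rather than fatal.
Output is Cluster-3.0-compatible CDT/GTR text plus Newick. The
functional-bin summary counts hyper/hypo DMGs per bin with genes missing
from the bin map reported as unbinned.

## miRNA promoters and BSP (`mirna_bsp`)

miRNA promoters reuse the −2200..+500 scheme anchored at the pre-miRNA 5′
end, and records are keyed by locus so duplicate miRNA names stay
distinct. The label rule is `**` for |log2fc| ≥ 1 and P < 0.01 and `*`
for |log2fc| ≥ 1 and 0.01 < P < 0.05, with log2fc taken on the smoothed
ratio quotient and P from the same χ² machinery as gene DMRs. The
threshold is inclusive at |log2fc| = 1 because the published 84-row
reference table labels three rows with |log2fc| exactly 1 as significant;
the strict open-interval reading is available via `lfc_inclusive=False`.
A boundary P exactly 0.01 satisfies neither tier and is labelled `ns`.
Coherence: hypo promoter & miRNA up & target down (or the mirrored hyper
case) ⇒ coherent; missing expression ⇒ untestable.

BSP clones align gap-free to their amplicon after C→T reduction of both
(primers assumed trimmed); clones over 20% reduced mismatches are
excluded, and optionally clones whose CHH conversion proxy falls below
90% are discarded as conversion failures. Per-site percent is
100·C/(C+T) over informative clones; per-context figures pool that
context's sites. The WGBS comparison pools read calls over the amplicon's
Watson-strand cytosines (the strand BSP assays) and reports per-context
absolute differences plus a sample-ranking agreement flag.

## Pipeline (`pipeline`, `cli`)

Stages run simulate → QC → align → call → annotate → dmr → enrich →
cluster → mirna → bsp → report, every stage writing its outputs (FASTA,
FASTQ, SAM, GFF3, BED, bedGraph, TSV) under the run directory with the
full configuration serialised for provenance. Resume is keyed on
per-stage config hashes in a manifest: unchanged heavy stages (simulate,
align) reload their serialised outputs. With a fixed seed, reruns are
byte-identical (config.yaml differs only by the recorded run path). The
planted truth feeds the downstream fixtures: the enriched term is planted
over the genes that truly carry DMRs, and expression tables are generated
from the planted miRNA-promoter directions (coherent with probability
0.9), so end-to-end recovery is checkable at every stage.

Problem sizes in the shipped defaults (3 × 120 kb genome, 30×;
test configurations use 2 × 60 kb at 12×) were chosen so a complete run
takes well under a minute on one CPU while leaving hundreds of testable
elements and ~10⁵ reads per sample — large enough for the χ² asymptotics
and BH behaviour the tests assert, small enough to iterate on.

## Numerical and degenerate-input choices

- Percent formatting: decimal half-up at 2 decimals (report convention).
- BH step-up implemented directly (q(i) = min over j ≥ i of m·p(j)/j,
  clipped at 1), cross-checked against statsmodels in tests.
- χ² p-values from the χ²₁ survival function; hypergeometric tails from
  scipy's distribution (log-space internally), cross-checked against
  exact enumeration.
- Empty inputs: empty DMG set ⇒ empty enrichment with a warning, not an
  error; zero-coverage control ⇒ explicit insufficient-data error;
  promoters shorter than the CpG window are classified on the full span;
  truncated promoter windows at chromosome ends are clipped and flagged.

## Known limitations

- The aligner is a functional stand-in: no indels, exact-seed sensitivity
  loss at the read 5′ end, no quality-aware scoring; it is not a
  reproduction of any production mapper's scores, and real-data mapping
  rates (~57% unique in the motivating study) are not expected from the
  clean synthetic genome (~98% here).
- No SNP-aware calling, M-bias trimming or duplicate marking.
- Headline biological counts of the motivating study (3471 DMRs, 2348
  DMGs) depend on its real sequencing data and genome and are outside
  what a synthetic desk-scale study can or should reproduce; the package
  validates conventions and algorithms, not those numbers.
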
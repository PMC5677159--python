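"""Simulate a small two-sample bisulfite study and call per-site methylation.

Builds a 2-chromosome synthetic plant genome, simulates directional
bisulfite reads for the sample of interest, aligns them, piles up C/T
calls at every cytosine and prints the per-context methylation summary.
The percents should sit near the configured context means
(CG 0.40, CHG 0.32, CHH 0.14).
"""
from ovulemeth import (BisulfiteAligner, ContextIndex, SimConfig, call_sites,
                       estimate_conversion_rate, pileup, summarize)
from ovulemeth.simdata import (generate_annotation, generate_genome,
                               generate_methylome, make_control,
                               simulate_control_reads, simulate_reads)
from ovulemeth.elements import build_elements

cfg = SimConfig(n_chromosomes=2, chrom_length=60_000, n_genes_per_chrom=5,
                n_mirna_per_chrom=0, coverage=15, dmr_plan=[], seed=1)
genome, _ = generate_genome(cfg)
genes, _ = generate_annotation(genome, cfg)
ctx = ContextIndex(genome)
truth = generate_methylome(genome, build_elements(genes, genome), cfg, ctx)
sample = cfg.samples[0]

reads = simulate_reads(genome, truth.probs[sample], cfg, cfg.rng(101))
aligner = BisulfiteAligner(genome)
alignments, stats = aligner.align(reads)
print(f"{stats.clean} reads, {stats.unique_rate:.2f}% uniquely mapped")

control = make_control(cfg)
ctrl_alns, _ = BisulfiteAligner({"control": control}).align(
    simulate_control_reads(control, cfg, cfg.rng(102)))
conversion = estimate_conversion_rate(
    pileup([a for a in ctrl_alns if a.is_unique], {"control": control}))
print(f"bisulfite conversion rate: {100 * conversion:.2f}%")

counts = pileup([a for a in alignments if a.is_unique], genome)
calls = call_sites(counts, ctx, conversion)
summary = summarize(ctx, calls)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nEach row: cytosine sites and methylated sites per context; the "
      "Total row sums counts and averages the chromosome percents.")
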
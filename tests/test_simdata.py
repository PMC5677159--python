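"""Synthetic-study generator: determinism, composition, truth fidelity."""
import io

import numpy as np
import pytest

from ovulemeth import seqio
from ovulemeth.elements import build_elements
from ovulemeth.methcall import CONTEXTS, ContextIndex, pileup
from ovulemeth.simdata import (ConfigError, DmrPlanEntry, PlanError,
                               SimConfig, generate_annotation,
                               generate_genome, generate_methylome,
                               make_control, simulate_clones, simulate_reads,
                               generate_term_map)


def _small_cfg(**kwargs):
    defaults = dict(n_chromosomes=2, chrom_length=40_000,
                    n_genes_per_chrom=3, n_mirna_per_chrom=2,
                    n_cgi_per_chrom=2, coverage=5, seed=1)
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestConfig:
    def test_invalid_fields_name_the_field(self):
        with pytest.raises(ConfigError, match="gc_fraction"):
            SimConfig(gc_fraction=1.5).validate()
        with pytest.raises(ConfigError, match="coverage"):
            SimConfig(coverage=0).validate()
        with pytest.raises(ConfigError, match="chrom_length"):
            SimConfig(chrom_length=1000).validate()


class TestGenome:
    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        paths = []
        for name in ("a.fa", "b.fa"):
            genome, _ = generate_genome(_small_cfg())
            path = tmp_path / name
            seqio.write_fasta(genome, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_gc_fraction_concentrates_at_large_length(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000_000,
                        gc_fraction=0.5, n_cgi_per_chrom=0, seed=2)
        genome, _ = generate_genome(cfg)
        seq = genome["Chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_requested_number_of_disjoint_truth_islands(self):
        cfg = _small_cfg(n_cgi_per_chrom=3)
        _, truth = generate_genome(cfg)
        for chrom in ("Chr1", "Chr2"):
            ivs = sorted((s, e) for c, s, e in truth if c == chrom)
            assert len(ivs) == 3
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_uppercase_acgt_only(self):
        genome, _ = generate_genome(_small_cfg())
        assert set("".join(genome.values())) <= set("ACGT")

    def test_context_composition_ordering(self):
        """Per chromosome: CHH sites outnumber CG sites outnumber CHG."""
        genome, _ = generate_genome(_small_cfg())
        ci = ContextIndex(genome)
        for chrom in genome:
            n = ci.n_sites(chrom)
            assert n["CHH"] > n["CG"] > n["CHG"]


class TestAnnotation:
    def test_exon_intron_chain(self):
        genes, _ = generate_annotation(*_gen(_small_cfg(exons_per_gene=3)))
        for g in genes:
            assert len(g.exons) == 3
            assert len(g.introns) == 2

    def test_both_strands_present(self):
        genes, mirnas = generate_annotation(*_gen(_small_cfg()))
        strands = {g.strand for g in genes} | {m.strand for m in mirnas}
        assert strands == {"+", "-"}

    def test_gene_bodies_do_not_overlap(self):
        genes, mirnas = generate_annotation(*_gen(_small_cfg()))
        spans = sorted((g.chrom, g.start, g.end) for g in genes)
        spans += sorted((m.chrom, m.start, m.end) for m in mirnas)
        spans.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 <= s2

    def test_promoters_fit_inside_chromosomes(self):
        cfg = _small_cfg()
        genome, _ = generate_genome(cfg)
        genes, mirnas = generate_annotation(genome, cfg)
        for g in list(genes) + list(mirnas):
            tss = g.tss
            length = len(genome[g.chrom])
            if g.strand == "+":
                assert tss - 2200 >= 0 and tss + 500 <= length
            else:
                assert tss - 500 >= 0 and tss + 2200 <= length

    def test_gff3_round_trip(self, tmp_path):
        genome, cfg = _gen(_small_cfg())
        genes, mirnas = generate_annotation(genome, cfg)
        path = tmp_path / "ann.gff3"
        seqio.write_gff3(genes, mirnas, path)
        genes2, mirnas2 = seqio.read_gff3(path)
        assert genes2 == genes and mirnas2 == mirnas

    def test_genome_too_short_raises_placement_error(self):
        from ovulemeth.simdata import PlacementError
        cfg = _small_cfg(chrom_length=27_000, n_genes_per_chrom=10)
        genome, _ = generate_genome(cfg)
        with pytest.raises(PlacementError):
            generate_annotation(genome, cfg)


def _gen(cfg):
    genome, _ = generate_genome(cfg)
    return genome, cfg


def _study(cfg):
    genome, _ = generate_genome(cfg)
    genes, mirnas = generate_annotation(genome, cfg)
    ci = ContextIndex(genome)
    element_sets = build_elements(genes, genome)
    from ovulemeth.elements import define_promoters
    element_sets["mirna_promoter"] = [
        e for e in define_promoters(mirnas,
                                    {c: len(s) for c, s in genome.items()})
        if e.element_type == "promoter"]
    return genome, genes, mirnas, ci, element_sets


class TestMethylome:
    def test_samplewide_context_means_match_configuration(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length=1_000_000,
                        n_genes_per_chrom=0, n_mirna_per_chrom=0,
                        n_cgi_per_chrom=0, dmr_plan=[], seed=4)
        genome, genes, mirnas, ci, element_sets = _study(cfg)
        truth = generate_methylome(genome, element_sets, cfg, ci)
        for sample in cfg.samples:
            for ctx_code, ctx in enumerate(CONTEXTS):
                idx = ci.codes["Chr1"] == ctx_code
                mean = np.nanmean(truth.probs[sample]["Chr1"][idx])
                assert abs(mean - cfg.context_means[ctx]) < 0.02, (sample, ctx)

    def test_zero_plan_gives_identical_samples(self):
        cfg = _small_cfg(dmr_plan=[])
        genome, genes, mirnas, ci, element_sets = _study(cfg)
        truth = generate_methylome(genome, element_sets, cfg, ci)
        a, b = (truth.probs[s] for s in cfg.samples)
        for chrom in genome:
            assert np.array_equal(a[chrom], b[chrom], equal_nan=True)

    def test_planted_element_fold_change_is_exact(self):
        cfg = _small_cfg(dmr_plan=[DmrPlanEntry("promoter", "hyper", 1,
                                                high=0.8, low=0.2)])
        genome, genes, mirnas, ci, element_sets = _study(cfg)
        truth = generate_methylome(genome, element_sets, cfg, ci)
        planted = truth.planted[0]
        interest, reference = cfg.samples
        sl = slice(planted.start, planted.end)
        hi = np.nanmean(truth.probs[interest][planted.chrom][sl])
        lo = np.nanmean(truth.probs[reference][planted.chrom][sl])
        assert hi == pytest.approx(0.8) and lo == pytest.approx(0.2)
        assert hi / lo == pytest.approx(4.0)
        assert planted.truth_fold_change == pytest.approx(4.0)

    def test_plan_conservation(self):
        cfg = _small_cfg(dmr_plan=[
            DmrPlanEntry("promoter", "hyper", 2),
            DmrPlanEntry("exon", "hypo", 2),
            DmrPlanEntry("intergenic", "hyper", 2),
            DmrPlanEntry("mirna_promoter", "hypo", 1),
        ])
        genome, genes, mirnas, ci, element_sets = _study(cfg)
        truth = generate_methylome(genome, element_sets, cfg, ci)
        assert len(truth.planted) == sum(e.count for e in cfg.dmr_plan)

    def test_overfull_plan_raises(self):
        cfg = _small_cfg(dmr_plan=[DmrPlanEntry("promoter", "hyper", 999)])
        genome, genes, mirnas, ci, element_sets = _study(cfg)
        with pytest.raises(PlanError):
            generate_methylome(genome, element_sets, cfg, ci)


class TestReads:
    def test_fixed_seed_gives_identical_fastq_bytes(self):
        cfg = _small_cfg(coverage=2)
        genome, _ = generate_genome(cfg)
        probs = {c: np.full(len(s), 0.5) for c, s in genome.items()}
        chunks = []
        for _ in range(2):
            buf = io.StringIO()
            for r in simulate_reads(genome, probs, cfg, cfg.rng(99)):
                buf.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")
            chunks.append(buf.getvalue())
        assert chunks[0] == chunks[1]

    def test_fully_methylated_truth_keeps_every_origin_strand_c(self):
        cfg = _small_cfg(coverage=2, seq_error=0.0, conversion_failure=0.0)
        genome, _ = generate_genome(cfg)
        probs = {c: np.ones(len(s)) for c, s in genome.items()}
        for read in simulate_reads(genome, probs, cfg, cfg.rng(99)):
            chrom, start, strand, _ = read.id.rsplit(":", 3)
            ref = genome[chrom][int(start):int(start) + len(read.sequence)]
            if strand == "-":
                ref = seqio.revcomp(ref)
            assert read.sequence == ref  # nothing converted, no errors

    def test_unmethylated_conversion_failure_rate(self):
        """At 0.5% failure and 50x over 100 kb, the observed fraction of
        retained C at origin-strand cytosines is 0.005 +/- 0.002."""
        cfg = SimConfig(n_chromosomes=1, chrom_length=100_000,
                        n_cgi_per_chrom=0, n_genes_per_chrom=0,
                        n_mirna_per_chrom=0, coverage=50, seq_error=0.0,
                        conversion_failure=0.005, seed=6)
        genome, _ = generate_genome(cfg)
        probs = {c: np.zeros(len(s)) for c, s in genome.items()}
        n_c = n_total = 0
        for read in simulate_reads(genome, probs, cfg, cfg.rng(99)):
            chrom, start, strand, _ = read.id.rsplit(":", 3)
            start = int(start)
            seq = read.sequence if strand == "+" else seqio.revcomp(read.sequence)
            ref = genome[chrom][start:start + len(seq)]
            target = "C" if strand == "+" else "G"
            emitted = "C" if strand == "+" else "G"
            for rb, gb in zip(seq, ref):
                if gb == target:
                    n_total += 1
                    n_c += rb == emitted
        assert abs(n_c / n_total - 0.005) <= 0.002

    def test_truth_recovered_from_deep_pileup(self):
        """Per-context mean site ratio converges to the simulated truth
        (within 0.03 at 200x), tying reads and truth files together."""
        cfg = SimConfig(n_chromosomes=1, chrom_length=30_000,
                        n_genes_per_chrom=2, n_mirna_per_chrom=1,
                        n_cgi_per_chrom=1, coverage=200, seq_error=0.0,
                        dmr_plan=[DmrPlanEntry("promoter", "hyper", 1),
                                  DmrPlanEntry("exon", "hypo", 1)],
                        seed=8)
        genome, genes, mirnas, ci, element_sets = _study(cfg)
        truth = generate_methylome(genome, element_sets, cfg, ci)
        sample = cfg.samples[0]
        reads = simulate_reads(genome, truth.probs[sample], cfg, cfg.rng(99))
        aligner = seqio.BisulfiteAligner(genome)
        alns, _ = aligner.align(reads)
        counts = pileup([a for a in alns if a.is_unique], genome)
        ratio = counts.ratio("Chr1")
        code = ci.codes["Chr1"]
        for ctx_code, ctx in enumerate(CONTEXTS):
            idx = np.nonzero(code == ctx_code)[0]
            covered = ~np.isnan(ratio[idx])
            obs = np.nanmean(ratio[idx][covered])
            expected = np.nanmean(truth.probs[sample]["Chr1"][idx][covered])
            assert abs(obs - expected) <= 0.03, ctx


class TestTermMapAndClones:
    def test_term_map_bytes_deterministic(self, tmp_path):
        genes = [f"g{i}" for i in range(100)]
        outs = []
        for name in ("a.tsv", "b.tsv"):
            df = generate_term_map(genes, n_terms=10, seed=3)
            p = tmp_path / name
            df.to_csv(p, sep="\t", index=False)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_enriched_subset_must_fit_universe(self):
        from ovulemeth.simdata import EnrichedTermSpec
        genes = [f"g{i}" for i in range(10)]
        with pytest.raises(ValueError):
            generate_term_map(genes, enriched=EnrichedTermSpec(
                "T", ["g0", "nope"], 5), seed=0)

    def test_clones_follow_truth_levels(self, rng):
        genome = {"c": "ACG" * 500}
        probs = {"c": np.full(1500, np.nan)}
        ci = ContextIndex(genome)
        probs["c"][ci.codes["c"] >= 0] = 1.0  # fully methylated
        clones = simulate_clones(genome, probs, "c", 0, 300, n_clones=5,
                                 conversion_failure=0.0, rng=rng)
        assert all(c == genome["c"][:300] for c in clones)

    def test_control_sequence_deterministic(self):
        cfg = _small_cfg()
        assert make_control(cfg) == make_control(cfg)
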
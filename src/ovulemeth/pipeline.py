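"""End-to-end orchestration of the synthetic two-sample methylome study.

Stages: simulate -> QC -> align -> call -> annotate -> dmr -> enrich ->
cluster -> mirna -> bsp -> report.  Every stage writes its outputs under
the run directory; a manifest of per-stage config hashes makes reruns with
``resume=True`` skip stages whose inputs are unchanged.  All randomness
derives from the single seed in the configuration, so a rerun with the
same seed reproduces every report table byte for byte.

Report tables mirror the layouts of a whole-genome bisulfite study report:
read/mapping rates (percentages rounded half-up to 2 decimals),
per-chromosome x context methylation levels with unweighted-mean totals,
DMR distributions over element types / promoter classes / promoter
subregions / CpG-island-vs-shore, and the labelled miRNA-promoter table.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import elements as el_mod
from . import methcall as mc
from .enrich import cluster_profiles, enrich as enrich_terms
from . import mirna_bsp as mb
from . import seqio
from . import simdata as sim

log = logging.getLogger("ovulemeth")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report formatting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(value: float) -> str:
    return f"{round_half_up(value, 2):.2f}"


@dataclass
class RunConfig:
    """Everything the pipeline needs; fully serialised for provenance."""

    outdir: str = "run"
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    qc_max_n_fraction: float = 0.10
    qc_min_mean_quality: float = 20.0
    adapter: str | None = None
    seed_length: int = 24
    max_mismatches: int = 4
    min_coverage: int = 4
    site_q_threshold: float = 0.05
    dmr_q_max: float = 0.001
    dmr_fc_min: float = 2.0
    enrich_q_max: float = 0.05
    n_terms: int = 25
    enriched_odds_ratio: float = 8.0
    coherence: float = 0.9
    bsp_n_clones: int = 15
    bsp_amplicon_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            plan = self.sim.get("dmr_plan")
            if plan and isinstance(plan[0], dict):
                self.sim["dmr_plan"] = [sim.DmrPlanEntry(**p) for p in plan]
            if "samples" in self.sim:
                self.sim["samples"] = tuple(self.sim["samples"])
            if "context_means" in self.sim:
                self.sim["context_means"] = dict(self.sim["context_means"])
            self.sim = sim.SimConfig(**self.sim)
        self.sim = replace(self.sim, seed=self.seed)

    def validate(self) -> None:
        self.sim.validate()
        if not 0 < self.site_q_threshold < 1:
            raise sim.ConfigError("site_q_threshold must be in (0, 1)")
        if not 0 < self.dmr_q_max < 1:
            raise sim.ConfigError("dmr_q_max must be in (0, 1)")
        if self.dmr_fc_min < 1:
            raise sim.ConfigError("dmr_fc_min must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sim"]["samples"] = list(data["sim"]["samples"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class RunResult:
    config: RunConfig
    outdir: Path
    counts: dict
    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path]


def _hash_config(*parts) -> str:
    text = json.dumps([repr(p) for p in parts], sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict[str, str] = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return (self.data.get(stage) == key
                and all(p.exists() for p in outputs))

    def record(self, stage: str, key: str) -> None:
        self.data[stage] = key
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler)
                    and Path(getattr(h, "baseFilename", "")) ==
                    (outdir / "pipeline.log")
                    for h in log.handlers)
    if not have_file:
        fh = logging.FileHandler(outdir / "pipeline.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def run_pipeline(config: RunConfig, resume: bool = False) -> RunResult:
    """Execute all stages; returns tables, stage counts and output paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "config.yaml")
    manifest = _Manifest(outdir / "manifest.json")
    counts: dict = {}
    paths: dict[str, Path] = {}
    interest, reference = config.sim.samples
    samples = [interest, reference]

    # ---------------- simulate ----------------
    sim_key = _hash_config("simulate", config.sim)
    genome_fa = outdir / "genome.fa"
    control_fa = outdir / "control.fa"
    gff = outdir / "annotation.gff3"
    truth_tsv = outdir / "truth_planted_dmrs.tsv"
    probs_npz = outdir / "truth_site_probs.npz"
    fastqs = {s: outdir / f"reads_{s}.fastq" for s in samples}
    control_fastqs = {s: outdir / f"control_{s}.fastq" for s in samples}
    sim_outputs = [genome_fa, control_fa, gff, truth_tsv, probs_npz,
                   *fastqs.values(), *control_fastqs.values()]

    need_sim = not (resume and manifest.fresh("simulate", sim_key, sim_outputs))
    if need_sim:
        log.info("simulate: generating genome/annotation/methylome/reads")
        genome, cgi_truth = sim.generate_genome(config.sim)
        genes, mirnas = sim.generate_annotation(genome, config.sim)
        context_index = mc.ContextIndex(genome)
        element_sets = el_mod.build_elements(genes, genome)
        element_sets["mirna_promoter"] = [
            e for e in el_mod.define_promoters(
                mirnas, {c: len(s) for c, s in genome.items()}, prefix="mir|")
            if e.element_type == "promoter"]
        truth = sim.generate_methylome(genome, element_sets, config.sim,
                                       context_index)
        seqio.write_fasta(genome, genome_fa)
        control = sim.make_control(config.sim)
        seqio.write_fasta({"control": control}, control_fa)
        seqio.write_gff3(genes, mirnas, gff)
        seqio.write_tsv(truth.planted_table(), truth_tsv)
        arrays = {f"{s}|{c}": truth.probs[s][c]
                  for s in samples for c in genome}
        np.savez(probs_npz, **arrays)
        rng_reads = config.sim.rng(101)
        for s in samples:
            reads = sim.simulate_reads(genome, truth.probs[s], config.sim,
                                       rng_reads)
            seqio.write_fastq(reads, fastqs[s])
            seqio.write_fastq(
                sim.simulate_control_reads(control, config.sim, rng_reads),
                control_fastqs[s])
        manifest.record("simulate", sim_key)
    else:
        log.info("simulate: resumed from %s", outdir)
        genome = seqio.read_fasta(genome_fa)
        control = seqio.read_fasta(control_fa)["control"]
        genes, mirnas = seqio.read_gff3(gff)
        context_index = mc.ContextIndex(genome)
        element_sets = el_mod.build_elements(genes, genome)
        element_sets["mirna_promoter"] = [
            e for e in el_mod.define_promoters(
                mirnas, {c: len(s) for c, s in genome.items()}, prefix="mir|")
            if e.element_type == "promoter"]
        planted_df = seqio.read_tsv(truth_tsv)
        npz = np.load(probs_npz)
        probs = {s: {c: npz[f"{s}|{c}"] for c in genome} for s in samples}
        truth = sim.MethylomeTruth(
            samples=config.sim.samples, probs=probs,
            planted=[sim.PlantedDmr(**row) for row in
                     planted_df.to_dict("records")])
    paths.update(genome=genome_fa, annotation=gff, truth=truth_tsv)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    counts["planted_dmrs"] = len(truth.planted)

    # ---------------- QC + align + pileup ----------------
    aln_key = _hash_config("align", config.sim, config.qc_max_n_fraction,
                           config.qc_min_mean_quality, config.adapter,
                           config.seed_length, config.max_mismatches)
    sams = {s: outdir / f"aligned_{s}.sam" for s in samples}
    stats_json = outdir / "read_stats.json"
    counts_npz = {s: outdir / f"counts_{s}.npz" for s in samples}
    control_counts_npz = {s: outdir / f"control_counts_{s}.npz" for s in samples}
    aln_outputs = [stats_json, *sams.values(), *counts_npz.values(),
                   *control_counts_npz.values()]

    sample_counts: dict[str, mc.MethCounts] = {}
    control_counts: dict[str, mc.MethCounts] = {}
    if not (resume and manifest.fresh("align", aln_key, aln_outputs)):
        aligner = seqio.BisulfiteAligner(genome, config.seed_length,
                                         config.max_mismatches)
        control_aligner = seqio.BisulfiteAligner(
            {"control": control}, config.seed_length, config.max_mismatches)
        read_stats = {}
        for s in samples:
            raw = list(seqio.read_fastq(fastqs[s]))
            clean, qc = seqio.qc_filter(
                raw, config.qc_max_n_fraction, config.qc_min_mean_quality,
                config.adapter)
            alns, mstats = aligner.align(clean)
            seqio.write_sam(alns, genome, sams[s])
            unique = [a for a in alns if a.is_unique]
            sample_counts[s] = mc.pileup(unique, genome)
            craw = list(seqio.read_fastq(control_fastqs[s]))
            calns, _ = control_aligner.align(craw)
            control_counts[s] = mc.pileup(
                [a for a in calns if a.is_unique], {"control": control})
            read_stats[s] = {"raw": qc.raw, "clean": qc.clean,
                             "mapped": mstats.mapped, "unique": mstats.unique}
            log.info("align %s: raw=%d clean=%d mapped=%d unique=%d",
                     s, qc.raw, qc.clean, mstats.mapped, mstats.unique)
        stats_json.write_text(json.dumps(read_stats, indent=1, sort_keys=True))
        for s in samples:
            np.savez(counts_npz[s],
                     **{f"m|{c}": sample_counts[s].meth[c] for c in genome},
                     **{f"u|{c}": sample_counts[s].unmeth[c] for c in genome})
            np.savez(control_counts_npz[s],
                     m=control_counts[s].meth["control"],
                     u=control_counts[s].unmeth["control"])
        manifest.record("align", aln_key)
        counts["reads"] = read_stats
    else:
        log.info("align: resumed")
        counts["reads"] = json.loads(stats_json.read_text())
        for s in samples:
            npz = np.load(counts_npz[s])
            scounts = mc.MethCounts(chrom_lengths)
            for c in genome:
                scounts.meth[c] = npz[f"m|{c}"]
                scounts.unmeth[c] = npz[f"u|{c}"]
            sample_counts[s] = scounts
            npz = np.load(control_counts_npz[s])
            ccounts = mc.MethCounts({"control": len(control)})
            ccounts.meth["control"] = npz["m"]
            ccounts.unmeth["control"] = npz["u"]
            control_counts[s] = ccounts
    paths.update({f"sam_{s}": sams[s] for s in samples})

    # ---------------- call ----------------
    conversion = {s: mc.estimate_conversion_rate(control_counts[s])
                  for s in samples}
    counts["conversion_rate"] = conversion
    site_calls = {}
    summaries = {}
    for s in samples:
        site_calls[s] = mc.call_sites(
            sample_counts[s], context_index, conversion[s],
            config.min_coverage, config.site_q_threshold)
        summaries[s] = mc.summarize(context_index, site_calls[s])
        report = outdir / f"calls_{s}.tsv"
        mc.write_cytosine_report(sample_counts[s], context_index,
                                 site_calls[s], report)
        paths[f"calls_{s}"] = report
        for ctx in mc.CONTEXTS:
            track_path = outdir / f"ratio_{s}_{ctx}.bedgraph"
            seqio.write_bedgraph(
                mc.ratio_track(sample_counts[s], context_index, ctx),
                track_path, name=f"{s} {ctx} methylation ratio")
        log.info("call %s: %d sites tested", s, site_calls[s].n_tested)
    counts["sites_tested"] = {s: site_calls[s].n_tested for s in samples}

    # ---------------- annotate ----------------
    all_elements = (element_sets["promoter"] + element_sets["promoter_sub"]
                    + element_sets["exon"] + element_sets["intron"]
                    + element_sets["intergenic"])
    seqio.write_bed(el_mod.elements_to_bed(
        all_elements + element_sets["CGI"] + element_sets["CGI_shore"]),
        outdir / "elements.bed")
    cgi_labels = el_mod.annotate_cgi_overlap(
        all_elements, element_sets["CGI"], element_sets["CGI_shore"])

    # ---------------- dmr ----------------
    region = dmr_mod.aggregate(all_elements, context_index,
                               sample_counts[interest],
                               sample_counts[reference])
    dmr_table = dmr_mod.call_dmrs(region, config.dmr_q_max, config.dmr_fc_min)
    main_types = ["promoter", "exon", "intron", "intergenic"]
    is_main = dmr_table["element_type"].isin(main_types)
    counts["testable_elements"] = int(dmr_table["testable"].sum())
    counts["n_dmrs"] = int((dmr_table["is_dmr"] & is_main).sum())
    dmg_table = dmr_mod.map_dmgs(dmr_table)
    counts["n_dmgs"] = len(dmg_table)
    counts["n_dmgs_hyper"] = int((dmg_table["direction"] == "hyper").sum())
    counts["n_dmgs_hypo"] = int((dmg_table["direction"] == "hypo").sum())
    log.info("dmr: %d testable, %d DMRs, %d DMGs", counts["testable_elements"],
             counts["n_dmrs"], counts["n_dmgs"])

    # ---------------- enrich + cluster ----------------
    background = [g.id for g in genes]
    planted_genes = sorted({p.element_id.split(":")[0] for p in truth.planted
                            if p.element_type in ("promoter", "exon", "intron")})
    enriched_spec = None
    if planted_genes:
        enriched_spec = sim.EnrichedTermSpec(
            term_id="TERM_PLANTED", subset=planted_genes,
            n_carriers=max(len(planted_genes), min(len(background) // 5, 50)),
            odds_ratio=config.enriched_odds_ratio)
    term_map = sim.generate_term_map(background, config.n_terms,
                                     enriched=enriched_spec,
                                     seed=config.seed)
    seqio.write_tsv(term_map, outdir / "term_map.tsv")
    enrichment = (enrich_terms(dmg_table["gene_id"], background,
                                    term_map, config.enrich_q_max)
                  if len(dmg_table) else pd.DataFrame())
    cluster_files: dict[str, Path] = {}
    if len(dmg_table) >= 2:
        mat = _gene_ratio_matrix(dmg_table["gene_id"], dmr_table, samples)
        clust = cluster_profiles(mat)
        (outdir / "dmg_clusters.cdt").write_text(clust.cdt_text())
        (outdir / "dmg_clusters.gtr").write_text(clust.gtr_text())
        (outdir / "dmg_clusters.nwk").write_text(clust.newick() + "\n")
        cluster_files = {k: outdir / f"dmg_clusters.{k}"
                         for k in ("cdt", "gtr", "nwk")}

    # ---------------- mirna + coherence ----------------
    dm_records = mb.mirna_promoter_dm(
        mirnas, context_index, sample_counts[interest],
        sample_counts[reference], chrom_lengths)
    mirna_table = mb.dm_records_table(dm_records, significant_only=True)
    counts["mirna_promoters_dm"] = len(mirna_table)
    planted_mirna_dirs = [
        (p.element_id.split(":")[0].replace("mir|", ""), p.direction)
        for p in truth.planted if p.element_type == "mirna_promoter"]
    target_rng = config.sim.rng(102)
    target_map = {m: background[int(target_rng.integers(0, len(background)))]
                  for m, _ in planted_mirna_dirs} if background else {}
    mirna_expr, gene_expr, target_df = sim.generate_expression_tables(
        planted_mirna_dirs, target_map, config.coherence,
        background_genes=background, seed=config.seed)
    for name, df in (("mirna_expression", mirna_expr),
                     ("gene_expression", gene_expr),
                     ("mirna_targets", target_df)):
        seqio.write_tsv(df, outdir / f"{name}.tsv")
    triples = mb.coherence_network(dm_records, mirna_expr, target_df,
                                   gene_expr)
    coherence_df = mb.coherence_table(triples)
    counts["coherent_triples"] = int((coherence_df["verdict"] == "coherent").sum())

    # ---------------- bsp ----------------
    bsp_tables = []
    bsp_targets = [p for p in truth.planted
                   if p.element_type in ("promoter", "exon")][:2]
    for p in bsp_targets:
        length = min(config.bsp_amplicon_length, p.end - p.start)
        amplicon = genome[p.chrom][p.start:p.start + length]
        clone_results = {}
        for i, s in enumerate(samples):
            clones = sim.simulate_clones(
                genome, truth.probs[s], p.chrom, p.start, length,
                n_clones=config.bsp_n_clones,
                conversion_failure=config.sim.conversion_failure,
                seed=config.seed + 7 * i)
            seqio.write_fasta(
                {f"clone{j}": cl for j, cl in enumerate(clones)},
                outdir / f"bsp_clones_{p.element_id.replace('|', '_').replace(':', '_')}_{s}.fa")
            clone_results[s] = mb.analyze_clones(
                mb.CloneSet(amplicon, clones, sample=s))
        comp = mb.compare_bsp_wgbs(clone_results, sample_counts,
                                   context_index, genome, amplicon)
        comp.insert(0, "amplicon", p.element_id)
        bsp_tables.append(comp)
    bsp_df = (pd.concat(bsp_tables, ignore_index=True)
              if bsp_tables else pd.DataFrame())

    # ---------------- report ----------------
    tables = make_tables(
        read_stats=counts["reads"], conversion=conversion,
        summaries=summaries, dmr_table=dmr_table, dmg_table=dmg_table,
        cgi_labels=cgi_labels, enrichment=enrichment,
        mirna_table=mirna_table, coherence=coherence_df, bsp=bsp_df,
        samples=samples)
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    for name, df in tables.items():
        path = report_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[name] = path
    seqio.write_tsv(dmr_table, outdir / "dmrs.tsv")
    seqio.write_tsv(dmg_table, outdir / "dmgs.tsv")
    (outdir / "stage_counts.json").write_text(
        json.dumps(counts, indent=1, sort_keys=True, default=str))
    log.info("pipeline complete: %s", outdir)
    return RunResult(config=config, outdir=outdir, counts=counts,
                     tables=tables, paths=paths)


def _gene_ratio_matrix(gene_ids, dmr_table: pd.DataFrame,
                       samples: list[str]) -> pd.DataFrame:
    """Per-gene smoothed methylation ratios (both samples) pooled over the
    gene's promoter/exon/intron elements."""
    sub = dmr_table[dmr_table["gene_id"].isin(set(gene_ids))
                    & dmr_table["element_type"].isin(dmr_mod.GENIC_TYPES)]
    rows = {}
    for gene_id, grp in sub.groupby("gene_id"):
        m_a, u_a = grp["m_a"].sum(), grp["u_a"].sum()
        m_b, u_b = grp["m_b"].sum(), grp["u_b"].sum()
        rows[gene_id] = [dmr_mod.smoothed_ratio(m_a, u_a),
                         dmr_mod.smoothed_ratio(m_b, u_b)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def make_tables(read_stats: dict, conversion: dict, summaries: dict,
                dmr_table: pd.DataFrame, dmg_table: pd.DataFrame,
                cgi_labels: dict, enrichment: pd.DataFrame,
                mirna_table: pd.DataFrame, coherence: pd.DataFrame,
                bsp: pd.DataFrame, samples: list[str]
                ) -> dict[str, pd.DataFrame]:
    """Assemble the report bundle from stage outputs."""
    tables: dict[str, pd.DataFrame] = {}
    rows = []
    for s in samples:
        st = read_stats[s]
        clean = st["clean"]
        rows.append({
            "sample": s, "raw_reads": st["raw"], "clean_reads": clean,
            "mapped_reads": st["mapped"],
            "mapping_rate_pct": fmt_pct(100.0 * st["mapped"] / clean) if clean else "0.00",
            "unique_reads": st["unique"],
            "unique_rate_pct": fmt_pct(100.0 * st["unique"] / clean) if clean else "0.00",
            "conversion_rate_pct": fmt_pct(100.0 * conversion[s]),
        })
    tables["mapping_stats"] = pd.DataFrame(rows)

    level_rows = []
    for s in samples:
        df = summaries[s].copy()
        df.insert(0, "sample", s)
        for col in df.columns:
            if col.endswith("_pct"):
                df[col] = df[col].map(fmt_pct)
        level_rows.append(df)
    tables["methylation_levels"] = pd.concat(level_rows, ignore_index=True)

    tables["dmr_by_element_type"] = dmr_mod.crosstab_types(dmr_table)
    tables["dmr_by_promoter_class"] = dmr_mod.crosstab_promoter_class(dmr_table)
    tables["dmr_by_promoter_subregion"] = \
        dmr_mod.crosstab_promoter_subregion(dmr_table)
    tables["dmr_cgi_crosstab"] = dmr_mod.crosstab_cgi(dmr_table, cgi_labels)
    # proportions per facet (distribution view)
    dist = tables["dmr_by_element_type"].copy()
    total = dist["total"].sum()
    dist["proportion"] = dist["total"] / total if total else 0.0
    tables["dmr_distribution"] = dist[["element_type", "total", "proportion"]]
    tables["dmgs"] = dmg_table
    tables["enrichment"] = enrichment
    tables["mirna_promoters"] = mirna_table
    tables["mirna_coherence"] = coherence
    if len(bsp):
        tables["bsp_vs_wgbs"] = bsp
    return tables
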
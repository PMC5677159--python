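"""miRNA-promoter differential methylation, the promoter->miRNA->target
coherence network, and bisulfite-PCR clone validation.

miRNA gene promoters use the same -2200..+500 window as protein-coding
genes, anchored at the annotated pre-miRNA 5' end.  A promoter's
significance label follows the two-tier rule used for reporting
differentially methylated miRNA promoters: '**' for |log2 fold-change| >= 1
and P < 0.01, '*' for |log2 fold-change| >= 1 and 0.01 < P < 0.05 (the
boundary P = 0.01 satisfies neither open interval and is labelled 'ns').
The threshold is inclusive of |log2fc| = 1 so that published reference rows
with a fold-change of exactly 2 keep their labels; set
``lfc_inclusive=False`` for the strict open-interval reading.

A (promoter, miRNA, target) triple is *coherent* when promoter
hypo-methylation pairs with miRNA up-regulation and target
down-regulation, or the fully mirrored hyper case.

Bisulfite-PCR clones are aligned gap-free to their amplicon
(bisulfite-aware: reference C may read C or T); per-site percent
methylation is 100 x (#clones reading C) / (#informative clones), pooled
per context for the assay-level figures.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dmr import chi2_test, smoothed_ratio, MIN_COVERED_SITES, MIN_TOTAL_CALLS
from .elements import define_promoters
from .methcall import CODE_NONE, CONTEXTS, ContextIndex, MethCounts
from .seqio import MirnaGene


# ---------------------------------------------------------------------------
# miRNA promoter differential methylation
# ---------------------------------------------------------------------------

@dataclass
class MiRNAPromoterDM:
    mirna: str
    locus_id: str
    chrom: str
    start: int
    end: int
    m_interest: int
    u_interest: int
    m_reference: int
    u_reference: int
    log2fc: float
    p: float
    direction: str
    label: str

    @property
    def significant(self) -> bool:
        return self.label in ("*", "**")


def dm_label(log2fc: float, p: float, lfc_min: float = 1.0,
             p_strong: float = 0.01, p_weak: float = 0.05,
             lfc_inclusive: bool = True) -> str:
    """Two-tier significance label for a promoter fold-change/p pair."""
    big = abs(log2fc) >= lfc_min if lfc_inclusive else abs(log2fc) > lfc_min
    if not big:
        return "ns"
    if p < p_strong:
        return "**"
    if p_strong < p < p_weak:
        return "*"
    return "ns"


def mirna_promoter_dm(mirna_loci: Sequence[MirnaGene],
                      context_index: ContextIndex,
                      counts_interest: MethCounts,
                      counts_reference: MethCounts,
                      chrom_lengths: dict[str, int],
                      min_covered_sites: int = MIN_COVERED_SITES,
                      min_total_calls: int = MIN_TOTAL_CALLS,
                      **label_kwargs) -> list[MiRNAPromoterDM]:
    """Per-miRNA-promoter chi-squared test, log2 fold-change and label.

    Promoters failing the coverage gate are excluded (logged by count in
    the pipeline).  Records are keyed by locus, not name: duplicate miRNA
    names with distinct loci stay distinct.
    """
    promoters = define_promoters(mirna_loci, chrom_lengths)
    out: list[MiRNAPromoterDM] = []
    for el in promoters:
        if el.element_type != "promoter":
            continue
        code = context_index.codes[el.chrom][el.start:el.end]
        idx = np.nonzero(code != CODE_NONE)[0] + el.start
        stats_ok = True
        vals = {}
        for key, counts in (("interest", counts_interest),
                            ("reference", counts_reference)):
            m = int(counts.meth[el.chrom][idx].sum())
            u = int(counts.unmeth[el.chrom][idx].sum())
            covered = int(np.count_nonzero(
                counts.meth[el.chrom][idx] + counts.unmeth[el.chrom][idx] > 0))
            vals[f"m_{key}"], vals[f"u_{key}"] = m, u
            if covered < min_covered_sites or m + u < min_total_calls:
                stats_ok = False
        if not stats_ok:
            continue
        _, p, _ = chi2_test(vals["m_interest"], vals["u_interest"],
                            vals["m_reference"], vals["u_reference"])
        r_int = smoothed_ratio(vals["m_interest"], vals["u_interest"])
        r_ref = smoothed_ratio(vals["m_reference"], vals["u_reference"])
        log2fc = math.log2(r_int / r_ref)
        out.append(MiRNAPromoterDM(
            mirna=el.gene_id or el.id, locus_id=el.id, chrom=el.chrom,
            start=el.start, end=el.end, log2fc=log2fc, p=p,
            direction="hyper" if log2fc > 0 else "hypo",
            label=dm_label(log2fc, p, **label_kwargs), **vals))
    return out


def dm_records_table(records: Sequence[MiRNAPromoterDM],
                     significant_only: bool = True) -> pd.DataFrame:
    rows = [{"mirna": r.mirna, "locus_id": r.locus_id, "chrom": r.chrom,
             "start": r.start, "end": r.end, "log2fc": r.log2fc,
             "direction": f"{r.direction}-methylation", "p_value": r.p,
             "label": r.label}
            for r in records if r.significant or not significant_only]
    return pd.DataFrame(rows, columns=["mirna", "locus_id", "chrom", "start",
                                       "end", "log2fc", "direction",
                                       "p_value", "label"])


# ---------------------------------------------------------------------------
# coherence network
# ---------------------------------------------------------------------------

@dataclass
class CoherenceTriple:
    mirna: str
    promoter_direction: str
    mirna_log2fc: float | None
    target: str | None
    target_log2fc: float | None
    verdict: str  # coherent | incoherent | untestable


def _expression_map(df: pd.DataFrame, id_col: str) -> dict[str, float]:
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].unique()
        raise ValueError(f"duplicate expression entries for {list(dups)[:5]}")
    return dict(zip(df[id_col], df["log2fc"].astype(float)))


def coherence_network(dm_records: Sequence[MiRNAPromoterDM] | pd.DataFrame,
                      mirna_expression: pd.DataFrame,
                      target_map: pd.DataFrame,
                      gene_expression: pd.DataFrame
                      ) -> list[CoherenceTriple]:
    """Classify each (promoter, miRNA, target) triple.

    Coherent: hypo promoter & miRNA up & target down, or hyper promoter &
    miRNA down & target up.  Missing expression for the miRNA or the target
    makes the triple untestable.
    """
    mirna_expr = _expression_map(mirna_expression, "mirna")
    gene_expr = _expression_map(gene_expression, "gene_id")
    targets: dict[str, list[str]] = {}
    for rec in target_map.itertuples(index=False):
        targets.setdefault(rec.mirna, []).append(rec.gene_id)
    if isinstance(dm_records, pd.DataFrame):
        items = [(r.mirna, str(r.direction).split("-")[0])
                 for r in dm_records.itertuples(index=False)]
    else:
        items = [(r.mirna, r.direction) for r in dm_records if r.significant]
    out: list[CoherenceTriple] = []
    for mirna, pdir in items:
        mfc = mirna_expr.get(mirna)
        tgts = targets.get(mirna) or [None]
        for target in tgts:
            tfc = gene_expr.get(target) if target else None
            if mfc is None or tfc is None:
                verdict = "untestable"
            elif pdir == "hypo" and mfc > 0 and tfc < 0:
                verdict = "coherent"
            elif pdir == "hyper" and mfc < 0 and tfc > 0:
                verdict = "coherent"
            else:
                verdict = "incoherent"
            out.append(CoherenceTriple(mirna, pdir, mfc, target, tfc, verdict))
    return out


def coherence_table(triples: Sequence[CoherenceTriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mirna": t.mirna, "promoter_direction": t.promoter_direction,
          "mirna_log2fc": t.mirna_log2fc, "target": t.target,
          "target_log2fc": t.target_log2fc, "verdict": t.verdict}
         for t in triples],
        columns=["mirna", "promoter_direction", "mirna_log2fc", "target",
                 "target_log2fc", "verdict"])


# ---------------------------------------------------------------------------
# bisulfite-PCR clone analysis
# ---------------------------------------------------------------------------

@dataclass
class CloneSet:
    """Sanger-sequenced clones of one bisulfite amplicon in one sample."""

    amplicon: str
    clones: list[str]
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("a clone set needs at least one clone")


@dataclass
class CloneAnalysis:
    per_site: pd.DataFrame       # pos, context, n_meth, n_informative, pct
    per_context: dict[str, float]  # context -> pooled percent
    n_clones_used: int
    excluded_clones: list[int]   # indices of clones over the mismatch cap
    low_conversion_clones: list[int]


def _amplicon_contexts(amplicon: str) -> list[tuple[int, str]]:
    """(position, context) for Watson-strand cytosines of the amplicon.

    BSP assays read one strand; only the amplicon's own-strand cytosines
    are scored.  3'-truncated contexts default to CHH-like 'undefined' and
    are excluded from context pooling but kept per-site.
    """
    out = []
    n = len(amplicon)
    for i, base in enumerate(amplicon):
        if base != "C":
            continue
        nxt = amplicon[i + 1:i + 3]
        if len(nxt) >= 1 and nxt[0] == "G":
            ctx = "CG"
        elif len(nxt) < 2 or "N" in nxt:
            ctx = "undefined"
        elif nxt[1] == "G":
            ctx = "CHG"
        else:
            ctx = "CHH"
        out.append((i, ctx))
    return out


def analyze_clones(clone_set: CloneSet, max_mismatch_frac: float = 0.20,
                   min_chh_conversion: float | None = None) -> CloneAnalysis:
    """Per-site and per-context percent methylation over a clone set.

    Clones are compared gap-free to the amplicon after C->T reduction of
    both; clones whose reduced mismatch fraction exceeds the cap are
    excluded.  With ``min_chh_conversion`` set, clones whose fraction of
    converted (T) calls at CHH sites falls below it are discarded as
    conversion failures (flagged).
    """
    amplicon = clone_set.amplicon.upper()
    sites = _amplicon_contexts(amplicon)
    reduced_ref = amplicon.replace("C", "T")
    used, excluded, low_conv = [], [], []
    for i, clone in enumerate(clone_set.clones):
        clone = clone.upper()
        if len(clone) != len(amplicon):
            excluded.append(i)
            continue
        red = clone.replace("C", "T")
        mism = sum(a != b for a, b in zip(red, reduced_ref))
        if mism / len(amplicon) > max_mismatch_frac:
            excluded.append(i)
            continue
        if min_chh_conversion is not None:
            chh = [(p, c) for p, c in sites if c == "CHH"]
            calls = [clone[p] for p, _ in chh if clone[p] in "CT"]
            if calls and calls.count("T") / len(calls) < min_chh_conversion:
                low_conv.append(i)
                continue
        used.append(clone)
    rows = []
    pooled: dict[str, list[int]] = {ctx: [0, 0] for ctx in CONTEXTS}
    for pos, ctx in sites:
        calls = [c[pos] for c in used if c[pos] in "CT"]
        n_meth = calls.count("C")
        n_inf = len(calls)
        pct = 100.0 * n_meth / n_inf if n_inf else float("nan")
        rows.append({"pos": pos, "context": ctx, "n_meth": n_meth,
                     "n_informative": n_inf, "pct": pct})
        if ctx in pooled:
            pooled[ctx][0] += n_meth
            pooled[ctx][1] += n_inf
    per_context = {ctx: (100.0 * m / n if n else float("nan"))
                   for ctx, (m, n) in pooled.items()}
    return CloneAnalysis(
        per_site=pd.DataFrame(rows, columns=["pos", "context", "n_meth",
                                             "n_informative", "pct"]),
        per_context=per_context, n_clones_used=len(used),
        excluded_clones=excluded, low_conversion_clones=low_conv)


def locate_amplicon(genome: dict[str, str], amplicon: str
                    ) -> tuple[str, int]:
    """Find the amplicon's (unique) Watson-strand position on the genome."""
    hits = [(chrom, seq.find(amplicon.upper()))
            for chrom, seq in genome.items() if amplicon.upper() in seq]
    if not hits:
        raise LookupError("amplicon sequence not found on the genome")
    return hits[0][0], hits[0][1]


def compare_bsp_wgbs(clone_results: Mapping[str, CloneAnalysis],
                     wgbs_counts: Mapping[str, MethCounts],
                     context_index: ContextIndex,
                     genome: dict[str, str], amplicon: str) -> pd.DataFrame:
    """Per-context BSP vs WGBS percent methylation over one amplicon.

    WGBS percent pools methylated/total read calls over the amplicon's
    Watson-strand cytosines of each context (the strand BSP assays).
    The agreement flag is true when both assays rank the two samples the
    same way within a context.
    """
    chrom, start = locate_amplicon(genome, amplicon)
    sites = _amplicon_contexts(genome[chrom][start:start + len(amplicon)])
    samples = list(clone_results)
    rows = []
    for ctx in CONTEXTS:
        pos = [start + p for p, c in sites if c == ctx]
        row: dict[str, object] = {"context": ctx}
        for sample in samples:
            counts = wgbs_counts[sample]
            m = int(counts.meth[chrom][pos].sum()) if pos else 0
            u = int(counts.unmeth[chrom][pos].sum()) if pos else 0
            wgbs = 100.0 * m / (m + u) if m + u else float("nan")
            bsp = clone_results[sample].per_context.get(ctx, float("nan"))
            row[f"bsp_{sample}"] = bsp
            row[f"wgbs_{sample}"] = wgbs
            row[f"absdiff_{sample}"] = abs(bsp - wgbs)
        if len(samples) == 2:
            a, b = samples
            bsp_cmp = np.sign(row[f"bsp_{a}"] - row[f"bsp_{b}"])
            wgbs_cmp = np.sign(row[f"wgbs_{a}"] - row[f"wgbs_{b}"])
            row["direction_agreement"] = bool(
                not np.isnan(bsp_cmp) and not np.isnan(wgbs_cmp)
                and bsp_cmp == wgbs_cmp)
        rows.append(row)
    return pd.DataFrame(rows)
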
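"""Element-level two-sample differential methylation.

For every genome element the methylated/unmethylated *read calls* of the two
samples are pooled over the element's cytosines (both strands, all contexts
by default) into a 2x2 table and tested with Pearson's chi-squared (df=1, no
continuity correction).  Sparse tables (any expected cell < 5) fall back to
Fisher's exact test.  One genome-wide Benjamini-Hochberg family covers all
testable elements; an element is a DMR iff q <= 0.001 and the
Haldane-smoothed ratio fold-change is >= 2.0.  Direction is hyper when the
sample of interest exceeds the reference.  A gene containing at least one
DMR in its promoter, exon or intron is a differentially methylated gene
(DMG).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .elements import GenomeElement
from .methcall import CODE_NONE, CONTEXTS, ContextIndex, MethCounts

DEFAULT_Q_MAX = 0.001
DEFAULT_FC_MIN = 2.0
MIN_COVERED_SITES = 5
MIN_TOTAL_CALLS = 20


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate(elements: Sequence[GenomeElement], context_index: ContextIndex,
              counts_a: MethCounts, counts_b: MethCounts,
              min_covered_sites: int = MIN_COVERED_SITES,
              min_total_calls: int = MIN_TOTAL_CALLS,
              context: str | None = None,
              mode: Literal["reads", "sites"] = "reads") -> pd.DataFrame:
    """Per-element pooled counts for both samples.

    ``mode='reads'`` (default) sums methylated/unmethylated read calls;
    ``mode='sites'`` counts covered cytosines with majority-methylated vs
    majority-unmethylated calls instead.  Elements with fewer than
    ``min_covered_sites`` covered cytosines or fewer than
    ``min_total_calls`` read calls in either sample are marked untestable.
    """
    ctx_code = CONTEXTS.index(context) if context else None
    rows = []
    for el in elements:
        code = context_index.codes[el.chrom][el.start:el.end]
        mask = (code != CODE_NONE) if ctx_code is None else (code == ctx_code)
        idx = np.nonzero(mask)[0] + el.start
        row = {"element_id": el.id, "chrom": el.chrom, "start": el.start,
               "end": el.end, "element_type": el.element_type,
               "gene_id": el.gene_id, "cpg_class": el.cpg_class,
               "rank": el.rank, "n_sites": len(idx)}
        testable = True
        for label, counts in (("a", counts_a), ("b", counts_b)):
            m = counts.meth[el.chrom][idx].astype(np.int64)
            u = counts.unmeth[el.chrom][idx].astype(np.int64)
            if mode == "sites":
                cov = m + u
                covered = cov > 0
                row[f"m_{label}"] = int(np.count_nonzero(covered & (m > u)))
                row[f"u_{label}"] = int(np.count_nonzero(covered & (m <= u)))
            else:
                row[f"m_{label}"] = int(m.sum())
                row[f"u_{label}"] = int(u.sum())
            row[f"covered_{label}"] = int(np.count_nonzero(m + u > 0))
            if (row[f"covered_{label}"] < min_covered_sites
                    or int(m.sum()) + int(u.sum()) < min_total_calls):
                testable = False
        row["testable"] = testable
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def chi2_test(m_a: int, u_a: int, m_b: int, u_b: int
              ) -> tuple[float, float, str]:
    """Pearson chi-squared on the 2x2 table [[m_a, u_a], [m_b, u_b]].

    No continuity correction, df=1.  Returns (statistic, p, method) where
    method is 'chi2', 'fisher' (any expected cell < 5) or 'degenerate'
    (a zero marginal: statistic 0, p 1).
    """
    a, b, c, d = (int(x) for x in (m_a, u_a, m_b, u_b))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 0.0, 1.0, "degenerate"
    expected_min = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
    if expected_min < 5:
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float("nan"), float(p), "fisher"
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(sps.chi2.sf(stat, df=1)), "chi2"


def bh_fdr(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p,
                   dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def smoothed_ratio(m: int, u: int) -> float:
    """Haldane-smoothed methylation ratio (m + 0.5) / (m + u + 1)."""
    return (m + 0.5) / (m + u + 1.0)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def call_dmrs(region_counts: pd.DataFrame, q_max: float = DEFAULT_Q_MAX,
              fc_min: float = DEFAULT_FC_MIN, interest: str = "a",
              reference: str = "b") -> pd.DataFrame:
    """Test every testable element, BH-correct genome-wide, apply the
    q <= q_max AND fold-change >= fc_min rule, assign direction.

    ``interest``/``reference`` name the count columns ('a'/'b'); direction
    hyper means the sample of interest has the higher smoothed ratio.
    Output is sorted by q then genomic position.
    """
    if interest == reference:
        raise ValueError("interest and reference samples must differ")
    df = region_counts.copy()
    testable = df["testable"].to_numpy(dtype=bool)
    stat = np.full(len(df), np.nan)
    pval = np.full(len(df), np.nan)
    method = np.full(len(df), "", dtype=object)
    for i in np.nonzero(testable)[0]:
        row = df.iloc[i]
        stat[i], pval[i], method[i] = chi2_test(
            row["m_a"], row["u_a"], row["m_b"], row["u_b"])
    df["chi2"], df["p"], df["method"] = stat, pval, method
    q = np.full(len(df), np.nan)
    if testable.any():
        q[testable] = bh_fdr(pval[testable])
    df["q"] = q
    r_int = (df[f"m_{interest}"] + 0.5) / (df[f"m_{interest}"] + df[f"u_{interest}"] + 1.0)
    r_ref = (df[f"m_{reference}"] + 0.5) / (df[f"m_{reference}"] + df[f"u_{reference}"] + 1.0)
    df["ratio_interest"], df["ratio_reference"] = r_int, r_ref
    df["fold_change"] = np.maximum(r_int / r_ref, r_ref / r_int)
    # both raw ratios zero: the smoothed quotient is a pure coverage
    # artifact, and such an element can never be differentially methylated
    both_zero = (df[f"m_{interest}"] == 0) & (df[f"m_{reference}"] == 0)
    df.loc[both_zero, "fold_change"] = 1.0
    df["direction"] = np.where(r_int > r_ref, "hyper", "hypo")
    df.loc[(r_int == r_ref) | both_zero, "direction"] = "none"
    df["is_dmr"] = testable & (df["q"] <= q_max) & (df["fold_change"] >= fc_min)
    order = df["q"].fillna(np.inf)
    df = df.iloc[np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy(),
                             order.to_numpy()))]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# DMGs and cross-tabulations
# ---------------------------------------------------------------------------

GENIC_TYPES = ("promoter", "exon", "intron")


def map_dmgs(dmr_table: pd.DataFrame) -> pd.DataFrame:
    """Genes with >= 1 DMR in their promoter, exon or intron.

    Gene direction is the majority of its DMR directions; ties are 'mixed'.
    """
    dmrs = dmr_table[dmr_table["is_dmr"]
                     & dmr_table["element_type"].isin(GENIC_TYPES)]
    rows = []
    for gene_id, grp in dmrs.groupby("gene_id"):
        n_hyper = int((grp["direction"] == "hyper").sum())
        n_hypo = int((grp["direction"] == "hypo").sum())
        if n_hyper > n_hypo:
            direction = "hyper"
        elif n_hypo > n_hyper:
            direction = "hypo"
        else:
            direction = "mixed"
        rows.append({"gene_id": gene_id, "n_dmrs": len(grp),
                     "n_hyper": n_hyper, "n_hypo": n_hypo,
                     "direction": direction,
                     "elements": ",".join(grp["element_id"])})
    return pd.DataFrame(rows, columns=["gene_id", "n_dmrs", "n_hyper",
                                       "n_hypo", "direction", "elements"])


def crosstab_types(dmr_table: pd.DataFrame) -> pd.DataFrame:
    """DMR counts by element type and direction (genome-element layout)."""
    dmrs = dmr_table[dmr_table["is_dmr"]]
    tab = (dmrs.groupby(["element_type", "direction"]).size()
           .unstack(fill_value=0))
    tab["total"] = tab.sum(axis=1)
    return tab.reset_index()


def crosstab_cgi(dmr_table: pd.DataFrame, cgi_labels: dict[str, str | None]
                 ) -> pd.DataFrame:
    """DMRs per element type x {CGI, CGI shore} (island-vs-shore layout)."""
    dmrs = dmr_table[dmr_table["is_dmr"]]
    order = ["promoter", "exon", "intron", "intergenic"]
    rows = []
    for etype in order:
        sub = dmrs[dmrs["element_type"] == etype]
        n_cgi = sum(1 for el in sub["element_id"] if cgi_labels.get(el) == "CGI")
        n_shore = sum(1 for el in sub["element_id"]
                      if cgi_labels.get(el) == "CGI_shore")
        rows.append({"element_type": etype, "CGI": n_cgi,
                     "CGI_shore": n_shore})
    total = {"element_type": "Total",
             "CGI": sum(r["CGI"] for r in rows),
             "CGI_shore": sum(r["CGI_shore"] for r in rows)}
    rows.append(total)
    return pd.DataFrame(rows)


def crosstab_promoter_class(dmr_table: pd.DataFrame) -> pd.DataFrame:
    """Promoter DMRs by CpG-density class (HCP/ICP/LCP)."""
    dmrs = dmr_table[dmr_table["is_dmr"]
                     & (dmr_table["element_type"] == "promoter")]
    tab = dmrs.groupby("cpg_class").size().reindex(
        ["HCP", "ICP", "LCP"], fill_value=0)
    return tab.rename("n_dmrs").reset_index()


def crosstab_promoter_subregion(dmr_table: pd.DataFrame) -> pd.DataFrame:
    """DMRs in promoter subregions (P/I/D)."""
    sub = dmr_table[dmr_table["is_dmr"] & dmr_table["element_type"].isin(
        ["promoter_P", "promoter_I", "promoter_D"])]
    tab = sub.groupby("element_type").size().reindex(
        ["promoter_P", "promoter_I", "promoter_D"], fill_value=0)
    return tab.rename("n_dmrs").reset_index()
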
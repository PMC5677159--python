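"""Cytosine context classification, pileup, and methylation calling.

Every reference cytosine (a C on the Watson strand or a G position, i.e. a C
on the Crick strand) is classified by the two bases immediately 3' of it on
its own strand: CG, CHG or CHH (H = A, T or C).  Reads contribute counts
only to cytosines of their strand of origin; a read base C at such a site is
a methylated call, T an unmethylated call, anything else is ignored.

Whether a covered site *is* methylated is decided by a one-sided binomial
test of the methylated count against the bisulfite conversion-failure rate,
with Benjamini-Hochberg correction across all tested sites.  The summary
mirrors the per-chromosome x context layout used for whole-genome reports:
counts in a totals row are column sums, percents are unweighted means of the
per-chromosome percents (a pooled-ratio convention is also available).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqio import Alignment, ValidationError

CODE_CG, CODE_CHG, CODE_CHH = 0, 1, 2
CODE_NONE = -1
CONTEXTS = ("CG", "CHG", "CHH")

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


class InsufficientDataError(ValueError):
    """Not enough observations to estimate the requested quantity."""


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


@dataclass(frozen=True)
class CytosineSite:
    chrom: str
    pos: int  # 0-based
    strand: str
    context: str


class ContextIndex:
    """Per-chromosome context codes for every reference cytosine.

    ``codes[chrom][pos]`` is 0/1/2 for CG/CHG/CHH, -1 where the position is
    not a classifiable cytosine (non-C base, N in the context, or too close
    to the chromosome end).  Strand is implicit: a classifiable position
    with base C is a Watson-strand cytosine, base G a Crick-strand one.
    """

    def __init__(self, genome: dict[str, str]):
        self.codes: dict[str, np.ndarray] = {}
        self.bases: dict[str, np.ndarray] = {}
        for chrom, seq in genome.items():
            b = _seq_array(seq)
            n = len(b)
            code = np.full(n, CODE_NONE, dtype=np.int8)
            if n >= 3:
                n1 = b[1:]  # next base for Watson C at i (i <= n-2)
                n2 = b[2:]  # second next (i <= n-3)
                is_c = b[:-2] == _C
                h1 = (n1[:-1] != _G) & (n1[:-1] != _N)
                code[:-2][is_c & (n1[:-1] == _G)] = CODE_CG
                code[:-2][is_c & h1 & (n2 == _G)] = CODE_CHG
                code[:-2][is_c & h1 & (n2 != _G) & (n2 != _N)] = CODE_CHH
                # Watson C at n-2 with next G is still a classifiable CG
                if b[n - 2] == _C and b[n - 1] == _G:
                    code[n - 2] = CODE_CG
                # Crick-strand cytosines sit at G positions; their 5'->3'
                # context runs leftwards: next bases are complement(b[i-1]),
                # complement(b[i-2]).  H on Crick <=> plus base != C.
                p1 = b[1:-1]   # b[i-1] for i in 2..n-1
                p2 = b[:-2]    # b[i-2]
                is_g = b[2:] == _G
                h1m = (p1 != _C) & (p1 != _N)
                sub = code[2:]
                sub[is_g & (p1 == _C)] = CODE_CG
                sub[is_g & h1m & (p2 == _C)] = CODE_CHG
                sub[is_g & h1m & (p2 != _C) & (p2 != _N)] = CODE_CHH
                if b[1] == _G and b[0] == _C:
                    code[1] = CODE_CG
            self.codes[chrom] = code
            self.bases[chrom] = b

    def strand(self, chrom: str, pos: int) -> str:
        return "+" if self.bases[chrom][pos] == _C else "-"

    def n_sites(self, chrom: str) -> dict[str, int]:
        code = self.codes[chrom]
        return {ctx: int(np.count_nonzero(code == i))
                for i, ctx in enumerate(CONTEXTS)}


def classify_context(genome: dict[str, str], chrom: str, pos: int,
                     strand: str) -> str:
    """Classify one cytosine; 'undefined' if the context is incomplete."""
    seq = genome[chrom].upper()
    if strand == "+":
        if seq[pos] != "C":
            raise ValidationError(f"{chrom}:{pos}(+) is {seq[pos]}, not C")
        ctx = seq[pos + 1:pos + 3]
    else:
        if seq[pos] != "G":
            raise ValidationError(f"{chrom}:{pos}(-) is {seq[pos]}, not C on Crick")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        ctx = "".join(comp[b] for b in seq[max(pos - 2, 0):pos][::-1])
    if len(ctx) >= 1 and ctx[0] == "G":
        return "CG"
    if len(ctx) < 2 or "N" in ctx:
        return "undefined"
    return "CHG" if ctx[1] == "G" else "CHH"


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

class MethCounts:
    """Methylated/unmethylated read-call counts per reference position."""

    def __init__(self, chrom_lengths: dict[str, int]):
        self.meth = {c: np.zeros(n, dtype=np.uint32) for c, n in chrom_lengths.items()}
        self.unmeth = {c: np.zeros(n, dtype=np.uint32) for c, n in chrom_lengths.items()}

    def coverage(self, chrom: str) -> np.ndarray:
        return self.meth[chrom].astype(np.int64) + self.unmeth[chrom]

    def ratio(self, chrom: str) -> np.ndarray:
        cov = self.coverage(chrom)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.meth[chrom] / cov, np.nan)


def pileup(alignments: Iterable[Alignment], genome: dict[str, str],
           unique_only: bool = True) -> MethCounts:
    """Tally read calls at reference cytosines of each read's origin strand.

    Watson-origin reads: at reference C positions, read base C is a
    methylated call and T an unmethylated one.  Crick-origin reads are
    stored genome-forward, so their cytosines appear as G (methylated) or A
    (unmethylated) at reference G positions.
    """
    counts = MethCounts({c: len(s) for c, s in genome.items()})
    bases = {c: _seq_array(s) for c, s in genome.items()}
    for aln in alignments:
        if unique_only and not aln.is_unique:
            continue
        g = bases[aln.chrom]
        if aln.end > len(g):
            raise ValidationError(
                f"alignment {aln.read_id} extends past end of {aln.chrom}")
        ref = g[aln.start:aln.end]
        arr = _seq_array(aln.seq_fw)
        if aln.strand == "+":
            site = ref == _C
            meth_idx = np.nonzero(site & (arr == _C))[0]
            unmeth_idx = np.nonzero(site & (arr == _T))[0]
        else:
            site = ref == _G
            meth_idx = np.nonzero(site & (arr == _G))[0]
            unmeth_idx = np.nonzero(site & (arr == _A))[0]
        counts.meth[aln.chrom][aln.start + meth_idx] += 1
        counts.unmeth[aln.chrom][aln.start + unmeth_idx] += 1
    return counts


def estimate_conversion_rate(control_counts: MethCounts) -> float:
    """Conversion rate = unmethylated calls / all calls on the control.

    The control substrate is fully unmethylated by construction, so every
    retained C is a conversion failure.
    """
    meth = sum(int(a.sum()) for a in control_counts.meth.values())
    unmeth = sum(int(a.sum()) for a in control_counts.unmeth.values())
    total = meth + unmeth
    if total == 0:
        raise InsufficientDataError("no read calls on the conversion control")
    return unmeth / total


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

@dataclass
class SiteCalls:
    """Per-position call codes: -1 no-call, 0 unmethylated, 1 methylated."""

    calls: dict[str, np.ndarray]
    n_tested: int
    q_threshold: float


def call_sites(counts: MethCounts, context_index: ContextIndex,
               conversion_rate: float, min_coverage: int = 4,
               q_threshold: float = 0.05) -> SiteCalls:
    """One-sided binomial test per covered site, BH-FDR across sites."""
    if not 0.0 < conversion_rate <= 1.0:
        raise ValueError(f"conversion_rate must be in (0, 1], got {conversion_rate}")
    if not 0.0 < q_threshold < 1.0:
        raise ValueError(f"q_threshold must be in (0, 1), got {q_threshold}")
    failure = 1.0 - conversion_rate
    calls = {}
    tested: list[tuple[str, np.ndarray]] = []
    m_all, n_all = [], []
    for chrom, code in context_index.codes.items():
        call = np.full(len(code), -1, dtype=np.int8)
        cov = counts.coverage(chrom)
        site = code != CODE_NONE
        covered = site & (cov >= min_coverage)
        call[covered] = 0
        idx = np.nonzero(covered)[0]
        tested.append((chrom, idx))
        m_all.append(counts.meth[chrom][idx].astype(np.int64))
        n_all.append(cov[idx])
        calls[chrom] = call
    m = np.concatenate(m_all) if m_all else np.empty(0, dtype=np.int64)
    n = np.concatenate(n_all) if n_all else np.empty(0, dtype=np.int64)
    if len(m):
        # P(X >= m | n, failure); sf(m-1) == P(X >= m)
        p = sps.binom.sf(m - 1, n, max(failure, 1e-12))
        from .dmr import bh_fdr
        q = bh_fdr(p)
        offset = 0
        for chrom, idx in tested:
            sub = q[offset:offset + len(idx)]
            calls[chrom][idx[sub < q_threshold]] = 1
            offset += len(idx)
    return SiteCalls(calls=calls, n_tested=int(len(m)), q_threshold=q_threshold)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(context_index: ContextIndex, site_calls: SiteCalls,
              totals: Literal["unweighted", "pooled"] = "unweighted"
              ) -> pd.DataFrame:
    """Per-chromosome x context site/methylated-site counts and percents.

    Site counts are all classifiable reference cytosines; methylated counts
    are sites called methylated.  The totals row sums counts; its percents
    are unweighted means of per-chromosome percents by default, or pooled
    ratios (sum m / sum n) when ``totals='pooled'``.
    """
    rows = []
    for chrom, code in context_index.codes.items():
        call = site_calls.calls[chrom]
        row: dict[str, object] = {"chrom": chrom}
        tot_sites = tot_meth = 0
        for i, ctx in enumerate(CONTEXTS):
            mask = code == i
            sites = int(np.count_nonzero(mask))
            meth = int(np.count_nonzero(mask & (call == 1)))
            row[f"{ctx.lower()}_sites"] = sites
            row[f"m{ctx.lower()}"] = meth
            row[f"m{ctx.lower()}_pct"] = 100.0 * meth / sites if sites else 0.0
            tot_sites += sites
            tot_meth += meth
        row["total_c"] = tot_sites
        row["total_mc"] = tot_meth
        row["total_pct"] = 100.0 * tot_meth / tot_sites if tot_sites else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {"chrom": "Total"}
    for col in df.columns:
        if col == "chrom":
            continue
        if col.endswith("_pct"):
            if totals == "unweighted":
                total[col] = float(df[col].mean())
            else:
                num_col = "total_mc" if col == "total_pct" else "m" + col[1:-4]
                den_col = ("total_c" if col == "total_pct"
                           else col[1:-4] + "_sites")
                den = df[den_col].sum()
                total[col] = 100.0 * df[num_col].sum() / den if den else 0.0
        else:
            total[col] = int(df[col].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def totals_percent(per_chrom_percents: Iterable[float],
                   convention: Literal["unweighted"] = "unweighted") -> float:
    """The totals-row percent convention: unweighted chromosome mean."""
    vals = list(per_chrom_percents)
    return sum(vals) / len(vals)


def write_cytosine_report(counts: MethCounts, context_index: ContextIndex,
                          site_calls: SiteCalls, path: str | Path) -> None:
    """Tab-separated per-site report (1-based positions on disk)."""
    call_name = {-1: "nocall", 0: "unmethylated", 1: "methylated"}
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tcontext\tmethylated\tunmethylated\tcall\n")
        for chrom, code in context_index.codes.items():
            idx = np.nonzero(code != CODE_NONE)[0]
            meth = counts.meth[chrom]
            unmeth = counts.unmeth[chrom]
            call = site_calls.calls[chrom]
            bases = context_index.bases[chrom]
            for pos in idx:
                strand = "+" if bases[pos] == _C else "-"
                fh.write(f"{chrom}\t{pos + 1}\t{strand}\t{CONTEXTS[code[pos]]}\t"
                         f"{meth[pos]}\t{unmeth[pos]}\t{call_name[int(call[pos])]}\n")


def ratio_track(counts: MethCounts, context_index: ContextIndex,
                context: str) -> list[tuple[str, int, int, float]]:
    """Per-site methylation-ratio bedGraph intervals for one context."""
    ctx_code = CONTEXTS.index(context)
    out = []
    for chrom, code in context_index.codes.items():
        cov = counts.coverage(chrom)
        idx = np.nonzero((code == ctx_code) & (cov > 0))[0]
        ratio = counts.meth[chrom][idx] / cov[idx]
        out.extend((chrom, int(p), int(p) + 1, float(r))
                   for p, r in zip(idx, ratio))
    return out
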
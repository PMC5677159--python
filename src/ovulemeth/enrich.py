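"""Hypergeometric term enrichment and hierarchical clustering of
methylation-ratio profiles.

Enrichment tests each term's overlap with the DMG set against the genome
background with the hypergeometric upper tail P(X >= k), BH-corrected
across tested terms.  Clustering log2-transforms ratios (log2(r + 0.01)),
uses 1 - Pearson correlation as the gene-gene distance and average-linkage
agglomeration, and emits Cluster-3.0-compatible CDT/GTR text plus Newick.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(n, K)) or K > N or n > N:
        raise ValueError(
            f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def enrich(dmg_genes: Iterable[str], background: Iterable[str],
           term_map: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Term enrichment of a gene set against the background universe.

    ``term_map`` needs columns ``gene_id`` and ``term_id`` (an optional
    ``term_name`` is carried through).  Only terms with K >= 1 background
    genes and k >= 1 DMGs are tested; records are sorted by q.
    """
    bg = set(background)
    dmgs = set(dmg_genes) & bg
    if not set(dmg_genes) <= bg:
        missing = set(dmg_genes) - bg
        raise ValueError(f"{len(missing)} DMGs absent from the background universe")
    names = {}
    if "term_name" in term_map.columns:
        names = dict(zip(term_map["term_id"], term_map["term_name"]))
    tm = term_map[term_map["gene_id"].isin(bg)]
    by_term = tm.groupby("term_id")["gene_id"].agg(set)
    N, n = len(bg), len(dmgs)
    rows = []
    for term_id, genes in by_term.items():
        K = len(genes)
        k = len(genes & dmgs)
        if K < 1 or k < 1:
            continue
        rows.append({"term_id": term_id, "term_name": names.get(term_id, ""),
                     "k": k, "n": n, "K": K, "N": N,
                     "p": hypergeom_upper_tail(k, K, n, N)})
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "n", "K",
                                     "N", "p"])
    if len(df):
        from .dmr import bh_fdr
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] <= q_max
        df = df.sort_values(["q", "p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: list[str]          # input gene order
    order: list[int]           # leaf order (indices into labels)
    linkage: np.ndarray        # scipy linkage matrix (average)
    distances: np.ndarray      # condensed 1 - Pearson distances
    matrix: pd.DataFrame       # log-transformed values, input order
    constant_genes: list[str]  # zero-variance profiles (distance 1 to all)

    def ordered_matrix(self) -> pd.DataFrame:
        return self.matrix.iloc[self.order]

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def _fmt(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return _fmt(tree, tree.dist) + ";"

    def cdt_text(self) -> str:
        buf = io.StringIO()
        cols = list(self.matrix.columns)
        buf.write("GID\tNAME\tGWEIGHT\t" + "\t".join(cols) + "\n")
        buf.write("EWEIGHT\t\t\t" + "\t".join("1" for _ in cols) + "\n")
        for i in self.order:
            vals = "\t".join(f"{v:.6g}" for v in self.matrix.iloc[i])
            buf.write(f"GENE{i}X\t{self.labels[i]}\t1\t{vals}\n")
        return buf.getvalue()

    def gtr_text(self) -> str:
        # Cluster 3.0 GTR: one merge per line, correlation = 1 - distance
        buf = io.StringIO()
        n = len(self.labels)
        node_name = {i: f"GENE{i}X" for i in range(n)}
        for j, (a, b, dist, _) in enumerate(self.linkage):
            name = f"NODE{j + 1}X"
            buf.write(f"{name}\t{node_name[int(a)]}\t{node_name[int(b)]}\t"
                      f"{1.0 - dist:.6g}\n")
            node_name[n + j] = name
        return buf.getvalue()


def cluster_profiles(matrix: pd.DataFrame, eps: float = 0.01) -> ClusterResult:
    """Average-linkage clustering of gene methylation-ratio profiles.

    Rows are genes, columns samples.  Values are transformed
    log2(ratio + eps); distance is 1 - Pearson r between gene profiles.
    Zero-variance profiles get distance 1 to everything (flagged, not an
    error).  Merge order ties break deterministically via scipy's
    (index-ordered) agglomeration.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 gene profiles to cluster")
    values = np.log2(matrix.to_numpy(dtype=float) + eps)
    logged = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    sd = values.std(axis=1)
    constant = sd == 0
    n = len(values)
    dm = np.ones((n, n))
    ok = ~constant
    if ok.sum() >= 2:
        corr = np.corrcoef(values[ok])
        dm[np.ix_(ok, ok)] = 1.0 - corr
    np.fill_diagonal(dm, 0.0)
    condensed = dm[np.triu_indices(n, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    order = list(hierarchy.leaves_list(linkage))
    labels = [str(x) for x in matrix.index]
    return ClusterResult(labels=labels, order=order, linkage=linkage,
                         distances=condensed, matrix=logged,
                         constant_genes=[labels[i] for i in np.nonzero(constant)[0]])


# ---------------------------------------------------------------------------
# functional bin summary
# ---------------------------------------------------------------------------

def mapman_bins(dmg_table: pd.DataFrame, bin_map: pd.DataFrame) -> pd.DataFrame:
    """Per-functional-bin hyper/hypo DMG counts with a net direction.

    ``dmg_table`` needs columns gene_id and direction; ``bin_map`` needs
    gene_id and bin.  Genes absent from the bin map are counted under the
    'unbinned' row.
    """
    gene_bins = dict(zip(bin_map["gene_id"], bin_map["bin"])) if len(bin_map) else {}
    rows: dict[str, dict[str, int]] = {}
    for rec in dmg_table.itertuples(index=False):
        b = gene_bins.get(rec.gene_id, "unbinned")
        slot = rows.setdefault(b, {"hyper": 0, "hypo": 0, "mixed": 0})
        slot[rec.direction] = slot.get(rec.direction, 0) + 1
    out = []
    for b, slot in sorted(rows.items()):
        net = ("hyper" if slot["hyper"] > slot["hypo"]
               else "hypo" if slot["hypo"] > slot["hyper"] else "balanced")
        out.append({"bin": b, "n_hyper": slot["hyper"], "n_hypo": slot["hypo"],
                    "n_mixed": slot["mixed"], "net_direction": net})
    return pd.DataFrame(out, columns=["bin", "n_hyper", "n_hypo", "n_mixed",
                                      "net_direction"])
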
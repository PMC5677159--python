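"""Fully synthetic two-sample bisulfite study with planted ground truth.

The generator emulates a small multi-chromosome plant genome: CpG-island
segments embedded in an i.i.d. background of configurable GC content,
non-overlapping gene models with exon/intron chains on both strands, short
single-exon pre-miRNA loci, and a two-sample methylome whose per-context
mean levels default to the whole-genome levels typical of rice ovules
(mCG ~ 0.40, mCHG ~ 0.32, mCHH ~ 0.14).  Differentially methylated regions
are planted on chosen elements by giving the two samples different
methylation levels there; outside planted elements the samples share one
baseline, so every remaining element is a true null.

Reads follow a directional (Lister-style) protocol: single-end reads are
drawn uniformly from both genome strands, each cytosine of the read's
strand of origin reads C with probability p + (1-p)*conversion_failure and
T otherwise, and independent substitution errors are applied.  An
unmethylated spike-in control sequence provides the substrate for
conversion-rate estimation.  Every generator is a pure function of
(config, seed); read names encode the true origin ("chrom:start:strand:i")
for alignment-recovery tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .elements import GenomeElement, PROMOTER_DOWN, PROMOTER_UP
from .methcall import CODE_NONE, ContextIndex
from .seqio import Gene, MirnaGene, ReadRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")

# fixed stream ids so that each generator draws from its own child stream
_STREAM_GENOME, _STREAM_ANNOT, _STREAM_METH, _STREAM_READS = 1, 2, 3, 4
_STREAM_TERMS, _STREAM_EXPR, _STREAM_CONTROL, _STREAM_CLONES = 5, 6, 7, 8


class ConfigError(ValueError):
    """A configuration field is invalid."""


@dataclass
class DmrPlanEntry:
    """One batch of planted DMRs: ``count`` elements of ``element_type``
    where the two samples get methylation levels ``high``/``low``
    (hyper: interest=high; hypo: interest=low), applied to all contexts."""

    element_type: str
    direction: str  # hyper | hypo
    count: int
    high: float = 0.8
    low: float = 0.2


def default_dmr_plan() -> list[DmrPlanEntry]:
    return [
        DmrPlanEntry("promoter", "hyper", 3),
        DmrPlanEntry("promoter", "hypo", 4),
        DmrPlanEntry("exon", "hyper", 2),
        DmrPlanEntry("exon", "hypo", 2),
        DmrPlanEntry("intron", "hyper", 2),
        DmrPlanEntry("intron", "hypo", 2),
        DmrPlanEntry("intergenic", "hyper", 2),
        DmrPlanEntry("intergenic", "hypo", 2),
        DmrPlanEntry("mirna_promoter", "hyper", 2),
        DmrPlanEntry("mirna_promoter", "hypo", 3),
    ]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic two-sample methylome."""

    n_chromosomes: int = 3
    chrom_length: int = 120_000
    gc_fraction: float = 0.44
    n_cgi_per_chrom: int = 3
    cgi_length: int = 400
    n_genes_per_chrom: int = 8
    exons_per_gene: int = 3
    exon_length: int = 200
    intron_length: int = 150
    n_mirna_per_chrom: int = 4
    mirna_length: int = 120
    context_means: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.40, "CHG": 0.32, "CHH": 0.14})
    beta_concentration: float = 0.5
    dmr_plan: list[DmrPlanEntry] = field(default_factory=default_dmr_plan)
    coverage: float = 30.0
    read_length: int = 100
    conversion_failure: float = 0.005
    seq_error: float = 0.001
    control_length: int = 10_000
    control_coverage: float = 50.0
    n_replicates: int = 1
    samples: tuple[str, str] = ("fsv1", "Gui99")  # (interest, reference)
    seed: int = 0

    def validate(self) -> None:
        for name in ("gc_fraction", "conversion_failure", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for ctx, v in self.context_means.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"context_means[{ctx}] must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ConfigError(f"coverage must be positive, got {self.coverage}")
        if self.chrom_length < 10 * (PROMOTER_UP + PROMOTER_DOWN):
            raise ConfigError(
                f"chrom_length must be at least 10x the promoter span "
                f"({10 * (PROMOTER_UP + PROMOTER_DOWN)}), got {self.chrom_length}")
        if self.read_length > self.chrom_length:
            raise ConfigError("read_length exceeds chrom_length")
        if self.n_chromosomes < 1 or self.n_genes_per_chrom < 0:
            raise ConfigError("counts must be non-negative (>=1 chromosome)")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31), stream])


@dataclass
class PlantedDmr:
    element_id: str
    element_type: str
    chrom: str
    start: int
    end: int
    direction: str
    high: float
    low: float

    @property
    def truth_fold_change(self) -> float:
        return self.high / self.low if self.low > 0 else math.inf


@dataclass
class MethylomeTruth:
    """Simulator-side per-site methylation probabilities and planted DMRs.

    ``probs[sample][chrom]`` holds one float per position: the methylation
    probability at classifiable cytosines, NaN elsewhere.
    """

    samples: tuple[str, str]
    probs: dict[str, dict[str, np.ndarray]]
    planted: list[PlantedDmr]

    def planted_ids(self) -> set[str]:
        return {p.element_id for p in self.planted}

    def planted_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"element_id": p.element_id, "element_type": p.element_type,
              "chrom": p.chrom, "start": p.start, "end": p.end,
              "direction": p.direction, "high": p.high, "low": p.low}
             for p in self.planted],
            columns=["element_id", "element_type", "chrom", "start", "end",
                     "direction", "high", "low"])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _cgi_segment(n: int, rng: np.random.Generator,
                 cg_rate: float = 0.30, gc: float = 0.65) -> np.ndarray:
    """A CpG-rich, GC-rich segment that satisfies the island rule."""
    out = np.empty(n, dtype=np.uint8)
    i = 0
    while i < n:
        if i + 1 < n and rng.random() < cg_rate:
            out[i], out[i + 1] = _C, _G
            i += 2
        else:
            out[i] = rng.choice(_BASES, p=[(1 - gc) / 2, gc / 2, gc / 2,
                                           (1 - gc) / 2])
            i += 1
    return out


def generate_genome(config: SimConfig
                    ) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Synthetic chromosomes plus the truth CpG-island intervals."""
    config.validate()
    rng = config.rng(_STREAM_GENOME)
    genome: dict[str, str] = {}
    cgi_truth: list[tuple[str, int, int]] = []
    margin = 2000
    for c in range(config.n_chromosomes):
        chrom = f"Chr{c + 1}"
        arr = _random_sequence(config.chrom_length, config.gc_fraction, rng)
        # place disjoint island segments with generous spacing
        usable = config.chrom_length - 2 * margin - config.cgi_length
        if config.n_cgi_per_chrom > 0:
            if usable <= 0:
                raise ConfigError("chrom_length too short for the requested CGIs")
            stride = usable // max(config.n_cgi_per_chrom, 1)
            if stride < config.cgi_length + 3000:
                raise ConfigError("n_cgi_per_chrom too dense for chrom_length")
            for k in range(config.n_cgi_per_chrom):
                lo = margin + k * stride
                start = int(rng.integers(lo, lo + stride - config.cgi_length - 3000))
                seg = _cgi_segment(config.cgi_length, rng)
                arr[start:start + config.cgi_length] = seg
                cgi_truth.append((chrom, start, start + config.cgi_length))
        genome[chrom] = arr.tobytes().decode()
    return genome, cgi_truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

class PlacementError(RuntimeError):
    """The genome is too short to place the requested features."""


def generate_annotation(genome: dict[str, str], config: SimConfig
                        ) -> tuple[list[Gene], list[MirnaGene]]:
    """Non-overlapping gene models and miRNA loci with room for promoters."""
    rng = config.rng(_STREAM_ANNOT)
    gene_span = (config.exons_per_gene * config.exon_length
                 + (config.exons_per_gene - 1) * config.intron_length)
    # reserve the full promoter window on either side regardless of strand
    unit = gene_span + PROMOTER_UP + PROMOTER_DOWN + 500
    genes: list[Gene] = []
    mirnas: list[MirnaGene] = []
    for chrom, seq in genome.items():
        length = len(seq)
        n_feat = config.n_genes_per_chrom + config.n_mirna_per_chrom
        if n_feat == 0:
            continue
        stride = (length - 2 * PROMOTER_UP) // n_feat
        if stride < unit:
            raise PlacementError(
                f"{chrom}: cannot place {n_feat} features of span {unit} "
                f"in {length} bp")
        kinds = (["gene"] * config.n_genes_per_chrom
                 + ["mirna"] * config.n_mirna_per_chrom)
        rng.shuffle(kinds)
        for i, kind in enumerate(kinds):
            slot = PROMOTER_UP + i * stride
            jitter = int(rng.integers(0, max(stride - unit, 1)))
            start = slot + jitter + PROMOTER_UP
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "gene":
                gid = f"gene_{chrom}_{len(genes):04d}"
                exons = []
                pos = start
                for _ in range(config.exons_per_gene):
                    exons.append((pos, pos + config.exon_length))
                    pos += config.exon_length + config.intron_length
                end = exons[-1][1]
                if end + PROMOTER_UP > length:
                    raise PlacementError(f"{chrom}: gene {gid} runs past the end")
                genes.append(Gene(gid, chrom, start, end, strand, exons))
            else:
                mid = f"mirna_{chrom}_{len(mirnas):04d}"
                end = start + config.mirna_length
                mirnas.append(MirnaGene(mid, chrom, start, end, strand))
    return genes, mirnas


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

class PlanError(ValueError):
    """The DMR plan requests more elements than exist."""


def generate_methylome(genome: dict[str, str],
                       element_sets: dict[str, list[GenomeElement]],
                       config: SimConfig,
                       context_index: ContextIndex | None = None
                       ) -> MethylomeTruth:
    """Two-sample per-site methylation probabilities with planted DMRs.

    Baseline probabilities are Beta-distributed around the per-context
    means and shared by both samples; planted elements get constant levels
    (``high`` for the hyper sample, ``low`` for the other), so the truth
    ratio fold-change inside a planted element is exactly high/low.

    ``element_sets`` maps element type -> elements (the output of
    ``elements.build_elements`` plus, optionally, "mirna_promoter").
    """
    config.validate()
    rng = config.rng(_STREAM_METH)
    if context_index is None:
        context_index = ContextIndex(genome)
    interest, reference = config.samples
    baseline: dict[str, np.ndarray] = {}
    conc = config.beta_concentration
    for chrom, code in context_index.codes.items():
        probs = np.full(len(code), np.nan)
        for ctx_code, ctx in enumerate(("CG", "CHG", "CHH")):
            mean = config.context_means[ctx]
            idx = np.nonzero(code == ctx_code)[0]
            if mean <= 0.0 or mean >= 1.0:
                probs[idx] = mean
            else:
                probs[idx] = rng.beta(mean * conc, (1 - mean) * conc,
                                      size=len(idx))
        baseline[chrom] = probs
    probs = {interest: {c: a.copy() for c, a in baseline.items()},
             reference: baseline}
    # plant DMRs on disjoint elements
    planted: list[PlantedDmr] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for entry in config.dmr_plan:
        pool = [el for el in element_sets.get(entry.element_type, [])
                if not any(el.start < e and s < el.end
                           for s, e in taken[el.chrom])]
        if len(pool) < entry.count:
            raise PlanError(
                f"dmr_plan requests {entry.count} free {entry.element_type} "
                f"elements, only {len(pool)} available")
        chosen = rng.choice(len(pool), size=entry.count, replace=False)
        for j in sorted(int(x) for x in chosen):
            el = pool[j]
            taken[el.chrom].append((el.start, el.end))
            hi_sample = interest if entry.direction == "hyper" else reference
            lo_sample = reference if entry.direction == "hyper" else interest
            sl = slice(el.start, el.end)
            for sample, level in ((hi_sample, entry.high),
                                  (lo_sample, entry.low)):
                arr = probs[sample][el.chrom][sl]
                arr[~np.isnan(arr)] = level
            planted.append(PlantedDmr(
                element_id=el.id, element_type=entry.element_type,
                chrom=el.chrom, start=el.start, end=el.end,
                direction=entry.direction, high=entry.high, low=entry.low))
    return MethylomeTruth(samples=config.samples, probs=probs, planted=planted)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(genome: dict[str, str], probs: dict[str, np.ndarray],
                   config: SimConfig, rng: np.random.Generator,
                   coverage: float | None = None) -> Iterator[ReadRecord]:
    """Directional single-end bisulfite reads for one sample.

    Read names encode the true origin as ``chrom:start:strand:serial``.
    Watson-origin reads convert their C positions; Crick-origin reads
    convert the Gs of the forward segment (the Crick-strand cytosines) and
    are emitted reverse-complemented.
    """
    cov = config.coverage if coverage is None else coverage
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    bases = {c: np.frombuffer(genome[c].encode(), dtype=np.uint8)
             for c in chroms}
    n_reads = int(round(cov * lengths.sum() / config.read_length))
    chrom_ids = rng.choice(len(chroms), size=n_reads, p=lengths / lengths.sum())
    L = config.read_length
    qual = "I" * L
    fail = config.conversion_failure
    serial = 0
    for ci in chrom_ids:
        chrom = chroms[ci]
        arr = bases[chrom]
        start = int(rng.integers(0, len(arr) - L + 1))
        watson = bool(rng.random() < 0.5)
        seg = arr[start:start + L].copy()
        p_arr = probs[chrom][start:start + L]
        target, meth_base, unmeth_base = ((_C, _C, _T) if watson
                                          else (_G, _G, _A))
        cmask = seg == target
        if cmask.any():
            p = np.nan_to_num(p_arr[cmask], nan=0.0)
            p_eff = p + (1.0 - p) * fail
            keep = rng.random(int(cmask.sum())) < p_eff
            seg[cmask] = np.where(keep, meth_base, unmeth_base)
        if config.seq_error > 0:
            err = rng.random(L) < config.seq_error
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                # rotate within ACGT to guarantee a different base
                cur = np.searchsorted(_BASES, seg[err])
                seg[err] = _BASES[(cur + shift) % 4]
        seq = seg.tobytes().decode()
        if not watson:
            seq = revcomp(seq)
        strand = "+" if watson else "-"
        yield ReadRecord(f"{chrom}:{start}:{strand}:{serial}", seq, qual)
        serial += 1


def make_control(config: SimConfig) -> str:
    """The unmethylated spike-in control sequence."""
    rng = config.rng(_STREAM_CONTROL)
    return _random_sequence(config.control_length, config.gc_fraction,
                            rng).tobytes().decode()


def simulate_control_reads(control: str, config: SimConfig,
                           rng: np.random.Generator) -> Iterator[ReadRecord]:
    """Reads from the fully unmethylated control at the control coverage."""
    zeros = {"control": np.zeros(len(control))}
    yield from simulate_reads({"control": control}, zeros, config, rng,
                              coverage=config.control_coverage)


# ---------------------------------------------------------------------------
# term maps and expression tables
# ---------------------------------------------------------------------------

@dataclass
class EnrichedTermSpec:
    """Plant one term enriched in a designated gene subset."""

    term_id: str
    subset: Sequence[str]
    n_carriers: int
    odds_ratio: float = 8.0


def generate_term_map(genes: Sequence[str], n_terms: int = 20,
                      mean_terms_per_gene: float = 2.0,
                      enriched: EnrichedTermSpec | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Random flat gene->term annotations, optionally with a planted
    enriched term whose carriers favour the designated subset at the
    configured odds ratio."""
    rng = np.random.default_rng([int(seed) % (2 ** 31), _STREAM_TERMS])
    genes = list(genes)
    terms = [f"TERM{i:04d}" for i in range(n_terms)]
    rows = []
    for g in genes:
        k = min(rng.poisson(mean_terms_per_gene), n_terms)
        for t in rng.choice(n_terms, size=k, replace=False):
            rows.append({"gene_id": g, "term_id": terms[t]})
    if enriched is not None:
        subset = set(enriched.subset)
        if not subset <= set(genes):
            raise ValueError("enriched subset must be contained in the universe")
        if enriched.n_carriers > len(genes):
            raise ValueError("enriched term has more carriers than the universe")
        weights = np.array([enriched.odds_ratio if g in subset else 1.0
                            for g in genes])
        weights /= weights.sum()
        carriers = rng.choice(len(genes), size=enriched.n_carriers,
                              replace=False, p=weights)
        for i in carriers:
            rows.append({"gene_id": genes[int(i)],
                         "term_id": enriched.term_id})
    df = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    return df.drop_duplicates().sort_values(
        ["term_id", "gene_id"], kind="stable").reset_index(drop=True)


def generate_expression_tables(
        mirna_directions: Sequence[tuple[str, str]],
        target_map: dict[str, str],
        coherence: float = 0.8,
        background_genes: Sequence[str] = (),
        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(miRNA expression, gene expression, miRNA->target map) TScolumns.

    For each (mirna, promoter_direction) a coherent triple is emitted with
    probability ``coherence``: hypo promoter -> miRNA up & target down,
    hyper promoter -> miRNA down & target up.  Incoherent triples flip the
    miRNA sign.  Background genes get small random fold-changes.
    """
    rng = np.random.default_rng([int(seed) % (2 ** 31), _STREAM_EXPR])
    mirna_rows, gene_fc, tgt_rows = [], {}, []
    for mirna, pdir in mirna_directions:
        coherent = bool(rng.random() < coherence)
        up = (pdir == "hypo") if coherent else (pdir != "hypo")
        m_fc = float(rng.uniform(1.0, 3.0)) * (1 if up else -1)
        target = target_map.get(mirna)
        mirna_rows.append({"mirna": mirna, "log2fc": m_fc})
        if target is not None:
            t_fc = float(rng.uniform(0.5, 2.0))
            # the coherent target moves opposite to the miRNA
            gene_fc[target] = -t_fc if m_fc > 0 else t_fc
            tgt_rows.append({"mirna": mirna, "gene_id": target})
    for g in background_genes:
        gene_fc.setdefault(g, float(rng.normal(0.0, 0.3)))
    mirna_df = pd.DataFrame(mirna_rows, columns=["mirna", "log2fc"])
    gene_df = pd.DataFrame(
        [{"gene_id": g, "log2fc": v} for g, v in gene_fc.items()],
        columns=["gene_id", "log2fc"])
    tgt_df = pd.DataFrame(tgt_rows, columns=["mirna", "gene_id"])
    return mirna_df, gene_df, tgt_df


# ---------------------------------------------------------------------------
# bisulfite-PCR clones
# ---------------------------------------------------------------------------

def simulate_clones(genome: dict[str, str], probs: dict[str, np.ndarray],
                    chrom: str, start: int, length: int,
                    n_clones: int = 15,
                    conversion_failure: float = 0.005,
                    rng: np.random.Generator | None = None,
                    seed: int = 0) -> list[str]:
    """Sanger clones of one bisulfite amplicon (Watson strand).

    Each clone converts the amplicon's C positions independently using the
    same per-site truth probabilities as the WGBS reads.
    """
    if rng is None:
        rng = np.random.default_rng([int(seed) % (2 ** 31), _STREAM_CLONES])
    seg = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)[
        start:start + length]
    p_arr = np.nan_to_num(probs[chrom][start:start + length], nan=0.0)
    cmask = seg == _C
    p_eff = p_arr[cmask] + (1.0 - p_arr[cmask]) * conversion_failure
    clones = []
    for _ in range(n_clones):
        clone = seg.copy()
        keep = rng.random(int(cmask.sum())) < p_eff
        clone[cmask] = np.where(keep, _C, _T)
        clones.append(clone.tobytes().decode())
    return clones
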
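"""Sequence/annotation I/O and a naive bisulfite-aware unique aligner.

All internal coordinates are 0-based half-open.  Conversion to and from the
1-based inclusive convention happens only at the GFF3 boundary; BED and
bedGraph are written 0-based half-open as their formats require.

The aligner is a deliberately simple replacement for a production bisulfite
mapper: reads and both genome strands are reduced to a three-letter alphabet
(C->T on the respective sense), candidate loci are found by an exact seed
match on the first ``seed_length`` reduced bases, and candidates are scored
by Hamming distance in reduced space.  A read is *uniquely* mapped iff
exactly one locus attains the best score within the mismatch budget.  Only
substitutions are modelled (no indels, single-end only).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_C_TO_T = str.maketrans("C", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed record in an input file."""


class ValidationError(ValueError):
    """A record is inconsistent with the genome it refers to."""


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (Phred+33 qualities)."""

    id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(ord(c) - 33 for c in self.qualities) / len(self.qualities)

    def n_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        return self.sequence.upper().count("N") / len(self.sequence)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    with open(path) as handle:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
            try:
                yield ReadRecord(title.split()[0], seq.upper(), qual)
            except FormatError as exc:  # re-raise with the record index
                raise FormatError(f"FASTQ record {i}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


# ---------------------------------------------------------------------------
# read QC
# ---------------------------------------------------------------------------

@dataclass
class QCStats:
    raw: int = 0
    clean: int = 0
    dropped_n: int = 0
    dropped_quality: int = 0
    adapter_trimmed: int = 0


def _trim_adapter(seq: str, qual: str, adapter: str, min_match: int = 8) -> tuple[str, str, bool]:
    """Trim an exact 3' match to a prefix of ``adapter`` of >= min_match bases.

    The leftmost suffix of the read that equals an adapter prefix is removed.
    """
    n = len(seq)
    for i in range(0, n - min_match + 1):
        tail = n - i
        if tail <= len(adapter) and seq[i:] == adapter[:tail]:
            return seq[:i], qual[:i], True
        if tail > len(adapter) and seq[i:i + len(adapter)] == adapter:
            # full adapter inside the read: drop it and everything 3' of it
            return seq[:i], qual[:i], True
    return seq, qual, False


def qc_filter(
    reads: Iterable[ReadRecord],
    max_n_fraction: float = 0.10,
    min_mean_quality: float = 20.0,
    adapter: str | None = None,
) -> tuple[list[ReadRecord], QCStats]:
    """Drop reads with too many Ns or low mean quality; trim 3' adapters."""
    stats = QCStats()
    kept: list[ReadRecord] = []
    for read in reads:
        stats.raw += 1
        seq, qual = read.sequence, read.qualities
        if adapter:
            seq, qual, trimmed = _trim_adapter(seq, qual, adapter)
            if trimmed:
                stats.adapter_trimmed += 1
        if not seq:
            stats.dropped_quality += 1
            continue
        cand = ReadRecord(read.id, seq, qual)
        if cand.n_fraction() > max_n_fraction:
            stats.dropped_n += 1
            continue
        if cand.mean_quality() < min_mean_quality:
            stats.dropped_quality += 1
            continue
        stats.clean += 1
        kept.append(cand)
    return kept, stats


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A gap-free placement of a bisulfite read on the genome.

    ``strand`` is the genome strand the read originates from ('+' Watson,
    '-' Crick).  ``seq_fw`` is the read sequence in genome-forward
    orientation (reverse-complemented for Crick-origin reads), so that
    downstream pileup can compare it base-by-base with the reference.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    seq_fw: str
    mismatches: int
    is_unique: bool

    @property
    def end(self) -> int:
        return self.start + len(self.seq_fw)


@dataclass
class MappingStats:
    clean: int = 0
    mapped: int = 0
    unique: int = 0

    @property
    def mapping_rate(self) -> float:
        """Percent of clean reads mapped (exact, before rounding)."""
        return 100.0 * self.mapped / self.clean if self.clean else 0.0

    @property
    def unique_rate(self) -> float:
        return 100.0 * self.unique / self.clean if self.clean else 0.0


class BisulfiteAligner:
    """Three-letter-alphabet unique aligner for directional bisulfite reads.

    Watson-origin reads are matched against the C->T-reduced forward genome;
    Crick-origin reads against the C->T-reduced reverse complement.
    """

    def __init__(self, genome: dict[str, str], seed_length: int = 24,
                 max_mismatches: int = 4):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValidationError("cannot index an empty genome")
        self.seed_length = int(seed_length)
        self.max_mismatches = int(max_mismatches)
        self.chroms = list(genome)
        self.lengths = {c: len(s) for c, s in genome.items()}
        # reduced references as uint8 arrays, per (chrom, strand)
        self._ref: list[np.ndarray] = []
        self._meta: list[tuple[str, str, int]] = []  # (chrom, strand, length)
        index: dict[str, list[tuple[int, int]]] = {}
        k = self.seed_length
        for chrom, seq in genome.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                red = s.upper().translate(_C_TO_T)
                ref_id = len(self._ref)
                self._ref.append(np.frombuffer(red.encode(), dtype=np.uint8))
                self._meta.append((chrom, strand, len(s)))
                for pos in range(0, len(red) - k + 1):
                    index.setdefault(red[pos:pos + k], []).append((ref_id, pos))
        self._index = index

    def align_read(self, read_id: str, seq: str) -> Alignment | None:
        """Align one read; None if unmapped, ``is_unique=False`` on ties."""
        seq = seq.upper()
        if len(seq) < self.seed_length:
            return None
        red = seq.translate(_C_TO_T)
        candidates = self._index.get(red[:self.seed_length])
        if not candidates:
            return None
        arr = np.frombuffer(red.encode(), dtype=np.uint8)
        n = len(arr)
        best_mm = self.max_mismatches + 1
        best_hit: tuple[int, int] | None = None
        n_best = 0
        for ref_id, pos in candidates:
            ref = self._ref[ref_id]
            if pos + n > len(ref):
                continue
            mm = int(np.count_nonzero(ref[pos:pos + n] != arr))
            if mm < best_mm:
                best_mm, best_hit, n_best = mm, (ref_id, pos), 1
            elif mm == best_mm:
                n_best += 1
        if best_hit is None or best_mm > self.max_mismatches:
            return None
        ref_id, pos = best_hit
        chrom, strand, length = self._meta[ref_id]
        if strand == "+":
            start, seq_fw = pos, seq
        else:
            start, seq_fw = length - pos - n, revcomp(seq)
        return Alignment(read_id, chrom, start, strand, seq_fw, best_mm,
                         is_unique=(n_best == 1))

    def align(self, reads: Iterable[ReadRecord]) -> tuple[list[Alignment], MappingStats]:
        stats = MappingStats()
        out: list[Alignment] = []
        for read in reads:
            stats.clean += 1
            aln = self.align_read(read.id, read.sequence)
            if aln is None:
                continue
            stats.mapped += 1
            if aln.is_unique:
                stats.unique += 1
            out.append(aln)
        return out, stats


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def write_sam(alignments: Iterable[Alignment], genome: dict[str, str],
              path: str | Path) -> None:
    """Write alignments as SAM (unique: MAPQ 42; ambiguous: MAPQ 0)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    }
    tid = {c: i for i, c in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.seq_fw
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_id = tid[aln.chrom]
            seg.reference_start = aln.start
            seg.mapping_quality = 42 if aln.is_unique else 0
            seg.cigarstring = f"{len(aln.seq_fw)}M"
            seg.set_tag("NM", aln.mismatches)
            out.write(seg)


def read_sam(path: str | Path, genome: dict[str, str] | None = None,
             mapq_min: int = 20) -> list[Alignment]:
    """Import SAM alignments from an external mapper.

    Secondary/supplementary/unmapped records are discarded; records with
    MAPQ >= ``mapq_min`` are treated as uniquely mapped (the surrogate for
    an aligner's own uniqueness call).
    """
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            seq = rec.query_sequence or ""
            if genome is not None:
                if chrom not in genome:
                    raise ValidationError(f"SAM record {rec.query_name}: unknown chromosome {chrom}")
                if rec.reference_start + len(seq) > len(genome[chrom]):
                    raise ValidationError(
                        f"SAM record {rec.query_name}: alignment extends past end of {chrom}")
            out.append(Alignment(
                read_id=rec.query_name,
                chrom=chrom,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                seq_fw=seq.upper(),
                mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                is_unique=rec.mapping_quality >= mapq_min,
            ))
    return out


# ---------------------------------------------------------------------------
# gene models / GFF3
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    """A protein-coding gene model with an exon chain.

    ``exons`` are genomic intervals sorted by coordinate; ``tss`` is the
    transcription start (0-based position of the first transcribed base).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


@dataclass
class MirnaGene:
    """A pre-miRNA locus (short, single exon)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def write_gff3(genes: Sequence[Gene], mirnas: Sequence[MirnaGene],
               path: str | Path) -> None:
    """Emit gene and miRNA models as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tovulemeth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}\n")
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(f"{g.chrom}\tovulemeth\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.id}.exon{i};Parent={g.id}\n")
        for m in mirnas:
            fh.write(f"{m.chrom}\tovulemeth\tmiRNA\t{m.start + 1}\t{m.end}\t.\t"
                     f"{m.strand}\t.\tID={m.id}\n")


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        k, _, v = part.partition("=")
        if k.strip() == key:
            return v.strip()
    return None


def read_gff3(path: str | Path,
              chrom_lengths: dict[str, int] | None = None
              ) -> tuple[list[Gene], list[MirnaGene]]:
    """Read gene/exon/miRNA features back into the internal convention."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attrs"],
        dtype={"chrom": str, "type": str, "attrs": str},
    )
    genes: dict[str, Gene] = {}
    mirnas: list[MirnaGene] = []
    for row in df.itertuples(index=False):
        start0, end = int(row.start) - 1, int(row.end)
        if start0 < 0 or (chrom_lengths and end > chrom_lengths.get(row.chrom, end)):
            raise ValidationError(f"GFF3 feature outside chromosome: {row}")
        ident = _gff_attr(row.attrs, "ID") or ""
        if row.type == "gene":
            genes[ident] = Gene(ident, row.chrom, start0, end, row.strand)
        elif row.type == "exon":
            parent = _gff_attr(row.attrs, "Parent")
            if parent not in genes:
                raise FormatError(f"exon {ident} references unknown gene {parent}")
            genes[parent].exons.append((start0, end))
        elif row.type == "miRNA":
            mirnas.append(MirnaGene(ident, row.chrom, start0, end, row.strand))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values()), mirnas


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end, name, score...) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(track: Iterable[tuple[str, int, int, float]],
                   path: str | Path, name: str | None = None) -> None:
    """Write a (chrom, start, end, value) track, 0-based half-open."""
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, start, end, value in track:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)
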
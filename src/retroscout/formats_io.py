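"""Standard-format I/O and the package's core genomic types.

All coordinates held in memory are 0-based half-open on the forward genome
strand; conversions to the 1-based conventions of GFF3 and SAM happen only
at the I/O boundary.  Only the match/clip/indel CIGAR alphabet (M, S, I, D)
is accepted — spliced or hard-clipped records are outside the DNA-read scope
of this pipeline and rejected with a clear error.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

STRANDS = {"+", "-", "."}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file or contract violation at an I/O boundary."""


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one transcript of an annotated gene.

    ``exons`` are ordered 5'->3' in *transcript* orientation (for a
    minus-strand gene the first exon is the genomically rightmost one).
    ``cds_offset``/``cds_length`` locate the coding sequence within the
    spliced transcript, when annotated.
    """

    gene_id: str
    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    strand: str
    cds_offset: int | None = None
    cds_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("gene strand must be + or -")
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start or a.chrom != b.chrom:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or span chromosomes"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != self.exons:
            raise ValueError(
                f"exons of {self.transcript_id} not in transcript orientation"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint from first to last exon."""
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def exon_offsets(self) -> list[int]:
        """Cumulative transcript offset of the start of each exon."""
        offs, total = [], 0
        for e in self.exons:
            offs.append(total)
            total += len(e)
        return offs

    def genomic_position(self, offset: int) -> int:
        """Genomic coordinate of a transcript offset (0-based)."""
        if not 0 <= offset < self.spliced_length:
            raise ValueError(f"transcript offset {offset} out of range")
        for start, exon in zip(self.exon_offsets(), self.exons):
            if start <= offset < start + len(exon):
                within = offset - start
                if self.strand == "+":
                    return exon.start + within
                return exon.end - 1 - within
        raise AssertionError("unreachable")

    def transcript_offset(self, chrom: str, pos: int) -> int | None:
        """Transcript offset of a genomic position, or None if intronic."""
        for start, exon in zip(self.exon_offsets(), self.exons):
            if exon.contains(chrom, pos):
                if self.strand == "+":
                    return start + (pos - exon.start)
                return start + (exon.end - 1 - pos)
        return None


@dataclass
class AlignedRead:
    """One SAM alignment record in internal coordinates.

    ``start``/``end`` span the reference bases consumed by M/D operations;
    soft-clipped tails are recorded with their sequence so breakpoint logic
    can use them directly.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    is_reverse: bool
    seq: str
    cigar: tuple[tuple[str, int], ...]
    left_clip: int = 0
    right_clip: int = 0
    is_proper_pair: bool = False
    is_paired: bool = False
    is_read1: bool = True
    mate_chrom: str | None = None
    mate_start: int | None = None
    mate_is_reverse: bool = False
    tlen: int = 0
    sample_id: str = ""
    mapq: int = 60

    @property
    def left_clip_seq(self) -> str:
        return self.seq[: self.left_clip]

    @property
    def right_clip_seq(self) -> str:
        return self.seq[len(self.seq) - self.right_clip :]

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


_ALLOWED_CIGAR = set("MSID")


def cigar_from_string(cigar: str) -> tuple[tuple[str, int], ...]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch not in _ALLOWED_CIGAR:
                raise FormatError(
                    f"unsupported CIGAR op {ch!r} (only M/S/I/D handled)"
                )
            ops.append((ch, int(num)))
            num = ""
    if num:
        raise FormatError(f"trailing digits in CIGAR {cigar!r}")
    return tuple(ops)


def cigar_to_string(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: uppercase sequence}`` map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | os.PathLike,
    seq_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModels.

    GFF3 1-based closed coordinates become 0-based half-open.  Exons are
    grouped per transcript and ordered 5'->3' in transcript orientation.
    """
    with open(path) as fh:
        text = fh.read()
    db = gffutils.create_db(
        text, ":memory:", from_string=True, merge_strategy="create_unique",
        keep_order=True,
    )
    transcript_ids = {f.id for f in db.features_of_type("mRNA")}
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = []
        for ex in db.children(mrna, featuretype="exon", order_by="start"):
            iv = GenomicInterval(ex.seqid, ex.start - 1, ex.end, mrna.strand)
            if seq_lengths is not None:
                if ex.seqid not in seq_lengths or iv.end > seq_lengths[ex.seqid]:
                    raise FormatError(
                        f"exon {ex.seqid}:{ex.start}-{ex.end} outside chromosome bounds"
                    )
            exons.append(iv)
        if not exons:
            continue
        if mrna.strand == "-":
            exons = exons[::-1]
        model = GeneModel(gene_id, mrna.id, tuple(exons), mrna.strand)
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if cds:
            cds_len = sum(c.end - c.start + 1 for c in cds)
            if mrna.strand == "+":
                first = min(c.start for c in cds) - 1
                off = model.transcript_offset(mrna.seqid, first)
            else:
                last = max(c.end for c in cds) - 1
                off = model.transcript_offset(mrna.seqid, last)
            model = replace(model, cds_offset=off, cds_length=cds_len)
        models.append(model)
    # orphan exons: exon features whose Parent is not a known mRNA
    for feat in db.features_of_type("exon"):
        for parent in feat.attributes.get("Parent", []):
            if parent not in transcript_ids:
                raise FormatError(
                    f"orphan exon with Parent={parent!r} (no such mRNA)"
                )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Emit gene/mRNA/exon (and CDS when annotated) features in GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id, ms in by_gene.items():
            chrom = ms[0].chrom
            strand = ms[0].strand
            start = min(m.span.start for m in ms)
            end = max(m.span.end for m in ms)
            fh.write(
                f"{chrom}\tretroscout\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for m in ms:
                fh.write(
                    f"{chrom}\tretroscout\tmRNA\t{m.span.start + 1}\t{m.span.end}\t.\t"
                    f"{strand}\t.\tID={m.transcript_id};Parent={gene_id}\n"
                )
                for i, e in enumerate(sorted(m.exons, key=lambda e: e.start)):
                    fh.write(
                        f"{chrom}\tretroscout\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{strand}\t.\tID={m.transcript_id}.exon{i + 1};"
                        f"Parent={m.transcript_id}\n"
                    )
                if m.cds_offset is not None and m.cds_length is not None:
                    for s, e2 in _cds_genomic_blocks(m):
                        fh.write(
                            f"{chrom}\tretroscout\tCDS\t{s + 1}\t{e2}\t.\t{strand}\t0\t"
                            f"ID={m.transcript_id}.cds;Parent={m.transcript_id}\n"
                        )


def _cds_genomic_blocks(m: GeneModel) -> list[tuple[int, int]]:
    """Genomic (start, end) blocks covered by the CDS, sorted by start."""
    assert m.cds_offset is not None and m.cds_length is not None
    blocks = []
    for off, exon in zip(m.exon_offsets(), m.exons):
        lo = max(m.cds_offset, off)
        hi = min(m.cds_offset + m.cds_length, off + len(exon))
        if lo >= hi:
            continue
        if m.strand == "+":
            s = exon.start + (lo - off)
            blocks.append((s, s + (hi - lo)))
        else:
            e = exon.end - (lo - off)
            blocks.append((e - (hi - lo), e))
    return sorted(blocks)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _cigar_ref_len(cigar: Sequence[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in "MD")


def _cigar_read_len(cigar: Sequence[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in "MSI")


def _checked(sam: "pysam.AlignmentFile") -> Iterator:
    """Surface htslib parse failures (e.g. CIGAR/SEQ length mismatch) as
    FormatError instead of raw OSError."""
    it = iter(sam)
    while True:
        try:
            yield next(it)
        except StopIteration:
            return
        except OSError as e:
            raise FormatError(f"malformed SAM record: {e}") from e


def read_sam(path: str | os.PathLike, sample_id: str = "") -> Iterator[AlignedRead]:
    """Stream mapped SAM records as AlignedReads (0-based coordinates)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        records = _checked(sam)
        for rec in records:
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            cigar = cigar_from_string(rec.cigarstring)
            seq = rec.query_sequence or ""
            if _cigar_read_len(cigar) != len(seq):
                raise FormatError(
                    f"CIGAR/sequence length mismatch for read {rec.query_name}"
                )
            left = cigar[0][1] if cigar[0][0] == "S" else 0
            right = cigar[-1][1] if cigar[-1][0] == "S" else 0
            yield AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_start + _cigar_ref_len(cigar),
                is_reverse=rec.is_reverse,
                seq=seq,
                cigar=cigar,
                left_clip=left,
                right_clip=right,
                is_proper_pair=rec.is_proper_pair,
                is_paired=rec.is_paired,
                is_read1=not rec.is_read2,
                mate_chrom=rec.next_reference_name if not rec.mate_is_unmapped else None,
                mate_start=rec.next_reference_start if not rec.mate_is_unmapped else None,
                mate_is_reverse=rec.mate_is_reverse,
                tlen=rec.template_length,
                sample_id=sample_id,
            )


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | os.PathLike,
    seq_lengths: Mapping[str, int],
) -> None:
    """Write AlignedReads as a text SAM file with a proper @SQ header."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in seq_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        refs = {name: i for i, name in enumerate(seq_lengths)}
        for r in sorted(reads, key=lambda r: (refs.get(r.chrom, 1 << 30), r.start)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.reference_id = refs[r.chrom]
            a.reference_start = r.start
            a.cigarstring = cigar_to_string(r.cigar)
            a.mapping_quality = r.mapq
            flag = 0
            if r.is_paired:
                flag |= 0x1
                flag |= 0x40 if r.is_read1 else 0x80
                if r.is_proper_pair:
                    flag |= 0x2
                if r.mate_is_reverse:
                    flag |= 0x20
                if r.mate_chrom is None:
                    flag |= 0x8
            if r.is_reverse:
                flag |= 0x10
            a.flag = flag
            if r.mate_chrom is not None:
                a.next_reference_id = refs[r.mate_chrom]
                a.next_reference_start = r.mate_start or 0
                a.template_length = r.tlen
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            out.write(a)


# ---------------------------------------------------------------------------
# BED / VCF / TSV helpers
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[GenomicInterval, str]], path: str | os.PathLike) -> None:
    """6-column BED (name + strand; score fixed at 0)."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


@dataclass
class VcfRecord:
    chrom: str
    pos: int  # 0-based internally; written 1-based
    ref: str
    alt: str
    id: str = "."
    qual: str = "."
    filter: str = "PASS"
    info: dict[str, str] = field(default_factory=dict)


def write_vcf(records: Iterable[VcfRecord], path: str | os.PathLike) -> None:
    """Minimal VCF 4.2 emission (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=retroscout\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = ";".join(f"{k}={v}" for k, v in r.info.items()) or "."
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.id}\t{r.ref}\t{r.alt}\t{r.qual}\t"
                f"{r.filter}\t{info}\n"
            )


def read_vcf(path: str | os.PathLike) -> list[VcfRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, vid, ref, alt, qual, filt, info = line.rstrip("\n").split("\t")[:8]
            d = {}
            if info != ".":
                for kv in info.split(";"):
                    k, _, v = kv.partition("=")
                    d[k] = v
            out.append(VcfRecord(chrom, int(pos) - 1, ref, alt, vid, qual, filt, d))
    return out
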
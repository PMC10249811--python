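"""Synthetic genomes with implanted retrocopies, and truth-guided reads.

The generator builds a toy reference (multi-exon genes with >=200 bp
introns), implants intron-less poly(A)-tailed retrocopies flanked by target
site duplications (TSDs), optionally amplifies a segment to N tandem copies
with shared and per-copy private substitutions, and emits paired-end reads.

Alignments are emitted from simulation truth rather than by running an
aligner: every base of the modified (sample) genome carries a record of
where it came from, so a read is aligned the way a short-read mapper would
place it against the *unmodified* reference — reads straddling an insertion
breakpoint are soft-clipped at the junction, and reads from inside a
retrocopy are placed on the parent gene's exons (the mismapping that makes
retroCNVs visible in real data).
"""

from __future__ import annotations

import bisect
import csv
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import AlignedRead, GeneModel, GenomicInterval, revcomp

BASES = np.array(list("ACGT"))

TSD_RANGE = (10, 31)  # observed TSD length range in equid retroCNVs


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Knobs of the toy study. Defaults mirror the study conditions:
    ~20x paired-end coverage, 100 bp reads, 0.2% base error."""

    seed: int = 0
    genome_length: int = 200_000
    n_chroms: int = 2
    n_genes: int = 8
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (90, 300)
    intron_length: tuple[int, int] = (200, 800)
    gc_content: float = 0.42
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    coverage: float = 20.0
    error_rate: float = 0.002

    def validate(self) -> None:
        if self.genome_length <= 0 or self.n_genes < 0 or self.n_chroms < 1:
            raise SimulationError("genome_length/n_genes/n_chroms must be positive")
        if not 0 <= self.error_rate < 0.05:
            raise SimulationError("error_rate must be in [0, 0.05)")
        if self.coverage <= 0:
            raise SimulationError("coverage must be > 0")
        if self.read_length > self.insert_mean:
            raise SimulationError("read_length exceeds mean insert size")
        if not 0 < self.gc_content < 1:
            raise SimulationError("gc_content must be a fraction")


@dataclass
class RetrocopyTruth:
    """Ground truth of one implanted retrocopy insertion."""

    gene_id: str
    site: int  # 0-based insertion point on the target chromosome (reference coords)
    chrom: str
    skipped_exons: frozenset[int] = frozenset()
    polyA_length: int = 30
    five_prime_truncation: int = 0
    tsd_length: int = 17
    tsd_sequence: str = ""
    strand: str = "+"
    copy_count: int = 1
    shared_variants: tuple[tuple[int, str, str], ...] = ()  # (transcript offset, ref, alt)
    private_variants: tuple[tuple[tuple[int, str, str], ...], ...] = ()
    inserted_length: int = 0

    @property
    def insertion_interval(self) -> GenomicInterval:
        """The duplicated target site [site - tsd_length, site)."""
        start = self.site - max(self.tsd_length, 1)
        return GenomicInterval(self.chrom, start, self.site)


@dataclass
class LineageSimSpec:
    """Molecular-clock simulation of post-insertion divergence."""

    target_age: float  # years
    mutation_rate: float = 7.24e-9  # substitutions/site/generation
    generation_time: float = 8.0  # years
    lineage_factor: int = 1  # 1 or 2 diverging lineages
    length: int = 2000

    def validate(self) -> None:
        if self.mutation_rate <= 0 or self.generation_time <= 0 or self.length <= 0:
            raise SimulationError("mutation_rate, generation_time, length must be > 0")
        if self.lineage_factor not in (1, 2):
            raise SimulationError("lineage_factor must be 1 or 2")
        if self.target_age < 0:
            raise SimulationError("target_age must be >= 0")

    @property
    def expected_substitutions(self) -> float:
        return (
            self.length
            * self.mutation_rate
            * self.lineage_factor
            * self.target_age
            / self.generation_time
        )


# ---------------------------------------------------------------------------
# Reference genome generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random reference with non-overlapping multi-exon genes.

    Genes are placed on every chromosome except the last, which is left
    gene-free as insertion target space. Deterministic for a fixed seed.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chroms
    genome = {
        f"chr{i + 1}": _random_seq(rng, chrom_len, config.gc_content)
        for i in range(config.n_chroms)
    }
    gene_chroms = list(genome)[:-1] if config.n_chroms > 1 else list(genome)
    models: list[GeneModel] = []
    per_chrom = math.ceil(config.n_genes / len(gene_chroms))
    gene_no = 0
    for chrom in gene_chroms:
        cursor = 300
        for _ in range(per_chrom):
            if gene_no >= config.n_genes:
                break
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
            in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, n_ex - 1) if n_ex > 1 else []
            span = int(np.sum(ex_lens) + np.sum(in_lens))
            gap = int(rng.integers(400, 1200))
            start = cursor + gap
            if start + span > chrom_len - 300:
                raise SimulationError(
                    f"genome too small to place {config.n_genes} genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            exons, pos = [], start
            for i, ln in enumerate(ex_lens):
                exons.append(GenomicInterval(chrom, pos, pos + int(ln), strand))
                pos += int(ln)
                if i < n_ex - 1:
                    pos += int(in_lens[i])
            if strand == "-":
                exons = exons[::-1]
            gene_no += 1
            gid = f"gene{gene_no}"
            spliced = sum(len(e) for e in exons)
            cds_off = 10 if spliced > 50 else 0
            cds_len = ((spliced - cds_off - 20) // 3) * 3
            models.append(
                GeneModel(gid, f"{gid}.t1", tuple(exons), strand,
                          cds_offset=cds_off, cds_length=max(cds_len, 3))
            )
            cursor = start + span
    if gene_no < config.n_genes:
        raise SimulationError(f"genome too small to place {config.n_genes} genes")
    return genome, models


def extract_transcript(genome: Mapping[str, str], gene: GeneModel) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation."""
    chrom_seq = genome[gene.chrom]
    parts = []
    for e in gene.exons:
        if e.end > len(chrom_seq):
            raise SimulationError(f"exon {e} beyond chromosome end")
        seg = chrom_seq[e.start : e.end]
        parts.append(seg if gene.strand == "+" else revcomp(seg))
    return "".join(parts)


# ---------------------------------------------------------------------------
# The block map: sample genome -> reference provenance
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    length: int
    kind: str  # 'ref' | 'retro' | 'none'
    # ref: (ref_chrom, ref_start); retro: (gene, t0, step); none: None
    payload: object = None


@dataclass
class _Emitted:
    """Where a window of the sample genome lands on the reference."""

    mapped: bool
    chrom: str = ""
    pos: int = 0
    cigar: tuple[tuple[str, int], ...] = ()
    flip: bool = False  # True: window aligns to the reference minus strand


class ImplantedGenome:
    """A sample genome derived from a reference by retrocopy insertion,
    segmental amplification, and deletion — with per-base provenance."""

    def __init__(self, reference: Mapping[str, str], genes: Sequence[GeneModel]):
        self.ref = dict(reference)
        self.genes = {g.gene_id: g for g in genes}
        self.seqs: dict[str, str] = dict(reference)
        self.blocks: dict[str, list[_Block]] = {
            c: [_Block(len(s), "ref", (c, 0))] for c, s in reference.items()
        }
        self.truths: list[RetrocopyTruth] = []

    # -- block bookkeeping --------------------------------------------------

    def _starts(self, chrom: str) -> list[int]:
        starts, t = [], 0
        for b in self.blocks[chrom]:
            starts.append(t)
            t += b.length
        return starts

    def _split_at(self, chrom: str, pos: int) -> int:
        """Ensure a block boundary at mod position ``pos``; return block index."""
        blocks = self.blocks[chrom]
        starts = self._starts(chrom)
        if pos == sum(b.length for b in blocks):
            return len(blocks)
        i = bisect.bisect_right(starts, pos) - 1
        off = pos - starts[i]
        if off == 0:
            return i
        b = blocks[i]
        left = _Block(off, b.kind, b.payload)
        right_payload = b.payload
        if b.kind == "ref":
            c, s = b.payload
            right_payload = (c, s + off)
        elif b.kind == "retro":
            g, t0, step = b.payload
            right_payload = (g, t0 + step * off, step)
        right = _Block(b.length - off, b.kind, right_payload)
        blocks[i : i + 1] = [left, right]
        return i + 1

    def mod_position_of_ref(self, chrom: str, ref_pos: int) -> int:
        """Sample-genome coordinate of a reference base (first occurrence)."""
        t = 0
        for b in self.blocks[chrom]:
            if b.kind == "ref":
                c, s = b.payload
                if c == chrom and s <= ref_pos < s + b.length:
                    return t + (ref_pos - s)
            t += b.length
        raise SimulationError(f"reference position {chrom}:{ref_pos} not present")

    # -- mutations ----------------------------------------------------------

    def insert_retrocopy(
        self,
        truth: RetrocopyTruth,
        rng: np.random.Generator | None = None,
        allow_tsd_outside_range: bool = False,
    ) -> RetrocopyTruth:
        """Implant a spliced retrocopy with poly(A) tail and TSD.

        The inserted sequence is the spliced transcript minus skipped exons
        and 5' truncation, plus the poly(A) tail, with the TSD copied from
        the ``tsd_length`` reference bases 5' of the insertion point.
        """
        gene = self.genes[truth.gene_id]
        if not allow_tsd_outside_range and truth.tsd_length and not (
            TSD_RANGE[0] <= truth.tsd_length <= TSD_RANGE[1]
        ):
            raise SimulationError(
                f"tsd_length {truth.tsd_length} outside {TSD_RANGE}"
            )
        if truth.skipped_exons and (
            0 in truth.skipped_exons or len(gene.exons) - 1 in truth.skipped_exons
        ):
            raise SimulationError("cannot skip the first or last exon")
        if gene.span.contains(truth.chrom, truth.site):
            raise SimulationError("insertion site inside the parent gene")

        transcript = extract_transcript(self.ref, gene)
        offs = gene.exon_offsets()
        segments: list[tuple[list[str], int, int, str]] = []  # seq, t0, step, kind
        for i, exon in enumerate(gene.exons):
            if i in truth.skipped_exons:
                continue
            o0 = offs[i]
            seg = list(transcript[o0 : o0 + len(exon)])
            segments.append((seg, o0, 1, "retro"))
        trunc = truth.five_prime_truncation
        total = sum(len(s[0]) for s in segments)
        if trunc >= total:
            raise SimulationError("5' truncation removes the whole transcript")
        while trunc > 0:
            seg, t0, step, kind = segments[0]
            take = min(trunc, len(seg))
            if take == len(seg):
                segments.pop(0)
            else:
                segments[0] = (seg[take:], t0 + take, step, kind)
            trunc -= take
        for off, ref_b, alt_b in truth.shared_variants:
            placed = False
            for seg, t0, step, kind in segments:
                if t0 <= off < t0 + len(seg):
                    idx = off - t0
                    if ref_b and seg[idx] != ref_b:
                        raise SimulationError(
                            f"variant ref mismatch at transcript offset {off}"
                        )
                    seg[idx] = alt_b
                    placed = True
                    break
            if not placed:
                raise SimulationError(
                    f"shared variant offset {off} outside the inserted sequence"
                )
        if truth.polyA_length:
            segments.append((list("A" * truth.polyA_length), 0, 0, "none"))
        if truth.strand == "-":
            flipped = []
            for seg, t0, step, kind in segments[::-1]:
                rseq = list(revcomp("".join(seg)))
                if kind == "retro":
                    flipped.append((rseq, t0 + len(seg) - 1, -1, kind))
                else:
                    flipped.append((rseq, 0, 0, kind))
            segments = flipped

        insert_seq = "".join("".join(s[0]) for s in segments)
        t = truth.tsd_length
        site = truth.site
        chrom = truth.chrom
        if site - t < 0:
            raise SimulationError("insertion too close to chromosome start for TSD")
        tsd_seq = self.ref[chrom][site - t : site]
        p = self.mod_position_of_ref(chrom, site)
        i = self._split_at(chrom, p)
        new_blocks: list[_Block] = []
        for seg, t0, step, kind in segments:
            payload = (gene, t0, step) if kind == "retro" else None
            new_blocks.append(_Block(len(seg), kind, payload))
        if t:
            new_blocks.append(_Block(t, "ref", (chrom, site - t)))
        self.blocks[chrom][i:i] = new_blocks
        self.seqs[chrom] = (
            self.seqs[chrom][:p] + insert_seq + tsd_seq + self.seqs[chrom][p:]
        )
        done = replace(
            truth,
            tsd_sequence=tsd_seq,
            inserted_length=len(insert_seq),
        )
        self.truths.append(done)
        return done

    def amplify_segment(
        self,
        chrom: str,
        mod_interval: tuple[int, int],
        copy_count: int,
        shared_variants: Sequence[tuple[int, str]] = (),
        private_variant_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> list[list[tuple[int, str, str]]]:
        """Replace [a, b) with ``copy_count`` tandem copies.

        ``shared_variants`` are (segment offset, alt base) applied to every
        copy (pre-duplication substitutions); private variants are drawn per
        copy at ``private_variant_rate`` per base (post-duplication). Returns
        per-copy variant lists as (segment offset, ref, alt).
        """
        if copy_count < 1:
            raise SimulationError("copy_count must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        a, b = mod_interval
        i0 = self._split_at(chrom, a)
        i1 = self._split_at(chrom, b)
        unit_blocks = [
            _Block(bl.length, bl.kind, bl.payload) for bl in self.blocks[chrom][i0:i1]
        ]
        unit = self.seqs[chrom][a:b]
        copies, per_copy = [], []
        for _ in range(copy_count):
            seq = list(unit)
            events: list[tuple[int, str, str]] = []
            for off, alt in shared_variants:
                if seq[off] != alt:
                    events.append((off, unit[off], alt))
                    seq[off] = alt
            if private_variant_rate > 0:
                n = rng.binomial(len(unit), private_variant_rate)
                for off in sorted(rng.choice(len(unit), size=n, replace=False)):
                    off = int(off)
                    alt = str(rng.choice([x for x in "ACGT" if x != seq[off]]))
                    events.append((off, unit[off], alt))
                    seq[off] = alt
            copies.append("".join(seq))
            per_copy.append(events)
        self.seqs[chrom] = self.seqs[chrom][:a] + "".join(copies) + self.seqs[chrom][b:]
        rep_blocks = []
        for _ in range(copy_count):
            rep_blocks.extend(_Block(bl.length, bl.kind, bl.payload) for bl in unit_blocks)
        self.blocks[chrom][i0:i1] = rep_blocks
        return per_copy

    def delete_interval(self, chrom: str, mod_interval: tuple[int, int]) -> None:
        """Remove [a, b) from the sample genome (reference keeps it)."""
        a, b = mod_interval
        i0 = self._split_at(chrom, a)
        i1 = self._split_at(chrom, b)
        del self.blocks[chrom][i0:i1]
        self.seqs[chrom] = self.seqs[chrom][:a] + self.seqs[chrom][b:]

    # -- read placement -----------------------------------------------------

    def _runs(self, chrom: str, p: int, length: int) -> list[tuple[int, str, object]]:
        """Provenance runs covering sample window [p, p+length)."""
        starts = self._starts(chrom)
        blocks = self.blocks[chrom]
        i = bisect.bisect_right(starts, p) - 1
        out: list[tuple[int, str, object]] = []
        remaining, pos = length, p
        while remaining > 0 and i < len(blocks):
            b = blocks[i]
            off = pos - starts[i]
            take = min(remaining, b.length - off)
            if b.kind == "ref":
                c, s = b.payload
                payload: object = (c, s + off)
            elif b.kind == "retro":
                g, t0, step = b.payload
                payload = (g, t0 + step * off, step)
            else:
                payload = None
            # merge with previous run when contiguous in provenance
            if out:
                ln0, k0, pl0 = out[-1]
                if k0 == b.kind == "ref":
                    c0, s0 = pl0
                    if payload[0] == c0 and s0 + ln0 == payload[1]:
                        out[-1] = (ln0 + take, k0, pl0)
                        payload = None
                elif k0 == b.kind == "retro":
                    g0, t00, st0 = pl0
                    g1, t01, st1 = payload
                    if g0 is g1 and st0 == st1 and t00 + st0 * ln0 == t01:
                        out[-1] = (ln0 + take, k0, pl0)
                        payload = None
                elif k0 == b.kind == "none":
                    out[-1] = (ln0 + take, k0, None)
                    payload = "merged"
            if payload is not None or (b.kind == "none" and (not out or out[-1][1] != "none")):
                out.append((take, b.kind, payload if b.kind != "none" else None))
            pos += take
            remaining -= take
            i += 1
        return out

    def place_window(self, chrom: str, p: int, length: int, min_anchor: int = 1) -> _Emitted:
        """Align the sample window [p, p+length) against the reference.

        The longest single-provenance run anchors the alignment (a mapper
        reports its best local hit); everything else is soft-clipped.
        Reference-derived runs win ties against retrocopy-derived runs.
        """
        runs = self._runs(chrom, p, length)
        # candidates: (priority len, kind, read_offset, run)
        best = None
        best_key = (-1, 0)
        read_off = 0
        for ln, kind, payload in runs:
            if kind == "ref":
                key = (ln, 1)
                if key > best_key:
                    best_key, best = key, ("ref", read_off, ln, payload)
            elif kind == "retro":
                gene, t0, step = payload
                for sub_off, sub_len, sub_t0 in _exon_subruns(gene, t0, step, ln):
                    key = (sub_len, 0)
                    if key > best_key:
                        best_key, best = key, (
                            "retro", read_off + sub_off, sub_len, (gene, sub_t0, step)
                        )
            read_off += ln
        if best is None or best_key[0] < min_anchor:
            return _Emitted(False)
        kind, q0, m_len, payload = best
        lead, tail = q0, length - q0 - m_len
        if kind == "ref":
            c, s = payload
            cigar = _assemble_cigar(lead, m_len, tail)
            return _Emitted(True, c, s, cigar, flip=False)
        gene, t0, step = payload
        genome_step = step * (1 if gene.strand == "+" else -1)
        if genome_step == 1:
            pos = gene.genomic_position(t0)
            cigar = _assemble_cigar(lead, m_len, tail)
            return _Emitted(True, gene.chrom, pos, cigar, flip=False)
        pos = gene.genomic_position(t0 + step * (m_len - 1))
        cigar = _assemble_cigar(tail, m_len, lead)  # reference orientation
        return _Emitted(True, gene.chrom, pos, cigar, flip=True)


def _exon_subruns(
    gene: GeneModel, t0: int, step: int, length: int
) -> list[tuple[int, int, int]]:
    """Split a transcript-offset run into per-exon pieces.

    Yields (offset within run, piece length, transcript offset at piece start).
    """
    offs = gene.exon_offsets()
    bounds = offs + [gene.spliced_length]
    pieces = []
    done = 0
    while done < length:
        t = t0 + step * done
        i = bisect.bisect_right(offs, t) - 1
        if step == 1:
            room = bounds[i + 1] - t
        else:
            room = t - bounds[i] + 1
        take = min(length - done, room)
        pieces.append((done, take, t))
        done += take
    return pieces


def _assemble_cigar(lead: int, m: int, tail: int) -> tuple[tuple[str, int], ...]:
    ops = []
    if lead:
        ops.append(("S", lead))
    ops.append(("M", m))
    if tail:
        ops.append(("S", tail))
    return tuple(ops)


# ---------------------------------------------------------------------------
# Read simulation (WGS)
# ---------------------------------------------------------------------------

def _apply_errors(
    windows: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    if rate <= 0 or not windows:
        return windows
    lens = np.array([len(w) for w in windows])
    n_err = rng.binomial(lens, rate)
    out = list(windows)
    for i in np.nonzero(n_err)[0]:
        w = list(out[i])
        for pos in rng.choice(lens[i], size=n_err[i], replace=False):
            w[pos] = str(rng.choice([b for b in "ACGT" if b != w[pos]]))
        out[i] = "".join(w)
    return out


def simulate_reads(
    ig: ImplantedGenome,
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "s1",
    with_sam: bool = True,
    min_anchor: int = 20,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[AlignedRead]]:
    """Paired-end fragments from the sample genome, aligned by provenance.

    Returns (read1 FASTQ tuples, read2 FASTQ tuples, SAM records). Read 1 is
    the forward end of the fragment, read 2 the reverse-complemented other
    end. A pair is flagged proper when both ends map to the same chromosome
    in FR orientation within mean + 4 SD of the configured insert size.
    """
    config.validate()
    rl = config.read_length
    chroms = list(ig.seqs)
    lens = np.array([len(ig.seqs[c]) for c in chroms], dtype=float)
    total = lens.sum()
    n_frags = int(round(config.coverage * total / (2 * rl)))
    chrom_idx = rng.choice(len(chroms), size=n_frags, p=lens / total)
    frag_lens = np.maximum(
        rl + 1, np.round(rng.normal(config.insert_mean, config.insert_sd, n_frags))
    ).astype(int)
    u = rng.random(n_frags)
    proper_max = config.insert_mean + 4 * config.insert_sd

    win1: list[str] = []
    win2: list[str] = []
    meta: list[tuple[str, int, int]] = []
    for j in range(n_frags):
        c = chroms[chrom_idx[j]]
        L = len(ig.seqs[c])
        fl = min(int(frag_lens[j]), L)
        start = int(u[j] * (L - fl + 1))
        win1.append(ig.seqs[c][start : start + rl])
        win2.append(ig.seqs[c][start + fl - rl : start + fl])
        meta.append((c, start, fl))
    win1 = _apply_errors(win1, config.error_rate, rng)
    win2 = _apply_errors(win2, config.error_rate, rng)

    fq1 = [(f"{sample_id}:frag{j}", win1[j]) for j in range(n_frags)]
    fq2 = [(f"{sample_id}:frag{j}", revcomp(win2[j])) for j in range(n_frags)]
    if not with_sam:
        return fq1, fq2, []

    records: list[AlignedRead] = []
    for j in range(n_frags):
        c, start, fl = meta[j]
        e1 = ig.place_window(c, start, rl, min_anchor)
        e2 = ig.place_window(c, start + fl - rl, rl, min_anchor)
        pair: list[AlignedRead] = []
        for mate, (e, w) in enumerate([(e1, win1[j]), (e2, win2[j])]):
            if not e.mapped:
                continue
            seq = revcomp(w) if e.flip else w
            is_reverse = e.flip != (mate == 1)  # mate 2 is fragment-reverse
            left = e.cigar[0][1] if e.cigar[0][0] == "S" else 0
            right = e.cigar[-1][1] if e.cigar[-1][0] == "S" else 0
            pair.append(
                AlignedRead(
                    read_id=f"{sample_id}:frag{j}",
                    chrom=e.chrom,
                    start=e.pos,
                    end=e.pos + sum(n for op, n in e.cigar if op == "M"),
                    is_reverse=is_reverse,
                    seq=seq,
                    cigar=e.cigar,
                    left_clip=left,
                    right_clip=right,
                    is_paired=True,
                    is_read1=(mate == 0),
                    sample_id=sample_id,
                )
            )
        if len(pair) == 2:
            a, b = pair
            proper = (
                a.chrom == b.chrom
                and a.is_reverse != b.is_reverse
                and abs(max(a.end, b.end) - min(a.start, b.start)) <= proper_max
            )
            span = max(a.end, b.end) - min(a.start, b.start)
            for r, o in ((a, b), (b, a)):
                r.is_proper_pair = proper
                r.mate_chrom = o.chrom
                r.mate_start = o.start
                r.mate_is_reverse = o.is_reverse
                r.tlen = span if r.start <= o.start else -span
        elif len(pair) == 1:
            pair[0].mate_chrom = None
            pair[0].mate_start = None
        records.extend(pair)
    return fq1, fq2, records


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def simulate_rnaseq(
    pool: Sequence[tuple[str, str, float]],
    n_pairs: int,
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "rna1",
) -> list[AlignedRead]:
    """Paired reads from a pool of (label, transcript sequence, proportion).

    All pool transcripts must be length-compatible substitution variants of
    one reference transcript (the masked transcript downstream); alignments
    are emitted in that shared coordinate system with full-match CIGARs.
    Truth labels are embedded in read names as ``...:<label>``.
    """
    if not pool:
        raise SimulationError("empty transcript pool")
    props = np.array([p for _, _, p in pool], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise SimulationError(f"proportions sum to {props.sum()}, not 1")
    rl = config.read_length
    choice = rng.choice(len(pool), size=n_pairs, p=props)
    records: list[AlignedRead] = []
    for j in range(n_pairs):
        label, seq, _ = pool[choice[j]]
        L = len(seq)
        fl = min(L, max(rl + 1, int(round(rng.normal(config.insert_mean, config.insert_sd)))))
        start = int(rng.integers(0, L - fl + 1))
        w1 = seq[start : start + rl]
        w2 = seq[start + fl - rl : start + fl]
        w1, w2 = _apply_errors([w1, w2], config.error_rate, rng)
        rid = f"{sample_id}:p{j}:{label}"
        a = AlignedRead(
            rid, "transcript", start, start + rl, False, w1,
            (("M", rl),), is_paired=True, is_read1=True, is_proper_pair=True,
            mate_chrom="transcript", mate_start=start + fl - rl,
            mate_is_reverse=True, tlen=fl, sample_id=sample_id,
        )
        b = AlignedRead(
            rid, "transcript", start + fl - rl, start + fl, True, w2,
            (("M", rl),), is_paired=True, is_read1=False, is_proper_pair=True,
            mate_chrom="transcript", mate_start=start,
            mate_is_reverse=False, tlen=-fl, sample_id=sample_id,
        )
        records.extend([a, b])
    return records


# ---------------------------------------------------------------------------
# Lineage divergence simulation
# ---------------------------------------------------------------------------

def simulate_lineage_divergence(
    spec: LineageSimSpec, seq: str, rng: np.random.Generator
) -> tuple[str, int]:
    """Mutate a copy of ``seq`` under the molecular clock.

    Substitution count is Poisson with mean L * mu * k_lin * (age / g),
    placed uniformly without position reuse.
    """
    spec.validate()
    if len(seq) != spec.length:
        spec = replace(spec, length=len(seq))
    mean = spec.expected_substitutions
    if mean > spec.length / 2:
        raise SimulationError(
            f"expected substitutions {mean:.1f} exceed saturation guard L/2"
        )
    n = min(int(rng.poisson(mean)), spec.length)
    out = list(seq)
    for pos in rng.choice(spec.length, size=n, replace=False):
        pos = int(pos)
        out[pos] = str(rng.choice([b for b in "ACGT" if b != out[pos]]))
    return "".join(out), n


# ---------------------------------------------------------------------------
# Truth table emission
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "gene_id", "chrom", "site", "tsd_length", "tsd_sequence", "strand",
    "skipped_exons", "polyA_length", "five_prime_truncation", "copy_count",
    "inserted_length", "n_shared_variants",
]


def write_truth_table(truths: Iterable[RetrocopyTruth], path: str | os.PathLike) -> None:
    """One row per implanted retrocopy event."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TRUTH_COLUMNS)
        for t in truths:
            w.writerow([
                t.gene_id, t.chrom, t.site, t.tsd_length, t.tsd_sequence,
                t.strand, ",".join(map(str, sorted(t.skipped_exons))),
                t.polyA_length, t.five_prime_truncation, t.copy_count,
                t.inserted_length, len(t.shared_variants),
            ])
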
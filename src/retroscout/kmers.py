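"""mRNA-specific k-mer inventories and raw-read scanning.

A retrocopy betrays its presence in raw reads through k-mers that exist in
the spliced transcript but nowhere in the reference genome — in practice
k-mers spanning exon-exon junctions. The inventory keeps only transcript
k-mers with *no* genomic occurrence, exact or within a small Hamming
distance on either strand (substitution-only, guarding against sequencing
errors turning a genomic k-mer into a spurious transcript-specific one).

k-mers are canonicalized (lexicographic minimum of a k-mer and its reverse
complement) in both inventory and scan, since reads are unstranded. All
heavy lifting runs on 2-bit-packed uint64 codes, so the default k = 30
(59 bits) is fine on megabase genomes.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import revcomp
from .synthetic import extract_transcript  # re-exported convenience

__all__ = [
    "KmerInventory", "ParentGeneCall", "build_specific_kmers", "scan_reads",
    "call_parent_genes", "extract_transcript", "write_inventories",
    "read_inventories", "write_calls",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


@dataclass
class KmerInventory:
    """Per-gene set of transcript k-mers absent from the genome."""

    gene_id: str
    k: int
    kmers: frozenset[str]

    @property
    def total_count(self) -> int:
        return len(self.kmers)


@dataclass
class ParentGeneCall:
    """Outcome of the parent-gene call rule for one gene in one sample."""

    gene_id: str
    specific_hits: int
    total_count: int
    called: bool
    sample_id: str = ""

    @property
    def fraction(self) -> float:
        return self.specific_hits / self.total_count if self.total_count else 0.0


# ---------------------------------------------------------------------------
# 2-bit encoding
# ---------------------------------------------------------------------------

def _encode_bases(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """uint64 codes of every valid (N-free) k-mer window of ``seq``."""
    codes = _encode_bases(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid_base = codes != 255
    codes = np.where(valid_base, codes, 0).astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j : j + n]
    bad = np.convolve((~valid_base).astype(np.int32), np.ones(k, dtype=np.int32))[
        k - 1 : k - 1 + n
    ]
    return out[bad == 0]


def revcomp_code(code: np.ndarray | int, k: int) -> np.ndarray | int:
    """Reverse-complement of 2-bit packed codes."""
    c = np.asarray(code, dtype=np.uint64)
    out = np.zeros_like(c)
    for _ in range(k):
        out = (out << np.uint64(2)) | ((c ^ np.uint64(3)) & np.uint64(3))
        c = c >> np.uint64(2)
    return out


def decode_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def encode_kmer(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | int(_CODE[ord(b)])
    return code


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _genome_code_array(genome: Mapping[str, str], k: int) -> np.ndarray:
    parts = [kmer_codes(seq, k) for seq in genome.values()]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def _hamming_neighbor_hit(
    codes: np.ndarray, genome_sorted: np.ndarray, k: int, max_mismatch: int
) -> np.ndarray:
    """Boolean mask: does any Hamming<=max_mismatch neighbor (of the given
    orientation) occur in the genome forward-k-mer set?"""
    hit = np.zeros(len(codes), dtype=bool)
    if len(codes) == 0 or max_mismatch < 1:
        return hit
    shifts = [np.uint64(2 * (k - 1 - i)) for i in range(k)]
    three = np.uint64(3)

    def _in_genome(c: np.ndarray) -> np.ndarray:
        if len(genome_sorted) == 0:
            return np.zeros(len(c), dtype=bool)
        idx = np.searchsorted(genome_sorted, c)
        idx = np.minimum(idx, len(genome_sorted) - 1)
        return genome_sorted[idx] == c

    singles = []
    for i in range(k):
        base_i = (codes >> shifts[i]) & three
        for d in (1, 2, 3):
            mut = codes ^ ((base_i ^ ((base_i + np.uint64(d)) & three)) << shifts[i])
            singles.append(mut)
            hit |= _in_genome(mut)
    if max_mismatch >= 2:
        # second substitution applied on top of each single-substitution variant
        for i in range(k):
            for j in range(i + 1, k):
                for d1 in (1, 2, 3):
                    base_i = (codes >> shifts[i]) & three
                    m1 = codes ^ ((base_i ^ ((base_i + np.uint64(d1)) & three)) << shifts[i])
                    base_j = (m1 >> shifts[j]) & three
                    for d2 in (1, 2, 3):
                        m2 = m1 ^ ((base_j ^ ((base_j + np.uint64(d2)) & three)) << shifts[j])
                        hit |= _in_genome(m2)
    return hit


# ---------------------------------------------------------------------------
# Inventory construction
# ---------------------------------------------------------------------------

def build_specific_kmers(
    transcripts: Mapping[str, Sequence[str] | str],
    genome: Mapping[str, str],
    k: int = 30,
    max_mismatch: int = 2,
) -> dict[str, KmerInventory]:
    """Per-gene inventories of genome-absent transcript k-mers.

    ``transcripts`` maps gene_id -> one or more spliced transcript
    sequences (multiple transcripts union under the gene). A k-mer is kept
    only if neither it nor any substitution variant within ``max_mismatch``
    occurs on either genome strand. k-mers containing N are skipped.
    """
    if k < 8:
        raise ValueError("k < 8 gives degenerate specificity")
    if k > 31:
        raise ValueError("k > 31 does not fit the 2-bit packing")
    genome_fwd = _genome_code_array(genome, k)

    inventories: dict[str, KmerInventory] = {}
    for gene_id, seqs in transcripts.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        cand = np.unique(
            np.concatenate([kmer_codes(s, k) for s in seqs])
            if seqs else np.empty(0, np.uint64)
        )
        if len(cand):
            rc = revcomp_code(cand, k)
            exact = np.isin(cand, genome_fwd) | np.isin(rc, genome_fwd)
            cand, rc = cand[~exact], rc[~exact]
        if len(cand):
            near = _hamming_neighbor_hit(cand, genome_fwd, k, max_mismatch)
            near |= _hamming_neighbor_hit(rc, genome_fwd, k, max_mismatch)
            cand = cand[~near]
        kmers = frozenset(canonical(decode_kmer(int(c), k)) for c in cand)
        inventories[gene_id] = KmerInventory(gene_id, k, kmers)
    return inventories


# ---------------------------------------------------------------------------
# Read scanning
# ---------------------------------------------------------------------------

def scan_reads(
    inventories: Mapping[str, KmerInventory],
    reads: Iterable[str],
    batch: int = 20_000,
) -> dict[str, int]:
    """Count DISTINCT inventory k-mers observed anywhere in the reads.

    A k-mer hits if its canonical form appears in any read (either strand).
    Returns gene_id -> number of distinct inventory k-mers seen.
    """
    ks = {inv.k for inv in inventories.values()}
    if len(ks) > 1:
        raise ValueError("mixed k across inventories")
    if not ks:
        return {}
    k = ks.pop()
    code2gene: dict[int, str] = {}
    for inv in inventories.values():
        for kmer in inv.kmers:
            code2gene[encode_kmer(kmer)] = inv.gene_id
    if not code2gene:
        return {g: 0 for g in inventories}
    inv_codes = np.array(sorted(code2gene), dtype=np.uint64)
    seen: dict[str, set[int]] = {g: set() for g in inventories}

    buf: list[str] = []

    def _flush() -> None:
        if not buf:
            return
        joined = "N".join(buf)
        fwd = kmer_codes(joined, k)
        if len(fwd) == 0:
            buf.clear()
            return
        rc = revcomp_code(fwd, k)
        canon = np.minimum(fwd, rc)
        hits = np.unique(canon[np.isin(canon, inv_codes)])
        for code in hits:
            g = code2gene[int(code)]
            seen[g].add(int(code))
        buf.clear()

    for r in reads:
        buf.append(r)
        if len(buf) >= batch:
            _flush()
    _flush()
    return {g: len(s) for g, s in seen.items()}


def call_parent_genes(
    counts: Mapping[str, int],
    inventories: Mapping[str, KmerInventory],
    t_min: int = 5,
    f_min: float = 0.10,
    sample_id: str = "",
) -> list[ParentGeneCall]:
    """Apply the parent-gene call rule.

    A gene is called when strictly more than ``t_min`` distinct specific
    k-mers are observed AND they make up at least ``f_min`` of the gene's
    inventory. Genes with empty inventories are excluded.
    """
    calls = []
    for gene_id, inv in inventories.items():
        if inv.total_count == 0:
            continue
        hits = counts.get(gene_id, 0)
        if hits > inv.total_count:
            raise ValueError(f"hits exceed inventory size for {gene_id}")
        called = hits > t_min and hits / inv.total_count >= f_min
        calls.append(ParentGeneCall(gene_id, hits, inv.total_count, called, sample_id))
    return calls


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_inventories(
    inventories: Mapping[str, KmerInventory], path: str | os.PathLike
) -> None:
    """gzip TSV: gene_id, k, kmer (one row per k-mer)."""
    with gzip.open(path, "wt") as fh:
        fh.write("gene_id\tk\tkmer\n")
        for inv in inventories.values():
            for kmer in sorted(inv.kmers):
                fh.write(f"{inv.gene_id}\t{inv.k}\t{kmer}\n")


def read_inventories(path: str | os.PathLike) -> dict[str, KmerInventory]:
    acc: dict[str, tuple[int, set[str]]] = {}
    with gzip.open(path, "rt") as fh:
        next(fh)
        for line in fh:
            gene_id, k, kmer = line.rstrip("\n").split("\t")
            acc.setdefault(gene_id, (int(k), set()))[1].add(kmer)
    return {
        g: KmerInventory(g, k, frozenset(s)) for g, (k, s) in acc.items()
    }


def write_calls(calls: Iterable[ParentGeneCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgene_id\tspecific_hits\ttotal\tfraction\tcalled\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.gene_id}\t{c.specific_hits}\t{c.total_count}\t"
                f"{c.fraction:.4f}\t{c.called}\n"
            )
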
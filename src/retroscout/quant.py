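"""Copy-number from read depth, allele-specific read partition, and TPM.

Copy number of an amplified segment follows from the depth ratio: reads
from all N copies pile onto the single reference copy, so region depth /
genome-wide depth estimates N. Expression is split between parent gene and
retrocopies by aligning RNA-seq to an N-masked transcript and voting each
read (pair) on the diagnostic alleles it covers.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats_io import AlignedRead, GenomicInterval


@dataclass
class CopyNumberEstimate:
    sample_id: str
    region: GenomicInterval
    region_mean_depth: float
    genome_mean_depth: float

    @property
    def copy_number(self) -> float:
        return self.region_mean_depth / self.genome_mean_depth


@dataclass
class ExpressionPartition:
    sample_id: str
    parent_reads: int
    retro_reads: int
    unassigned_reads: int

    @property
    def total(self) -> int:
        return self.parent_reads + self.retro_reads + self.unassigned_reads

    @property
    def retro_fraction(self) -> float:
        assigned = self.parent_reads + self.retro_reads
        return self.retro_reads / assigned if assigned else float("nan")


def estimate_copy_number(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    genome_mean_depth: float,
    sample_id: str = "",
) -> CopyNumberEstimate:
    """Depth-ratio copy number over a region.

    Region depth counts M-aligned bases only (duplicates assumed removed
    upstream); dividing by the genome-wide mean depth yields copies per
    haploid reference locus.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome_mean_depth must be > 0")
    if len(region) < 1000:
        warnings.warn(
            f"region of {len(region)} bp is short for stable depth estimates",
            stacklevel=2,
        )
    covered = 0
    for r in reads:
        if r.chrom != region.chrom:
            continue
        gp = r.start
        for op, n in r.cigar:
            if op == "M":
                ov = min(gp + n, region.end) - max(gp, region.start)
                if ov > 0:
                    covered += ov
                gp += n
            elif op == "D":
                gp += n
    depth = covered / len(region)
    return CopyNumberEstimate(sample_id, region, depth, genome_mean_depth)


def genome_mean_depth_from_summary(
    per_chrom: Mapping[str, tuple[int, int]]
) -> float:
    """Mean depth from a per-chromosome (aligned_bases, length) summary."""
    total_bases = sum(b for b, _ in per_chrom.values())
    total_len = sum(l for _, l in per_chrom.values())
    if total_len == 0:
        raise ValueError("empty depth summary")
    return total_bases / total_len


# ---------------------------------------------------------------------------
# Allele-specific read partition
# ---------------------------------------------------------------------------

def _read_votes(read: AlignedRead, diag: Mapping[int, tuple[str, str]]) -> set[str]:
    """Alleles a read observes at diagnostic positions: {'parent','retro',...}."""
    votes: set[str] = set()
    rp, gp = 0, read.start
    for op, n in read.cigar:
        if op == "S" or op == "I":
            rp += n
        elif op == "D":
            gp += n
        elif op == "M":
            for pos in range(gp, gp + n):
                if pos in diag:
                    base = read.seq[rp + (pos - gp)]
                    parent_b, retro_b = diag[pos]
                    if base == parent_b:
                        votes.add("parent")
                    elif base == retro_b:
                        votes.add("retro")
                    elif base != "N":
                        votes.add("other")
            rp += n
            gp += n
    return votes


def partition_reads(
    reads: Iterable[AlignedRead],
    diagnostic_table: Sequence[Mapping],
    sample_id: str = "",
) -> ExpressionPartition:
    """Assign masked-transcript alignments to parent vs retrocopy origin.

    Mates of a pair vote jointly (one molecule): all observed diagnostic
    alleles parent -> parent; all retro -> retro; conflicting or no
    diagnostic site covered -> unassigned.
    """
    diag = {
        int(row["position"]): (row["parent_allele"], row["retro_allele"])
        for row in diagnostic_table
        if row.get("masked", True)
    }
    if not diag:
        raise ValueError("diagnostic table has no masked SNV sites")
    by_pair: dict[str, set[str]] = defaultdict(set)
    for r in reads:
        by_pair[r.read_id] |= _read_votes(r, diag)
    parent = retro = unassigned = 0
    for votes in by_pair.values():
        votes.discard("other")
        if votes == {"parent"}:
            parent += 1
        elif votes == {"retro"}:
            retro += 1
        else:
            unassigned += 1
    return ExpressionPartition(sample_id, parent, retro, unassigned)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def compute_tpm(
    counts: Mapping[str, float], lengths: Mapping[str, float]
) -> dict[str, float]:
    """Transcripts per million: rate_i = count_i / length_i, normalized to 1e6.

    All-zero counts yield all-zero TPM.
    """
    rates = {}
    for t, c in counts.items():
        L = lengths[t]
        if L <= 0:
            raise ValueError(f"non-positive effective length for {t}")
        rates[t] = c / L
    total = sum(rates.values())
    if total == 0:
        return {t: 0.0 for t in counts}
    return {t: 1e6 * r / total for t, r in rates.items()}
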
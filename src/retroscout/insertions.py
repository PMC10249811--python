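"""Insertion-site, junction and TSD resolution from discordant alignments.

A retrocopy absent from the reference leaves two footprints in paired-end
alignments: read pairs with one mate on the parent gene's exons and the
other at the insertion locus (discordant pairs), and soft-clipped reads
whose clip boundary marks the insertion breakpoints. Because the LINE-1
integration duplicates the target site, the left breakpoint (resolved from
left-flank-anchored clips) lies *downstream* of the right breakpoint
(from right-flank-anchored clips); the overlap between them is the TSD.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats_io import AlignedRead, GeneModel, GenomicInterval, revcomp

DEFAULT_D_MAX = 10_000
DEFAULT_CLUSTER_WINDOW = 500
DEFAULT_MIN_SUPPORT = 4


@dataclass
class DiscordantCluster:
    """A pile of discordant-pair mate positions supporting one insertion."""

    gene_id: str
    interval: GenomicInterval
    read_ids: tuple[str, ...]
    support_by_sample: dict[str, int] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.read_ids)


@dataclass
class InsertionCall:
    """A resolved retrocopy insertion."""

    gene_id: str
    interval: GenomicInterval  # duplicated target site (or cluster span if unresolved)
    five_prime_junction: str
    three_prime_junction: str
    tsd_sequence: str | None
    tsd_length: int
    samples: tuple[str, ...]
    discordant_support: int
    mean_discordant_reads: float
    resolved: bool = True

    def __post_init__(self) -> None:
        if self.tsd_sequence is not None and not 5 <= self.tsd_length <= 50:
            warnings.warn(
                f"TSD length {self.tsd_length} outside the plausible 5-50 bp range",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Discordant-pair collection and clustering
# ---------------------------------------------------------------------------

def find_discordant_pairs(
    reads: Iterable[AlignedRead],
    gene: GeneModel,
    d_max: int = DEFAULT_D_MAX,
) -> list[AlignedRead]:
    """Reads overlapping a parent exon whose mate maps elsewhere.

    Keeps alignments with >=1 bp of exon overlap and a mate on a different
    chromosome or more than ``d_max`` away; proper pairs and intron-only
    overlaps are excluded (retrocopies are intron-less, so intron-only
    mates carry no retrocopy signal).
    """
    out = []
    for r in reads:
        if r.is_proper_pair or r.mate_chrom is None:
            continue
        if not any(
            e.overlaps(GenomicInterval(r.chrom, r.start, r.end)) for e in gene.exons
        ):
            continue
        if r.mate_chrom != r.chrom or abs((r.mate_start or 0) - r.start) > d_max:
            out.append(r)
    return out


def cluster_mates(
    candidates: Sequence[AlignedRead],
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
    gene_id: str = "",
) -> list[DiscordantCluster]:
    """Single-linkage clustering of mate positions.

    Mates on the same chromosome whose sorted positions are within
    ``cluster_window`` of their neighbor join one cluster; clusters below
    ``min_support`` reads are dropped.
    """
    by_chrom: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in candidates:
        if r.mate_chrom is not None and r.mate_start is not None:
            by_chrom[r.mate_chrom].append(r)
    clusters = []
    for chrom, rs in sorted(by_chrom.items()):
        rs.sort(key=lambda r: r.mate_start)
        group: list[AlignedRead] = []
        for r in rs:
            if group and r.mate_start - group[-1].mate_start > cluster_window:
                clusters.extend(
                    _make_cluster(chrom, group, min_support, gene_id)
                )
                group = []
            group.append(r)
        clusters.extend(_make_cluster(chrom, group, min_support, gene_id))
    return clusters


def _make_cluster(
    chrom: str, group: list[AlignedRead], min_support: int, gene_id: str
) -> list[DiscordantCluster]:
    if len(group) < min_support:
        return []
    lo = min(r.mate_start for r in group)
    hi = max(r.mate_start for r in group) + 1
    per_sample = Counter(r.sample_id for r in group)
    return [
        DiscordantCluster(
            gene_id,
            GenomicInterval(chrom, lo, hi),
            tuple(r.read_id for r in group),
            dict(per_sample),
        )
    ]


# ---------------------------------------------------------------------------
# Breakpoint, junction and TSD resolution
# ---------------------------------------------------------------------------

def resolve_breakpoints(
    cluster: DiscordantCluster,
    reads: Iterable[AlignedRead],
    genome: Mapping[str, str],
    flank: int = 600,
    junction_bases: int = 20,
    min_clip: int = 5,
) -> InsertionCall:
    """Resolve breakpoints, TSD and junction sequences from soft-clips.

    The left breakpoint is the modal right edge of alignments clipped on
    the right (reads anchored in the left flank running into the insert);
    the right breakpoint is the modal left edge of left-clipped alignments.
    When left > right the intervening reference bases are the TSD. Modal
    ties break toward higher clip support, then the leftmost coordinate.
    """
    iv = cluster.interval
    lo, hi = iv.start - flank, iv.end + flank
    left_edges: Counter[int] = Counter()   # candidate left breakpoints
    right_edges: Counter[int] = Counter()  # candidate right breakpoints
    left_clips: dict[int, list[str]] = defaultdict(list)
    right_clips: dict[int, list[str]] = defaultdict(list)
    for r in reads:
        if r.chrom != iv.chrom or r.end < lo or r.start > hi:
            continue
        if r.right_clip >= min_clip:
            left_edges[r.end] += 1
            left_clips[r.end].append(r.right_clip_seq)
        if r.left_clip >= min_clip:
            right_edges[r.start] += 1
            right_clips[r.start].append(r.left_clip_seq)

    samples = tuple(sorted(s for s in cluster.support_by_sample))
    n_samples = max(len(samples), 1)
    mean_disc = cluster.support / n_samples

    if not left_edges or not right_edges:
        return InsertionCall(
            cluster.gene_id, iv, "", "", None, 0, samples,
            cluster.support, mean_disc, resolved=False,
        )
    left_bp = _modal(left_edges)
    right_bp = _modal(right_edges)
    chrom_seq = genome[iv.chrom]
    if left_bp > right_bp:
        tsd = chrom_seq[right_bp:left_bp]
        interval = GenomicInterval(iv.chrom, right_bp, left_bp)
    else:
        tsd = None
        interval = GenomicInterval(iv.chrom, left_bp, max(right_bp, left_bp + 1))
    five_ref = chrom_seq[max(0, left_bp - junction_bases) : left_bp]
    five_ins = _consensus(left_clips[left_bp], junction_bases, from_start=True)
    three_ref = chrom_seq[right_bp : right_bp + junction_bases]
    three_ins = _consensus(right_clips[right_bp], junction_bases, from_start=False)
    return InsertionCall(
        cluster.gene_id,
        interval,
        five_prime_junction=five_ref + five_ins,
        three_prime_junction=three_ins + three_ref,
        tsd_sequence=tsd,
        tsd_length=len(tsd) if tsd else 0,
        samples=samples,
        discordant_support=cluster.support,
        mean_discordant_reads=mean_disc,
    )


def _modal(counter: Counter[int]) -> int:
    best = max(counter.values())
    return min(pos for pos, n in counter.items() if n == best)


def _consensus(clips: list[str], n: int, from_start: bool) -> str:
    """Per-column majority consensus over clipped sequences.

    ``from_start``: columns counted from the clip's breakpoint-proximal end
    (the start of right-of-alignment clips, the end of left-of-alignment
    clips). Ties break to the alphabetically first base.
    """
    if not clips:
        return ""
    cols = []
    depth = min(n, max(len(c) for c in clips))
    for j in range(depth):
        col = Counter()
        for c in clips:
            if j < len(c):
                col[c[j] if from_start else c[len(c) - 1 - j]] += 1
        if not col:
            break
        best = max(col.values())
        cols.append(min(b for b, v in col.items() if v == best))
    s = "".join(cols)
    return s if from_start else s[::-1]


# ---------------------------------------------------------------------------
# Junction-spanning read detection (unresolved parents)
# ---------------------------------------------------------------------------

def junction_windows(transcript: str, exon_lengths: Sequence[int], j: int = 20) -> list[str]:
    """Splice-junction windows: last j bases of exon i + first j of exon i+1."""
    if 2 * j > len(transcript):
        raise ValueError("junction window longer than transcript")
    windows = []
    off = 0
    for ln in exon_lengths[:-1]:
        off += ln
        lo, hi = max(0, off - j), min(len(transcript), off + j)
        windows.append(transcript[lo:hi])
    return windows


def detect_junction_reads(
    reads: Iterable[str],
    windows_by_gene: Mapping[str, Sequence[str]],
    read_length: int | None = None,
) -> dict[str, int]:
    """Count reads containing any splice-junction window contiguously.

    Reads are unstranded: a window matches in forward or reverse-complement
    orientation. Only genome-absent windows are informative — callers build
    them from spliced transcripts, so a contiguous match implies an
    intron-less (retrocopy) template.
    """
    pats: list[tuple[str, str]] = []
    for gene_id, ws in windows_by_gene.items():
        for w in ws:
            if read_length is not None and len(w) > read_length:
                raise ValueError(
                    f"junction window ({len(w)} bp) longer than reads"
                )
            pats.append((gene_id, w))
            pats.append((gene_id, revcomp(w)))
    counts = {g: 0 for g in windows_by_gene}
    for r in reads:
        seen: set[str] = set()
        for gene_id, w in pats:
            if gene_id not in seen and w in r:
                counts[gene_id] += 1
                seen.add(gene_id)
    return counts


# ---------------------------------------------------------------------------
# Reference-retrocopy absence (deletion evidence)
# ---------------------------------------------------------------------------

def reference_retrocopy_absence(
    reads: Iterable[AlignedRead],
    interval: GenomicInterval,
    genome_depth: float,
    insert_mean: float = 350.0,
    insert_sd: float = 35.0,
    hom_ratio: float = 0.15,
    het_ratio: float = 0.75,
    min_straddle: int = 2,
) -> tuple[str, dict[str, float]]:
    """Classify an annotated reference retrocopy as present/het_absent/hom_absent.

    Evidence: (a) pairs straddling the interval with an apparent insert
    consistent with its deletion, (b) interval depth relative to genome
    depth. Ratio < ``hom_ratio`` -> hom_absent; between ``hom_ratio`` and
    ``het_ratio`` with straddling pairs -> het_absent; else present.
    """
    if genome_depth <= 0:
        raise ValueError("genome_depth must be > 0")
    covered = 0
    straddle = 0
    min_del_span = insert_mean + 4 * insert_sd + len(interval) * 0.5
    for r in reads:
        if r.chrom != interval.chrom:
            continue
        ov = min(r.end, interval.end) - max(r.start, interval.start)
        if ov > 0:
            covered += ov
        if (
            r.mate_chrom == r.chrom
            and r.mate_start is not None
            and r.end <= interval.start
            and r.mate_start >= interval.end
            and (r.mate_start - r.start) >= min_del_span
        ):
            straddle += 1
    depth = covered / len(interval)
    ratio = depth / genome_depth
    evidence = {"depth_ratio": ratio, "straddling_pairs": float(straddle)}
    if ratio < hom_ratio:
        state = "hom_absent"
    elif ratio <= het_ratio and straddle >= min_straddle:
        state = "het_absent"
    else:
        state = "present"
    return state, evidence


# ---------------------------------------------------------------------------
# Sex-bias flag for unresolved parents
# ---------------------------------------------------------------------------

def flag_sex_bias(
    evidence_by_sample: Mapping[str, Mapping[str, bool]],
    sample_sex: Mapping[str, str],
    m_min: int = 2,
) -> dict[str, bool]:
    """Flag genes whose evidence occurs in >= m_min males and zero females.

    ``evidence_by_sample``: gene_id -> {sample_id: has_evidence}. Samples
    missing a sex annotation are excluded with a warning. Mirrors the
    Y-chromosome inference for parents absent from a female-assembled
    reference.
    """
    sexes = set()
    for g, ev in evidence_by_sample.items():
        for s in ev:
            if s in sample_sex:
                sexes.add(sample_sex[s])
            else:
                warnings.warn(f"sample {s} missing sex annotation; excluded", stacklevel=2)
    flags: dict[str, bool] = {}
    evaluable = {"M", "F"} <= {x.upper()[:1] for x in sexes}
    if not evaluable:
        warnings.warn("need >=1 male and >=1 female sample; sex bias not evaluable",
                      stacklevel=2)
    for gene_id, ev in evidence_by_sample.items():
        males = sum(
            1 for s, has in ev.items()
            if has and sample_sex.get(s, "?").upper().startswith("M")
        )
        females = sum(
            1 for s, has in ev.items()
            if has and sample_sex.get(s, "?").upper().startswith("F")
        )
        flags[gene_id] = evaluable and males >= m_min and females == 0
    return flags
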
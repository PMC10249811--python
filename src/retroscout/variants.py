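"""Attribution of parent-locus variants to retrocopies, consequences,
fixed-variant selection and transcript masking.

Reads originating from an intron-less retrocopy mismap onto the parent
gene's exons, so substitutions the retrocopy has accumulated appear as
alt alleles at the parent locus — but only in carriers. The attribution
rule conditions on carrier status: an alt allele seen in at least one
carrier and in no non-carrier is a retrocopy variant; one seen in any
non-carrier belongs to the parental gene pool.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .formats_io import AlignedRead, GeneModel, GenomicInterval, VcfRecord

DEFAULT_R_MIN = 3
DEFAULT_TAU_FIXED = 0.5

CONSEQUENCES = (
    "synonymous", "missense", "nonsense", "frameshift", "inframe_indel",
    "UTR", "noncoding",
)


@dataclass
class AlleleSite:
    """One alternate allele at a parent-locus site across the cohort."""

    site: GenomicInterval
    ref: str
    alt: str
    presence: dict[str, bool] = field(default_factory=dict)
    alt_fraction: dict[str, float] = field(default_factory=dict)


@dataclass
class RetroVariant:
    """A variant attributed to the retrocopy or the parental gene."""

    site: GenomicInterval
    ref: str
    alt: str
    attribution: str  # retrocopy | parental | ambiguous
    consequence: str = "noncoding"
    fixed_across_copies: bool = False

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def pileup_alleles(
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
    exons: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    r_min: int = DEFAULT_R_MIN,
) -> list[AlleleSite]:
    """Exact base pileup over exon intervals -> cohort allele table.

    Substitutions come from M-aligned bases differing from the reference;
    insertions/deletions from I/D CIGAR operations, reported left-aligned
    as ref/alt strings anchored on the preceding reference base. A sample
    is alt-positive when >= ``r_min`` reads carry the alt.
    """
    exon_pos: dict[str, set[int]] = defaultdict(set)
    for e in exons:
        exon_pos[e.chrom].update(range(e.start, e.end))

    def in_exon(chrom: str, pos: int) -> bool:
        return pos in exon_pos[chrom]

    # (chrom,pos,ref,alt) -> sample -> [alt_count, total_count at site]
    alt_counts: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    depth: dict[tuple[str, int], dict[str, int]] = defaultdict(lambda: defaultdict(int))

    for sample, reads in reads_by_sample.items():
        for r in reads:
            rp, gp = 0, r.start
            for op, n in r.cigar:
                if op == "S":
                    rp += n
                elif op == "M":
                    chrom_seq = genome[r.chrom]
                    for i in range(n):
                        pos = gp + i
                        if in_exon(r.chrom, pos):
                            depth[(r.chrom, pos)][sample] += 1
                            base = r.seq[rp + i]
                            refb = chrom_seq[pos]
                            if base != refb and base != "N":
                                alt_counts[(r.chrom, pos, refb, base)][sample] += 1
                    rp += n
                    gp += n
                elif op == "I":
                    pos = gp - 1
                    if pos >= 0 and in_exon(r.chrom, pos):
                        refb = genome[r.chrom][pos]
                        alt = refb + r.seq[rp : rp + n]
                        alt_counts[(r.chrom, pos, refb, alt)][sample] += 1
                    rp += n
                elif op == "D":
                    pos = gp - 1
                    if pos >= 0 and in_exon(r.chrom, pos):
                        ref = genome[r.chrom][pos : gp + n]
                        alt_counts[(r.chrom, pos, ref, ref[0])][sample] += 1
                    gp += n

    sites: list[AlleleSite] = []
    for (chrom, pos, ref, alt), per_sample in sorted(alt_counts.items()):
        presence, frac = {}, {}
        for sample in reads_by_sample:
            a = per_sample.get(sample, 0)
            d = depth.get((chrom, pos), {}).get(sample, 0)
            presence[sample] = a >= r_min
            frac[sample] = a / d if d else 0.0
        if not any(presence.values()):
            continue
        sites.append(
            AlleleSite(
                GenomicInterval(chrom, pos, pos + max(len(ref), 1)),
                ref, alt, presence, frac,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

def attribute_variants(
    sites: Sequence[AlleleSite],
    carriers: Mapping[str, bool],
) -> list[RetroVariant]:
    """Carrier-conditioned attribution of each alt allele.

    retrocopy: alt present in >= 1 carrier and 0 non-carriers;
    parental: alt present in >= 1 non-carrier;
    ambiguous: no informative contrast (e.g. a carrier-only cohort —
    the situation that forces exclusion of events private to one group).
    """
    have_carrier = any(carriers.values())
    have_noncarrier = any(not v for v in carriers.values())
    if not (have_carrier and have_noncarrier):
        warnings.warn(
            "cohort lacks a carrier/non-carrier contrast; all attributions ambiguous",
            stacklevel=2,
        )
    out = []
    for s in sites:
        in_car = any(s.presence.get(x, False) for x, c in carriers.items() if c)
        in_non = any(s.presence.get(x, False) for x, c in carriers.items() if not c)
        if not (in_car or in_non):
            continue
        if not (have_carrier and have_noncarrier):
            attr = "ambiguous"
        elif in_non:
            attr = "parental"
        elif in_car:
            attr = "retrocopy"
        else:
            attr = "ambiguous"
        out.append(RetroVariant(s.site, s.ref, s.alt, attr))
    return out


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

def classify_consequence(
    variant: RetroVariant,
    gene: GeneModel,
    transcript: str,
) -> str:
    """Standard-genetic-code consequence of a variant on one transcript.

    The variant site is mapped into transcript coordinates; variants outside
    the transcript are noncoding, inside the transcript but outside the
    annotated CDS are UTR. Indels shift or preserve frame by length % 3;
    substitutions compare the mutated codon's amino acid.
    """
    pos = variant.site.start
    off = gene.transcript_offset(variant.site.chrom, pos)
    if off is None:
        return "noncoding"
    if gene.cds_offset is None or gene.cds_length is None:
        return "noncoding"
    cds_lo, cds_hi = gene.cds_offset, gene.cds_offset + gene.cds_length
    if variant.is_indel:
        change = abs(len(variant.alt) - len(variant.ref))
        if not cds_lo <= off < cds_hi:
            return "UTR"
        return "inframe_indel" if change % 3 == 0 else "frameshift"
    if not cds_lo <= off < cds_hi:
        return "UTR"
    # substitution: mutate the codon
    ref_t, alt_t = variant.ref, variant.alt
    if gene.strand == "-":
        ref_t = str(Seq(ref_t).reverse_complement())
        alt_t = str(Seq(alt_t).reverse_complement())
    if transcript[off] != ref_t:
        raise ValueError(
            f"reference allele mismatch at transcript offset {off}: "
            f"{transcript[off]} != {ref_t}"
        )
    cds_pos = off - cds_lo
    codon_i = cds_pos // 3
    codon = transcript[cds_lo + codon_i * 3 : cds_lo + codon_i * 3 + 3]
    if len(codon) < 3:
        return "UTR"
    mut = list(codon)
    mut[cds_pos % 3] = alt_t
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq("".join(mut)).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def classify_all(
    variants: Sequence[RetroVariant], gene: GeneModel, transcript: str
) -> list[RetroVariant]:
    return [
        replace(v, consequence=classify_consequence(v, gene, transcript))
        for v in variants
    ]


# ---------------------------------------------------------------------------
# Fixed-variant selection and transcript masking
# ---------------------------------------------------------------------------

def select_fixed_variants(
    variants: Sequence[RetroVariant],
    alt_fractions: Mapping[tuple[str, int, str], Mapping[str, float]] | None,
    sites: Sequence[AlleleSite] | None,
    copy_number: Mapping[str, float],
    carriers: Mapping[str, bool],
    tau_fixed: float = DEFAULT_TAU_FIXED,
) -> list[RetroVariant]:
    """Variants fixed across all retrocopy copies in every carrier.

    With CN retrocopy-derived haplotypes mismapping onto the 2 parental
    alleles, a variant carried by *every* copy shows an expected alt
    fraction of CN/(CN+2) at the parent locus. A variant is deemed fixed
    when every carrier's observed alt fraction reaches
    ``tau_fixed * CN/(CN+2)``. Carriers without a CN estimate exclude the
    variant with a warning.
    """
    frac_by_key: dict[tuple[str, int, str], Mapping[str, float]]
    if sites is not None:
        frac_by_key = {
            (s.site.chrom, s.site.start, s.alt): s.alt_fraction for s in sites
        }
    else:
        frac_by_key = dict(alt_fractions or {})
    out = []
    for v in variants:
        if v.attribution != "retrocopy":
            out.append(v)
            continue
        fr = frac_by_key.get((v.site.chrom, v.site.start, v.alt), {})
        fixed = True
        for sample, is_carrier in carriers.items():
            if not is_carrier:
                continue
            cn = copy_number.get(sample)
            if cn is None:
                warnings.warn(
                    f"no copy-number estimate for carrier {sample}; "
                    f"variant at {v.site.chrom}:{v.site.start} excluded",
                    stacklevel=2,
                )
                fixed = False
                break
            threshold = tau_fixed * cn / (cn + 2)
            if fr.get(sample, 0.0) < threshold:
                fixed = False
                break
        out.append(replace(v, fixed_across_copies=fixed))
    return out


def build_masked_transcript(
    transcript: str,
    fixed_variants: Sequence[RetroVariant],
    gene: GeneModel,
) -> tuple[str, list[dict]]:
    """N-mask fixed diagnostic SNV positions in the transcript.

    Returns the masked sequence and a diagnostic-site table of
    {position, parent allele, retro allele} in transcript coordinates.
    Indel diagnostics are recorded (unmasked) since N-masking is
    positional. Conflicting alleles at one position are an error.
    """
    masked = list(transcript)
    table: list[dict] = []
    seen: dict[int, str] = {}
    for v in fixed_variants:
        if not (v.fixed_across_copies and v.attribution == "retrocopy"):
            continue
        off = gene.transcript_offset(v.site.chrom, v.site.start)
        if off is None:
            raise ValueError(f"fixed variant at {v.site.chrom}:{v.site.start} "
                             "outside the transcript")
        ref_t, alt_t = v.ref, v.alt
        if gene.strand == "-" and not v.is_indel:
            ref_t = str(Seq(ref_t).reverse_complement())
            alt_t = str(Seq(alt_t).reverse_complement())
        if v.is_indel:
            table.append({
                "position": off, "parent_allele": v.ref, "retro_allele": v.alt,
                "masked": False,
            })
            continue
        if off in seen and seen[off] != alt_t:
            raise ValueError(
                f"conflicting fixed alleles at transcript position {off}"
            )
        seen[off] = alt_t
        masked[off] = "N"
        table.append({
            "position": off, "parent_allele": ref_t, "retro_allele": alt_t,
            "masked": True,
        })
    return "".join(masked), table


def unmask_transcript(masked: str, table: Sequence[Mapping]) -> str:
    """Inverse of :func:`build_masked_transcript` (restores parent alleles)."""
    out = list(masked)
    for row in table:
        if row.get("masked"):
            out[row["position"]] = row["parent_allele"]
    return "".join(out)


def variants_to_vcf_records(variants: Sequence[RetroVariant]) -> list[VcfRecord]:
    recs = []
    for v in variants:
        recs.append(
            VcfRecord(
                v.site.chrom, v.site.start, v.ref, v.alt,
                info={
                    "ATTRIB": v.attribution,
                    "CONSEQ": v.consequence,
                    "FIXED": str(int(v.fixed_across_copies)),
                },
            )
        )
    return recs
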
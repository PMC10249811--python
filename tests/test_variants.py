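"""Pileup thresholds, carrier-conditioned attribution, consequence
classification vs a translate-and-compare oracle, fixed-variant selection
and transcript masking."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from retroscout.formats_io import AlignedRead, GeneModel, GenomicInterval
from retroscout.kmers import extract_transcript
from retroscout.synthetic import ImplantedGenome, RetrocopyTruth, simulate_reads
from retroscout.variants import (
    AlleleSite, RetroVariant, attribute_variants, build_masked_transcript,
    classify_all, classify_consequence, pileup_alleles, select_fixed_variants,
    unmask_transcript,
)


def _mread(chrom, start, seq, read_id="r"):
    return AlignedRead(read_id, chrom, start, start + len(seq), False, seq,
                       (("M", len(seq)),))


GENOME = {"c": "ACGTTGCAAC" * 100}
EXONS = (GenomicInterval("c", 0, 1000, "+"),)


class TestPileup:
    def test_reference_only_site_has_no_row(self):
        reads = {"s1": [_mread("c", 0, GENOME["c"][:50], f"r{i}")
                        for i in range(30)]}
        assert pileup_alleles(reads, EXONS, GENOME) == []

    def test_alt_fraction_counted(self):
        ref = GENOME["c"][:50]
        alt = ref[:10] + ("A" if ref[10] != "A" else "G") + ref[11:]
        reads = {"s1": [_mread("c", 0, ref, f"a{i}") for i in range(10)]
                 + [_mread("c", 0, alt, f"b{i}") for i in range(5)]}
        (site,) = pileup_alleles(reads, EXONS, GENOME)
        assert site.site.start == 10
        assert site.alt_fraction["s1"] == pytest.approx(5 / 15)
        assert site.presence["s1"] is True

    def test_r_min_threshold(self):
        ref = GENOME["c"][:50]
        alt = ref[:10] + ("A" if ref[10] != "A" else "G") + ref[11:]
        reads = {"s1": [_mread("c", 0, ref, f"a{i}") for i in range(20)]
                 + [_mread("c", 0, alt, f"b{i}") for i in range(2)]}
        assert pileup_alleles(reads, EXONS, GENOME, r_min=3) == []


def _site(presence, fractions=None):
    return AlleleSite(GenomicInterval("c", 10, 11), "A", "G", dict(presence),
                      dict(fractions or {k: float(v) for k, v in presence.items()}))


class TestAttribution:
    CARRIERS = {"c1": True, "c2": True, "c3": True,
                "n1": False, "n2": False, "n3": False, "n4": False, "n5": False}

    def test_carrier_only_allele_is_retrocopy(self):
        s = _site({"c1": True, "c2": True, "c3": True, "n1": False})
        (v,) = attribute_variants([s], self.CARRIERS)
        assert v.attribution == "retrocopy"

    def test_allele_in_any_noncarrier_is_parental(self):
        s = _site({"c1": True, "c2": True, "n1": True})
        (v,) = attribute_variants([s], self.CARRIERS)
        assert v.attribution == "parental"

    def test_carrier_only_cohort_is_ambiguous(self):
        s = _site({"c1": True})
        with pytest.warns(UserWarning, match="contrast"):
            (v,) = attribute_variants([s], {"c1": True, "c2": True})
        assert v.attribution == "ambiguous"


def translate_compare_oracle(cds_ref: str, cds_alt: str) -> str:
    """Independent oracle: full translation of ref vs alt CDS."""
    if len(cds_ref) != len(cds_alt):
        return "inframe_indel" if abs(len(cds_ref) - len(cds_alt)) % 3 == 0 \
            else "frameshift"
    p_ref = str(Seq(cds_ref).translate())
    p_alt = str(Seq(cds_alt).translate())
    if p_ref == p_alt:
        return "synonymous"
    diffs = [(a, b) for a, b in zip(p_ref, p_alt) if a != b]
    if any(b == "*" for _, b in diffs):
        return "nonsense"
    return "missense"


class TestConsequence:
    def _gene(self, length=300, cds_offset=10, cds_length=270):
        return GeneModel("g", "t", (GenomicInterval("c", 0, length, "+"),),
                         "+", cds_offset=cds_offset, cds_length=cds_length)

    def test_33bp_inframe_deletion_loses_11_codons(self):
        gene = self._gene()
        ref = GENOME["c"][20 : 20 + 34]
        v = RetroVariant(GenomicInterval("c", 20, 54), ref, ref[0], "retrocopy")
        assert classify_consequence(v, gene, GENOME["c"][:300]) == "inframe_indel"
        assert (len(ref) - 1) // 3 == 11

    def test_stop_gain_is_nonsense(self):
        tr = "A" * 10 + "ATGCAATTTTAA" + "A" * 20
        gene = self._gene(length=len(tr), cds_offset=10, cds_length=12)
        genome = {"c": tr}
        # CAA -> TAA at codon 2, position 1
        v = RetroVariant(GenomicInterval("c", 13, 14), "C", "T", "retrocopy")
        assert classify_consequence(v, gene, tr) == "nonsense"

    def test_single_base_insertion_is_frameshift(self):
        gene = self._gene()
        refb = GENOME["c"][20]
        v = RetroVariant(GenomicInterval("c", 20, 21), refb, refb + "T", "retrocopy")
        assert classify_consequence(v, gene, GENOME["c"][:300]) == "frameshift"

    def test_outside_transcript_is_noncoding(self):
        gene = self._gene(length=300)
        v = RetroVariant(GenomicInterval("c", 500, 501), "A", "G", "retrocopy")
        assert classify_consequence(v, gene, GENOME["c"][:300]) == "noncoding"

    def test_utr_variant(self):
        gene = self._gene(length=300, cds_offset=10, cds_length=270)
        refb = GENOME["c"][5]
        alt = "A" if refb != "A" else "G"
        v = RetroVariant(GenomicInterval("c", 5, 6), refb, alt, "retrocopy")
        assert classify_consequence(v, gene, GENOME["c"][:300]) == "UTR"

    def test_agrees_with_translate_oracle_on_random_substitutions(self, rng):
        tr = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
        gene = self._gene(length=600, cds_offset=30, cds_length=540)
        genome = {"c": tr}
        checked = 0
        for _ in range(1000):
            pos = int(rng.integers(30, 570))
            refb = tr[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != refb]))
            v = RetroVariant(GenomicInterval("c", pos, pos + 1), refb, alt,
                             "retrocopy")
            got = classify_consequence(v, gene, tr)
            cds_ref = tr[30:570]
            i = pos - 30
            cds_alt = cds_ref[:i] + alt + cds_ref[i + 1 :]
            assert got == translate_compare_oracle(cds_ref, cds_alt)
            checked += 1
        assert checked == 1000


class TestFixedSelection:
    def _variant(self):
        return RetroVariant(GenomicInterval("c", 10, 11), "A", "G", "retrocopy")

    def test_high_copy_number_arithmetic(self):
        # CN = 25: threshold 0.5 * 25/27 = 0.463; fractions 0.93 pass
        v = self._variant()
        sites = [_site({"s1": True, "s2": True}, {"s1": 0.93, "s2": 0.95})]
        out = select_fixed_variants([v], None, sites, {"s1": 25, "s2": 25},
                                    {"s1": True, "s2": True})
        assert out[0].fixed_across_copies is True

    def test_low_fraction_in_one_carrier_rejects(self):
        v = self._variant()
        sites = [_site({"s1": True, "s2": True}, {"s1": 0.93, "s2": 0.04})]
        out = select_fixed_variants([v], None, sites, {"s1": 25, "s2": 25},
                                    {"s1": True, "s2": True})
        assert out[0].fixed_across_copies is False

    def test_missing_cn_warns_and_excludes(self):
        v = self._variant()
        sites = [_site({"s1": True}, {"s1": 0.9})]
        with pytest.warns(UserWarning, match="copy-number"):
            out = select_fixed_variants([v], None, sites, {}, {"s1": True})
        assert out[0].fixed_across_copies is False

    def test_end_to_end_25_copies_vs_5_of_25(self, toy):
        """A variant in all 25 copies is selected; one in 5/25 is rejected."""
        cfg, genome, genes = toy
        gene = next(g for g in genes if g.gene_id == "gene1")
        tr = extract_transcript(genome, gene)
        off_fixed = 30
        alt_fixed = "A" if tr[off_fixed] != "A" else "G"
        ig = ImplantedGenome(genome, genes)
        truth = ig.insert_retrocopy(RetrocopyTruth(
            gene_id="gene1", site=9000, chrom="chr2", tsd_length=17,
            polyA_length=0,
            shared_variants=((off_fixed, tr[off_fixed], alt_fixed),)))
        # the insert occupies sample coordinates [site, site + inserted_length);
        # amplify it to 25 copies, then add a variant private to 5 copies
        a = truth.site
        ig.amplify_segment("chr2", (a, a + truth.inserted_length), 25)
        off_part = 60
        alt_part = "A" if ig.seqs["chr2"][a + off_part] != "A" else "G"
        for c in range(5):
            s = ig.seqs["chr2"]
            p = a + c * truth.inserted_length + off_part
            ig.seqs["chr2"] = s[:p] + alt_part + s[p + 1 :]
        _, _, sam = simulate_reads(ig, cfg, np.random.default_rng(21), "s1")
        ign = ImplantedGenome(genome, genes)
        _, _, sam_n = simulate_reads(ign, cfg, np.random.default_rng(22), "s2")
        reads = {"s1": [r for r in sam if r.chrom == gene.chrom],
                 "s2": [r for r in sam_n if r.chrom == gene.chrom]}
        sites = pileup_alleles(reads, gene.exons, genome)
        carriers = {"s1": True, "s2": False}
        vs = attribute_variants(sites, carriers)
        vs = select_fixed_variants(vs, None, sites, {"s1": 25.0}, carriers)
        by_off = {}
        for v in vs:
            o = gene.transcript_offset(v.site.chrom, v.site.start)
            by_off[o] = v
        assert by_off[off_fixed].fixed_across_copies is True
        assert by_off[off_part].fixed_across_copies is False


class TestMasking:
    def _gene(self, n=400):
        return GeneModel("g", "t", (GenomicInterval("c", 0, n, "+"),), "+",
                         cds_offset=0, cds_length=(n // 3) * 3)

    def test_fifteen_fixed_snvs_mask_fifteen_positions(self, rng):
        tr = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        gene = self._gene()
        positions = sorted(rng.choice(400, size=15, replace=False))
        vs = []
        for p in positions:
            p = int(p)
            alt = "A" if tr[p] != "A" else "G"
            vs.append(RetroVariant(GenomicInterval("c", p, p + 1), tr[p], alt,
                                   "retrocopy", fixed_across_copies=True))
        masked, table = build_masked_transcript(tr, vs, gene)
        assert masked.count("N") == 15
        assert sum(a != b for a, b in zip(masked, tr)) == 15

    def test_zero_fixed_variants_is_identity(self):
        gene = self._gene()
        masked, table = build_masked_transcript("ACGT" * 100, [], gene)
        assert masked == "ACGT" * 100 and table == []

    def test_conflicting_alleles_rejected(self):
        gene = self._gene()
        tr = "ACGT" * 100
        v1 = RetroVariant(GenomicInterval("c", 8, 9), tr[8], "T", "retrocopy",
                          fixed_across_copies=True)
        v2 = RetroVariant(GenomicInterval("c", 8, 9), tr[8], "C", "retrocopy",
                          fixed_across_copies=True)
        with pytest.raises(ValueError, match="conflict"):
            build_masked_transcript(tr, [v1, v2], gene)

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_masking_involution(self, data):
        """Unmasking with the diagnostic table restores the transcript."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        tr = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        gene = self._gene(200)
        n_var = data.draw(st.integers(0, 10))
        positions = rng.choice(200, size=n_var, replace=False)
        vs = []
        for p in positions:
            p = int(p)
            alt = "A" if tr[p] != "A" else "G"
            vs.append(RetroVariant(GenomicInterval("c", p, p + 1), tr[p], alt,
                                   "retrocopy", fixed_across_copies=True))
        masked, table = build_masked_transcript(tr, vs, gene)
        assert unmask_transcript(masked, table) == tr
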
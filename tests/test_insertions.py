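"""Discordant clustering, breakpoint/TSD resolution, junction reads,
reference-retrocopy absence, and sex-bias flagging."""

import numpy as np
import pytest

from retroscout.formats_io import AlignedRead, GenomicInterval, GeneModel, revcomp
from retroscout.insertions import (
    cluster_mates, detect_junction_reads, find_discordant_pairs, flag_sex_bias,
    junction_windows, reference_retrocopy_absence, resolve_breakpoints,
)
from retroscout.synthetic import (
    ImplantedGenome, RetrocopyTruth, SimConfig, generate_genome, simulate_reads,
)
from retroscout.kmers import extract_transcript


def _read(chrom="chr1", start=100, mate_chrom="chr2", mate_start=500,
          proper=False, rl=50, **kw):
    return AlignedRead(
        kw.pop("read_id", f"r{start}"), chrom, start, start + rl, False,
        "A" * rl, (("M", rl),), is_paired=True, is_proper_pair=proper,
        mate_chrom=mate_chrom, mate_start=mate_start, **kw,
    )


GENE = GeneModel("g", "t", (
    GenomicInterval("chr1", 100, 200, "+"),
    GenomicInterval("chr1", 500, 700, "+"),
), "+")


class TestFindDiscordant:
    def test_exon_overlap_with_interchromosomal_mate_kept(self):
        r = _read(start=150)
        assert find_discordant_pairs([r], GENE) == [r]

    def test_proper_pair_excluded(self):
        r = _read(start=150, mate_chrom="chr1", mate_start=300, proper=True)
        assert find_discordant_pairs([r], GENE) == []

    def test_intron_only_overlap_excluded(self):
        r = _read(start=300, rl=50)  # inside the 200-500 intron
        assert find_discordant_pairs([r], GENE) == []

    def test_distant_same_chromosome_mate_kept(self):
        r = _read(start=150, mate_chrom="chr1", mate_start=50_000)
        assert find_discordant_pairs([r], GENE, d_max=10_000) == [r]


def brute_force_single_linkage(positions, gap):
    """Oracle: split sorted positions wherever neighbors differ by > gap."""
    groups, cur = [], []
    for p in sorted(positions):
        if cur and p - cur[-1] > gap:
            groups.append(cur)
            cur = []
        cur.append(p)
    if cur:
        groups.append(cur)
    return groups


class TestClusterMates:
    def test_eight_mates_one_cluster(self):
        reads = [_read(start=100 + i, mate_start=500 + 30 * i, read_id=f"r{i}")
                 for i in range(8)]
        (c,) = cluster_mates(reads, cluster_window=300, min_support=4)
        assert c.support == 8

    def test_below_min_support_dropped(self):
        reads = [_read(start=100 + i, mate_start=500 + i, read_id=f"r{i}")
                 for i in range(3)]
        assert cluster_mates(reads, min_support=4) == []

    def test_distant_groups_split_matches_oracle(self, rng):
        positions = sorted(
            list(rng.integers(1000, 1400, 6)) + list(rng.integers(12_000, 12_300, 7))
        )
        reads = [_read(start=100, mate_start=int(p), read_id=f"r{i}")
                 for i, p in enumerate(positions)]
        clusters = cluster_mates(reads, cluster_window=500, min_support=4)
        oracle = brute_force_single_linkage(positions, 500)
        assert len(clusters) == len([g for g in oracle if len(g) >= 4]) == 2
        for c, g in zip(clusters, [g for g in oracle if len(g) >= 4]):
            assert c.support == len(g)
            assert (c.interval.start, c.interval.end - 1) == (min(g), max(g))


def _clip_read(read_id, start, end, seq, left_clip=0, right_clip=0):
    ops = []
    if left_clip:
        ops.append(("S", left_clip))
    ops.append(("M", end - start))
    if right_clip:
        ops.append(("S", right_clip))
    return AlignedRead(read_id, "chr2", start, end, False, seq, tuple(ops),
                       left_clip=left_clip, right_clip=right_clip)


class TestResolveBreakpoints:
    def _end_to_end(self, toy, tsd_length, seed=5):
        cfg, genome, genes = toy
        ig = ImplantedGenome(genome, genes)
        truth = ig.insert_retrocopy(RetrocopyTruth(
            gene_id="gene2", site=8000, chrom="chr2", tsd_length=tsd_length))
        _, _, sam = simulate_reads(ig, cfg, np.random.default_rng(seed))
        gene = next(g for g in genes if g.gene_id == "gene2")
        cands = find_discordant_pairs(sam, gene)
        (cluster,) = cluster_mates(cands, gene_id="gene2")
        return truth, resolve_breakpoints(cluster, sam, genome)

    def test_median_length_tsd_recovered_exactly(self, toy):
        truth, call = self._end_to_end(toy, tsd_length=17)
        assert call.tsd_sequence == truth.tsd_sequence
        assert call.tsd_length == 17
        assert call.interval == truth.insertion_interval

    def test_tsd_self_consistency(self, toy):
        _, genome, _ = toy
        _, call = self._end_to_end(toy, tsd_length=23)
        iv = call.interval
        assert call.tsd_sequence == genome[iv.chrom][iv.start : iv.end]

    def test_modal_breakpoint_wins(self):
        genome = {"chr2": "ACGT" * 2500}
        from retroscout.insertions import DiscordantCluster
        cl = DiscordantCluster("g", GenomicInterval("chr2", 4000, 4200), ("a",) * 6,
                               {"s1": 6})
        reads = (
            [_clip_read(f"L{i}", 3950, 4000, "A" * 80, right_clip=30)
             for i in range(6)]
            + [_clip_read(f"l{i}", 3952, 4005, "A" * 83, right_clip=30)
               for i in range(2)]
            + [_clip_read(f"R{i}", 3983, 4050, "A" * 97, left_clip=30)
               for i in range(5)]
        )
        call = resolve_breakpoints(cl, reads, genome)
        # modal left edge 4000 (6 > 2), right edge 3983 -> TSD = [3983, 4000)
        assert (call.interval.start, call.interval.end) == (3983, 4000)
        assert call.tsd_length == 17

    def test_blunt_insertion_has_null_tsd(self):
        genome = {"chr2": "ACGT" * 2500}
        from retroscout.insertions import DiscordantCluster
        cl = DiscordantCluster("g", GenomicInterval("chr2", 4000, 4200), ("a",) * 4,
                               {"s1": 4})
        reads = (
            [_clip_read(f"L{i}", 3950, 4000, "A" * 80, right_clip=30)
             for i in range(4)]
            + [_clip_read(f"R{i}", 4000, 4060, "A" * 90, left_clip=30)
               for i in range(4)]
        )
        call = resolve_breakpoints(cl, reads, genome)
        assert call.tsd_sequence is None and call.tsd_length == 0

    def test_no_clips_yields_low_resolution_call(self):
        genome = {"chr2": "ACGT" * 2500}
        from retroscout.insertions import DiscordantCluster
        cl = DiscordantCluster("g", GenomicInterval("chr2", 4000, 4200), ("a",) * 4,
                               {"s1": 4})
        call = resolve_breakpoints(cl, [], genome)
        assert not call.resolved and call.tsd_sequence is None
        assert call.interval == cl.interval


class TestJunctionReads:
    def test_junction_spanning_read_counted(self, toy):
        _, genome, genes = toy
        gene = genes[0]
        tr = extract_transcript(genome, gene)
        lens = [len(e) for e in gene.exons]
        windows = junction_windows(tr, lens, j=20)
        read = "T" * 10 + windows[0] + "G" * 10
        counts = detect_junction_reads([read], {gene.gene_id: windows})
        assert counts[gene.gene_id] == 1
        # reverse-complement read also counts
        counts = detect_junction_reads([revcomp(read)], {gene.gene_id: windows})
        assert counts[gene.gene_id] == 1

    def test_exon_into_intron_not_counted(self, toy):
        _, genome, genes = toy
        gene = genes[0]
        tr = extract_transcript(genome, gene)
        lens = [len(e) for e in gene.exons]
        windows = junction_windows(tr, lens, j=20)
        # genomic (intron-containing) context around the first exon boundary
        e0 = sorted(gene.exons, key=lambda e: e.start)[0]
        genomic = genome[gene.chrom][e0.end - 20 : e0.end + 20]
        counts = detect_junction_reads([genomic], {gene.gene_id: windows})
        assert counts[gene.gene_id] == 0

    def test_clean_reads_have_zero_junction_hits(self, toy, rng):
        cfg, genome, genes = toy
        cfg0 = SimConfig(**{**cfg.__dict__, "error_rate": 0.0, "coverage": 5.0})
        ig = ImplantedGenome(genome, genes)
        fq1, fq2, _ = simulate_reads(ig, cfg0, rng, with_sam=False)
        wbg = {}
        for g in genes:
            tr = extract_transcript(genome, g)
            wbg[g.gene_id] = junction_windows(tr, [len(e) for e in g.exons])
        counts = detect_junction_reads(
            [s for _, s in fq1] + [s for _, s in fq2], wbg)
        assert all(v == 0 for v in counts.values())

    def test_window_longer_than_read_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            detect_junction_reads([], {"g": ["A" * 60]}, read_length=50)


class TestReferenceRetrocopyAbsence:
    def _simulate(self, toy, mode, seed=9):
        """Two-haplotype read simulation over a reference retrocopy locus."""
        cfg, genome, genes = toy
        interval = GenomicInterval("chr2", 10_000, 12_000)
        half = SimConfig(**{**cfg.__dict__, "coverage": cfg.coverage / 2})
        reads = []
        for h in range(2):
            ig = ImplantedGenome(genome, genes)
            if mode == "hom" or (mode == "het" and h == 0):
                ig.delete_interval("chr2", (10_000, 12_000))
            _, _, sam = simulate_reads(
                ig, half, np.random.default_rng(seed + h), f"h{h}")
            reads.extend(sam)
        return reads, interval, cfg.coverage

    @pytest.mark.parametrize("mode,expected", [
        ("present", "present"), ("het", "het_absent"), ("hom", "hom_absent"),
    ])
    def test_classification(self, toy, mode, expected):
        reads, interval, depth = self._simulate(toy, mode)
        state, ev = reference_retrocopy_absence(reads, interval, depth)
        assert state == expected

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            reference_retrocopy_absence([], GenomicInterval("c", 0, 100), 0)


class TestSexBias:
    def test_male_only_evidence_flagged(self):
        ev = {"g": {**{f"m{i}": True for i in range(4)},
                    **{f"f{i}": False for i in range(6)}}}
        sex = {**{f"m{i}": "M" for i in range(4)}, **{f"f{i}": "F" for i in range(6)}}
        assert flag_sex_bias(ev, sex) == {"g": True}

    def test_any_female_evidence_unflags(self):
        ev = {"g": {"m0": True, "m1": True, "m2": True, "f0": True}}
        sex = {"m0": "M", "m1": "M", "m2": "M", "f0": "F"}
        assert flag_sex_bias(ev, sex) == {"g": False}

    def test_single_sex_cohort_not_evaluable(self):
        ev = {"g": {"m0": True}}
        with pytest.warns(UserWarning, match="not evaluable"):
            flags = flag_sex_bias(ev, {"m0": "M"})
        assert flags == {"g": False}

    def test_missing_annotation_warns(self):
        ev = {"g": {"m0": True, "m1": True, "x": True, "f0": False}}
        sex = {"m0": "M", "m1": "M", "f0": "F"}
        with pytest.warns(UserWarning, match="missing sex"):
            flags = flag_sex_bias(ev, sex)
        assert flags == {"g": True}
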
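"""End-to-end orchestration: simulate -> k-mers -> calls -> insertions ->
variants -> copy number -> expression -> dating, with a provenance manifest.

The pipeline is declarative: a single schema-validated config drives every
stage, artifacts land in one output directory, and a manifest records the
parameters, seed and outputs of each stage so re-runs can skip completed
work and stochastic outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .formats_io import (
    write_bed, write_fasta, write_fastq, write_gff3, write_sam, write_vcf,
)
from .insertions import cluster_mates, find_discordant_pairs, resolve_breakpoints
from .kmers import (
    build_specific_kmers, call_parent_genes, extract_transcript, scan_reads,
    write_calls, write_inventories,
)
from .quant import compute_tpm, estimate_copy_number, partition_reads
from .dating import DivergenceRecord, aggregate_ages, estimate_age
from .synthetic import (
    ImplantedGenome, RetrocopyTruth, SimConfig, simulate_reads,
    simulate_rnaseq, write_truth_table,
)
from .variants import (
    attribute_variants, build_masked_transcript, classify_all, pileup_alleles,
    select_fixed_variants, variants_to_vcf_records,
)

STAGES = ("simulate", "kmers", "scan", "call", "resolve", "attribute",
          "cn", "ase", "age")

_SCHEMA: dict[str, dict[str, type]] = {
    "simulate": {
        "genome_length": int, "n_chroms": int, "n_genes": int,
        "coverage": (int, float), "error_rate": (int, float),
        "n_samples": int, "n_insertions": int, "read_length": int,
    },
    "kmers": {"k": int, "max_mismatch": int, "t_min": int, "f_min": (int, float)},
    "resolve": {"d_max": int, "cluster_window": int, "min_support": int},
    "variants": {"r_min": int, "tau_fixed": (int, float)},
    "age": {"mu": (int, float), "generation_time": (int, float), "k_lin": int},
    "ase": {"enabled": bool, "retro_fraction": (int, float), "n_pairs": int},
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "genome_length": 300_000, "n_chroms": 2, "n_genes": 8,
        "coverage": 20.0, "error_rate": 0.002, "n_samples": 2,
        "n_insertions": 3, "read_length": 100,
    },
    "kmers": {"k": 30, "max_mismatch": 2, "t_min": 5, "f_min": 0.10},
    "resolve": {"d_max": 10_000, "cluster_window": 500, "min_support": 4},
    "variants": {"r_min": 3, "tau_fixed": 0.5},
    "age": {"mu": 7.24e-9, "generation_time": 8.0, "k_lin": 1},
    "ase": {"enabled": True, "retro_fraction": 0.8, "n_pairs": 4000},
}


class ConfigError(ValueError):
    pass


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Merge a user config over the defaults, with schema checking."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if key == "seed":
            if not isinstance(val, int):
                raise ConfigError("seed must be an integer")
            merged["seed"] = val
            continue
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config section {key!r}")
        if not isinstance(val, Mapping):
            raise ConfigError(f"section {key!r} must be a mapping")
        for k2, v2 in val.items():
            if k2 not in _SCHEMA[key]:
                raise ConfigError(f"unknown key {key}.{k2}")
            if not isinstance(v2, _SCHEMA[key][k2]):
                raise ConfigError(f"{key}.{k2} has wrong type")
            merged[key][k2] = v2
    sim = merged["simulate"]
    if sim["coverage"] <= 0:
        raise ConfigError("simulate.coverage must be > 0")
    if not 0 <= sim["error_rate"] < 0.05:
        raise ConfigError("simulate.error_rate must be in [0, 0.05)")
    if sim["n_samples"] < 1 or sim["n_insertions"] < 0:
        raise ConfigError("simulate.n_samples/n_insertions out of range")
    return merged


@dataclass
class CohortSummary:
    """Cohort-level bookkeeping over resolved calls."""

    per_sample_counts: dict[str, int]
    carriers_by_event: dict[str, tuple[str, ...]]
    allele_frequency: dict[str, float]
    population_totals: dict[str, int]
    population_averages: dict[str, float]
    exclusive_counts: dict[str, int]


def summarize_cohort(
    carriers_by_event: Mapping[str, Sequence[str]],
    populations: Mapping[str, str],
) -> CohortSummary:
    """Set algebra over carrier lists.

    ``carriers_by_event``: event id -> carrier sample ids.
    ``populations``: sample id -> population label. An event is exclusive
    to a population when all of its carriers belong to it.
    """
    for event, samples in carriers_by_event.items():
        for s in samples:
            if s not in populations:
                raise ConfigError(f"sample {s!r} has no population label")
    per_sample = {s: 0 for s in populations}
    for samples in carriers_by_event.values():
        for s in samples:
            per_sample[s] += 1
    n_samples = len(populations)
    af = {
        e: len(set(ss)) / n_samples for e, ss in carriers_by_event.items()
    }
    pops = sorted(set(populations.values()))
    totals = {
        p: sum(
            1 for ss in carriers_by_event.values()
            if any(populations[s] == p for s in ss)
        )
        for p in pops
    }
    averages = {
        p: (
            float(np.mean([per_sample[s] for s in populations if populations[s] == p]))
            if any(populations[s] == p for s in populations) else 0.0
        )
        for p in pops
    }
    exclusive = {
        p: sum(
            1 for ss in carriers_by_event.values()
            if ss and all(populations[s] == p for s in ss)
        )
        for p in pops
    }
    return CohortSummary(
        per_sample, {e: tuple(ss) for e, ss in carriers_by_event.items()},
        af, totals, averages, exclusive,
    )


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

class Pipeline:
    """Stage runner with manifest-based idempotence."""

    def __init__(self, config: Mapping[str, Any], outdir: str | os.PathLike):
        self.config = validate_config(config)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest: dict[str, Any] = {"version": __version__,
                                         "seed": self.config["seed"], "stages": {}}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())

    def _stage_done(self, name: str, params: Mapping[str, Any]) -> bool:
        rec = self.manifest["stages"].get(name)
        if not rec or rec.get("params") != dict(params):
            return False
        return all((self.outdir / f).exists() for f in rec.get("outputs", []))

    def _record(self, name: str, params: Mapping[str, Any],
                outputs: Sequence[str], counts: Mapping[str, int]) -> None:
        self.manifest["stages"][name] = {
            "params": dict(params), "outputs": list(outputs),
            "counts": dict(counts),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    # The pipeline is exercised on the bundled simulator; externally
    # produced FASTQ/SAM drop in at the scan/resolve stages via the same
    # file layout.
    def run(self) -> dict[str, Any]:
        cfg = self.config
        seed = cfg["seed"]
        rng = np.random.default_rng(seed)
        sim_cfg = SimConfig(
            seed=seed,
            genome_length=cfg["simulate"]["genome_length"],
            n_chroms=cfg["simulate"]["n_chroms"],
            n_genes=cfg["simulate"]["n_genes"],
            coverage=float(cfg["simulate"]["coverage"]),
            error_rate=float(cfg["simulate"]["error_rate"]),
            read_length=cfg["simulate"]["read_length"],
        )
        n_samples = cfg["simulate"]["n_samples"]
        n_ins = cfg["simulate"]["n_insertions"]
        results: dict[str, Any] = {}

        from .synthetic import generate_genome  # local to keep import graph simple

        # -- simulate ----------------------------------------------------
        params = {**cfg["simulate"], "seed": seed}
        genome, genes = generate_genome(sim_cfg, np.random.default_rng(seed))
        target_chrom = list(genome)[-1]
        gene_by_id = {g.gene_id: g for g in genes}
        pick = [genes[i] for i in
                rng.choice(len(genes), size=min(n_ins, len(genes)), replace=False)]
        truths: list[RetrocopyTruth] = []
        carriers_truth: dict[str, set[str]] = {}
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
        sample_igs: dict[str, ImplantedGenome] = {}
        site_cursor = 2000
        chrom_len = len(genome[target_chrom])
        planned = []
        for gmodel in pick:
            tsd = int(rng.integers(10, 32))
            site = site_cursor + int(rng.integers(0, 2000))
            site_cursor = site + 4000
            if site > chrom_len - 2000:
                raise ConfigError("target chromosome too small for insertions")
            transcript = extract_transcript(genome, gmodel)
            v_off = int(rng.integers(5, len(transcript) - 5))
            shared = ((v_off, transcript[v_off],
                       str(rng.choice([b for b in "ACGT" if b != transcript[v_off]]))),)
            planned.append(RetrocopyTruth(
                gene_id=gmodel.gene_id, site=site, chrom=target_chrom,
                tsd_length=tsd, polyA_length=30, shared_variants=shared,
            ))
        for s_i, sid in enumerate(sample_ids):
            ig = ImplantedGenome(genome, genes)
            carried: set[str] = set()
            for t_i, truth in enumerate(planned):
                # even samples carry every event, odd samples none, so the
                # cohort always has a carrier/non-carrier contrast
                carry = s_i % 2 == 0 if n_samples > 1 else True
                if carry:
                    done = ig.insert_retrocopy(truth)
                    carried.add(truth.gene_id)
                    truths.append(done)
            carriers_truth[sid] = carried
            sample_igs[sid] = ig
        if not self._stage_done("simulate", params):
            write_fasta(genome, self.outdir / "reference.fa")
            write_gff3(genes, self.outdir / "annotation.gff3")
            unique_truths = {t.gene_id: t for t in truths}
            write_truth_table(unique_truths.values(), self.outdir / "truth.tsv")
            self._record("simulate", params,
                         ["reference.fa", "annotation.gff3", "truth.tsv"],
                         {"genes": len(genes), "insertions": len(planned)})
        reads_by_sample = {}
        fastq_by_sample = {}
        for sid in sample_ids:
            srng = np.random.default_rng((seed * 1000 + sample_ids.index(sid)) % (2**31))
            fq1, fq2, sam = simulate_reads(sample_igs[sid], sim_cfg, srng, sid)
            reads_by_sample[sid] = sam
            fastq_by_sample[sid] = [s for _, s in fq1] + [s for _, s in fq2]
            f1 = self.outdir / f"{sid}_R1.fastq"
            if not f1.exists():
                write_fastq(fq1, f1)
                write_fastq(fq2, self.outdir / f"{sid}_R2.fastq")
                write_sam(sam, self.outdir / f"{sid}.sam",
                          {c: len(s) for c, s in genome.items()})
        results["truth_carriers"] = carriers_truth

        # -- kmers -------------------------------------------------------
        kp = cfg["kmers"]
        transcripts = {g.gene_id: extract_transcript(genome, g) for g in genes}
        inventories = build_specific_kmers(transcripts, genome,
                                           k=kp["k"], max_mismatch=kp["max_mismatch"])
        if not self._stage_done("kmers", kp):
            write_inventories(inventories, self.outdir / "inventory.tsv.gz")
            self._record("kmers", kp, ["inventory.tsv.gz"],
                         {"genes": len(inventories),
                          "kmers": sum(v.total_count for v in inventories.values())})

        # -- scan + call ---------------------------------------------------
        calls_by_sample = {}
        all_calls = []
        for sid in sample_ids:
            counts = scan_reads(inventories, fastq_by_sample[sid])
            calls = call_parent_genes(counts, inventories,
                                      t_min=kp["t_min"], f_min=kp["f_min"],
                                      sample_id=sid)
            calls_by_sample[sid] = {c.gene_id for c in calls if c.called}
            all_calls.extend(calls)
        if not self._stage_done("call", kp):
            write_calls(all_calls, self.outdir / "calls.tsv")
            self._record("call", kp, ["calls.tsv"],
                         {"called": sum(c.called for c in all_calls)})
        results["calls"] = calls_by_sample

        # -- resolve -------------------------------------------------------
        rp = cfg["resolve"]
        insertion_calls = []
        all_reads = [r for rs in reads_by_sample.values() for r in rs]
        called_genes = sorted(set().union(*calls_by_sample.values()))
        for gid in called_genes:
            gmodel = gene_by_id[gid]
            cands = find_discordant_pairs(all_reads, gmodel, d_max=rp["d_max"])
            clusters = cluster_mates(cands, cluster_window=rp["cluster_window"],
                                     min_support=rp["min_support"], gene_id=gid)
            for cl in clusters:
                insertion_calls.append(resolve_breakpoints(cl, all_reads, genome))
        if not self._stage_done("resolve", rp):
            with open(self.outdir / "insertions.tsv", "w") as fh:
                fh.write("gene_id\tchrom\tstart\tend\ttsd_length\ttsd\tsupport\tsamples\n")
                for ic in insertion_calls:
                    fh.write(
                        f"{ic.gene_id}\t{ic.interval.chrom}\t{ic.interval.start}\t"
                        f"{ic.interval.end}\t{ic.tsd_length}\t{ic.tsd_sequence or '.'}\t"
                        f"{ic.discordant_support}\t{','.join(ic.samples)}\n"
                    )
            write_bed([(ic.interval, ic.gene_id) for ic in insertion_calls],
                      self.outdir / "insertions.bed")
            self._record("resolve", rp, ["insertions.tsv", "insertions.bed"],
                         {"in_genes": len(called_genes),
                          "out_insertions": len(insertion_calls)})
        results["insertions"] = insertion_calls

        # -- attribute -----------------------------------------------------
        vp = cfg["variants"]
        variant_rows = []
        fixed_by_gene = {}
        for gid in called_genes:
            gmodel = gene_by_id[gid]
            carrier_map = {sid: gid in carriers_truth[sid] for sid in sample_ids}
            sites = pileup_alleles(
                {sid: [r for r in reads_by_sample[sid]
                       if r.chrom == gmodel.chrom] for sid in sample_ids},
                gmodel.exons, genome, r_min=vp["r_min"])
            attributed = attribute_variants(sites, carrier_map)
            attributed = classify_all(attributed, gmodel, transcripts[gid])
            cn_by_sample = {sid: 1.0 for sid in sample_ids}
            attributed = select_fixed_variants(
                attributed, None, sites, cn_by_sample, carrier_map,
                tau_fixed=vp["tau_fixed"])
            fixed_by_gene[gid] = [v for v in attributed
                                  if v.fixed_across_copies and not v.is_indel]
            variant_rows.extend(attributed)
        if not self._stage_done("attribute", vp):
            write_vcf(variants_to_vcf_records(variant_rows),
                      self.outdir / "variants.vcf")
            self._record("attribute", vp, ["variants.vcf"],
                         {"variants": len(variant_rows),
                          "retrocopy": sum(v.attribution == "retrocopy"
                                           for v in variant_rows)})
        results["variants"] = variant_rows

        # -- cn ------------------------------------------------------------
        genome_bp = sum(len(s) for s in genome.values())
        cn_rows = {}
        for sid in sample_ids:
            aligned = sum(sum(n for op, n in r.cigar if op == "M")
                          for r in reads_by_sample[sid])
            gdepth = aligned / genome_bp
            for ic in insertion_calls:
                if sid not in ic.samples:
                    continue
                gmodel = gene_by_id[ic.gene_id]
                est = estimate_copy_number(
                    [r for r in reads_by_sample[sid] if r.chrom == gmodel.chrom],
                    gmodel.span, gdepth, sample_id=sid)
                cn_rows[(sid, ic.gene_id)] = est.copy_number
        if not self._stage_done("cn", {}):
            with open(self.outdir / "copy_number.tsv", "w") as fh:
                fh.write("sample_id\tgene_id\tdepth_ratio\n")
                for (sid, gid), v in sorted(cn_rows.items()):
                    fh.write(f"{sid}\t{gid}\t{v:.3f}\n")
            self._record("cn", {}, ["copy_number.tsv"], {"rows": len(cn_rows)})
        results["cn"] = cn_rows

        # -- ase -----------------------------------------------------------
        ap = cfg["ase"]
        if ap["enabled"]:
            gid = next((g for g in called_genes if fixed_by_gene.get(g)), None)
            if gid is not None:
                gmodel = gene_by_id[gid]
                masked, table = build_masked_transcript(
                    transcripts[gid], fixed_by_gene[gid], gmodel)
                retro_seq = list(transcripts[gid])
                for row in table:
                    retro_seq[row["position"]] = row["retro_allele"]
                pool = [("parent", transcripts[gid], 1 - ap["retro_fraction"]),
                        ("retro", "".join(retro_seq), ap["retro_fraction"])]
                rna = simulate_rnaseq(pool, ap["n_pairs"], sim_cfg,
                                      np.random.default_rng(seed + 77))
                part = partition_reads(rna, table)
                tpm = compute_tpm(
                    {"parent": part.parent_reads, "retro": part.retro_reads},
                    {"parent": len(masked), "retro": len(masked)})
                results["ase"] = {"partition": part, "tpm": tpm, "gene": gid}
                if not self._stage_done("ase", ap):
                    with open(self.outdir / "expression.tsv", "w") as fh:
                        fh.write("gene\tparent_reads\tretro_reads\tunassigned\t"
                                 "retro_fraction\n")
                        fh.write(f"{gid}\t{part.parent_reads}\t{part.retro_reads}\t"
                                 f"{part.unassigned_reads}\t{part.retro_fraction:.4f}\n")
                    self._record("ase", ap, ["expression.tsv"],
                                 {"pairs": part.total})

        # -- age -----------------------------------------------------------
        agep = cfg["age"]
        age_rows = []
        for gid in called_genes:
            n_retro = sum(1 for v in results["variants"]
                          if v.attribution == "retrocopy" and not v.is_indel)
            rec = DivergenceRecord(gid, min(n_retro, len(transcripts[gid])),
                                   len(transcripts[gid]))
            est = estimate_age(rec, mu=float(agep["mu"]),
                               generation_time=float(agep["generation_time"]),
                               k_lin=agep["k_lin"])
            age_rows.append(est)
        if age_rows and not self._stage_done("age", agep):
            agg = aggregate_ages(age_rows)
            with open(self.outdir / "ages.tsv", "w") as fh:
                fh.write("pair_id\tS\tL\tage_years\n")
                for e in age_rows:
                    fh.write(f"{e.record.pair_id}\t{e.record.substitutions}\t"
                             f"{e.record.aligned_length}\t{e.age_years:.1f}\n")
            self._record("age", agep, ["ages.tsv"], {"estimates": len(age_rows)})
        results["ages"] = age_rows
        return results


def run_pipeline(config: Mapping[str, Any], outdir: str | os.PathLike) -> dict[str, Any]:
    """Validate config, run all stages in dependency order, return results."""
    return Pipeline(config, outdir).run()


def load_config(path: str | os.PathLike) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
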
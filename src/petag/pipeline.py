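"""End-to-end orchestration: simulate -> search -> process -> nominate ->
call -> analyze -> report.

Each stage logs its in/out counts, writes its intermediate artifacts into the
output directory, and is recorded in a manifest keyed by the configuration
hash; re-running with ``resume=True`` reloads unchanged upstream artifacts
instead of recomputing them.  All randomness flows from the single config
seed through spawned generator streams.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

from . import analytics, editcall, nomination, readproc, search, simulate
from .config import PipelineConfig, config_hash
from .genome import Genome

log = logging.getLogger("petag")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def _designate_edited(planted, validated_fraction: float) -> dict[str, bool]:
    """Which planted sites truly undergo editing (the on-target always does)."""
    offs = [s.name for s in planted if s.name != "on_target"]
    n_edited = int(round(validated_fraction * len(offs)))
    edited = {"on_target": True}
    for i, name in enumerate(offs):
        edited[name] = i < n_edited
    return edited


def run_pipeline(
    config: PipelineConfig, outdir, resume: bool = False
) -> dict:
    """Execute the full pipeline; returns the machine-readable summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest_path = outdir / "manifest.json"
    old_manifest = {}
    if resume and manifest_path.exists():
        try:
            old_manifest = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            old_manifest = {}
    can_resume = resume and old_manifest.get("config_hash") == chash
    artifacts: list[str] = []
    summary: dict = {"seed": config.seed, "stages": {}}

    def declare(*names: str) -> None:
        artifacts.extend(names)

    def have(*names: str) -> bool:
        return can_resume and all(
            n in old_manifest.get("artifacts", []) and (outdir / n).exists()
            for n in names
        )

    ss = np.random.SeedSequence(config.seed)
    sim_seeds = ss.spawn(4)

    # ---- stage: simulate / load inputs -----------------------------------
    planted = None
    truth = None
    edited_sites: dict[str, bool] = {}
    try:
        if config.simulate is not None:
            sim = config.simulate
            pegrna, block, proto_off = simulate.example_target()
            if config.pegrna.name != "toy_peg":
                pegrna, block, proto_off = config.pegrna, None, 0
            genome_path, reads_path = "genome.fa", "reads.fastq"
            rng_g = np.random.default_rng(sim_seeds[0])
            genome, planted = simulate.make_genome(
                pegrna, sim, rng=rng_g,
                on_target_block=block, on_target_proto_offset=proto_off,
            )
            edited_sites = _designate_edited(planted, config.amplicon.validated_fraction)
            activity = {
                name: 1.0 if is_edited else sim.false_site_activity
                for name, is_edited in edited_sites.items()
            }
            false_rates = {
                name: sim.false_tagmentation_rate if is_edited else sim.false_site_false_rate
                for name, is_edited in edited_sites.items()
            }
            rng_r = np.random.default_rng(sim_seeds[1])
            reads, truth = simulate.simulate_tape_reads(
                genome, planted, pegrna, sim, rng=rng_r,
                site_activity=activity, site_false_rate=false_rates,
            )
            genome.to_fasta(outdir / genome_path)
            simulate.write_fastq(reads, outdir / reads_path)
            simulate.write_truth(
                truth, outdir / "truth_sites.tsv", outdir / "truth_reads.tsv"
            )
            declare(genome_path, reads_path, "truth_sites.tsv", "truth_reads.tsv")
            log.info("simulate: %d planted sites, %d reads", len(planted), len(reads))
        else:
            pegrna = config.pegrna
            if config.genome is None:
                raise FileNotFoundError("no genome path and no simulate block")
            genome = Genome.from_fasta(config.genome)
            reads = _read_fastq(config.reads) if config.reads else []
            log.info("load: %d contigs, %d reads", len(genome), len(reads))
        summary["stages"]["inputs"] = {
            "n_reads": len(reads),
            "n_planted_sites": len(planted) if planted else 0,
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _write_manifest(manifest_path, chash, artifacts, failed="inputs")
        raise StageError("inputs", exc) from exc

    # ---- stage: search ----------------------------------------------------
    try:
        sites_path = outdir / "sites.tsv"
        if have("sites.tsv"):
            sites = search.read_sites(sites_path)
            log.info("search: resumed %d sites from %s", len(sites), sites_path)
        else:
            sites = search.find_candidates(
                genome, pegrna.spacer, pegrna.pam_pattern,
                config.search.max_mismatch, config.search.max_bulge,
            )
            sites = search.annotate_nick(sites, config.filters.cut_offset)
            sites = search.collapse_by_nick(sites)
            search.write_sites(sites, sites_path)
            search.write_bed(sites, outdir / "sites.bed")
        declare("sites.tsv", "sites.bed")
        summary["stages"]["search"] = {"n_candidates": len(sites)}
        log.info("search: %d candidate sites", len(sites))
    except Exception as exc:  # noqa: BLE001
        _write_manifest(manifest_path, chash, artifacts, failed="search")
        raise StageError("search", exc) from exc

    # ---- stage: process ---------------------------------------------------
    try:
        audit_path = outdir / "read_audit.tsv"
        queries = readproc.default_tag_queries(
            pegrna.tag.full_tag if pegrna.tag else simulate.example_target()[0].tag.full_tag
        )
        counts = {"input": len(reads), "tag_detected": 0, "trimmed": 0, "mapped": 0}
        if config.sam:
            mappings, sam_counts = readproc.ingest_sam(config.sam)
            counts["mapped"] = len(mappings)
            counts.update({f"sam_{k}": v for k, v in sam_counts.items()})
        else:
            index = readproc.KmerIndex(genome, config.mapper.seed_k)
            mappings = []
            with open(audit_path, "w") as audit:
                audit.write("read_id\tstage\tdisposition\treason\n")
                for rid, seq in reads:
                    hits = readproc.detect_tag_all(seq, queries, read_id=rid)
                    if not hits:
                        audit.write(f"{rid}\tdetect\tdiscarded\tno_tag_query\n")
                        continue
                    counts["tag_detected"] += 1
                    # a read spanning the tag has two genomic flanks; keep the
                    # first junction side whose flank trims and maps
                    m = None
                    trimmed_any = False
                    for hit in hits:
                        trimmed = readproc.trim_tag(seq, hit)
                        if trimmed is None:
                            continue
                        trimmed_any = True
                        fragment, side = trimmed
                        m = readproc.map_fragment(
                            fragment, index, config.mapper.max_mismatch,
                            read_id=rid, tag_end="R" if side == "left" else "L",
                        )
                        if m is not None:
                            break
                    if not trimmed_any:
                        audit.write(f"{rid}\ttrim\tdiscarded\tempty_fragment\n")
                        continue
                    counts["trimmed"] += 1
                    if m is None:
                        audit.write(f"{rid}\tmap\tdiscarded\tno_unique_placement\n")
                        continue
                    counts["mapped"] += 1
                    audit.write(f"{rid}\tmap\tkept\tmapped\n")
                    mappings.append(m)
            readproc.write_sam(mappings, genome, outdir / "mappings.sam")
            declare("mappings.sam", "read_audit.tsv")
        filtered = readproc.filter_mappings(mappings, config.filters.min_mapped_length)
        counts["after_length_filter"] = len(filtered)
        summary["stages"]["process"] = counts
        log.info("process: %s", counts)
    except Exception as exc:  # noqa: BLE001
        _write_manifest(manifest_path, chash, artifacts, failed="process")
        raise StageError("process", exc) from exc

    # ---- stage: nominate --------------------------------------------------
    try:
        reports, n_ambiguous = nomination.build_site_reports(
            filtered, sites,
            flank=config.filters.flank,
            nick_tolerance=config.filters.nick_tolerance,
            min_copy=config.filters.min_copy,
        )
        nominated = nomination.nominate(reports, config.filters.min_copy)
        nomination.write_site_reports(reports, outdir / "site_reports.tsv")
        nomination.write_nominated_bed(nominated, outdir / "nominated.bed")
        declare("site_reports.tsv", "nominated.bed")
        summary["stages"]["nominate"] = {
            "n_sites": len(reports),
            "n_nominated": len(nominated),
            "n_ambiguous_reads": n_ambiguous,
        }
        log.info("nominate: %d/%d sites nominated", len(nominated), len(reports))
    except Exception as exc:  # noqa: BLE001
        _write_manifest(manifest_path, chash, artifacts, failed="nominate")
        raise StageError("nominate", exc) from exc

    # ---- stage: call (simulated amplicon validation) ----------------------
    validation_records: list[editcall.ValidationRecord] = []
    validated_keys: list[analytics.SiteKey] = []
    try:
        if planted is not None and pegrna.tag is not None:
            amp = config.amplicon
            tables = []
            rng_amp = np.random.default_rng(sim_seeds[2])
            for site in planted:
                win = 60
                ref_window = genome.fetch(
                    site.contig, site.nick - win, site.nick + win, site.strand
                )
                is_edited = edited_sites.get(site.name, False)
                treated_freqs = (
                    {
                        "major_edited": amp.major_edited_freq,
                        "tagmented_case1_with_edit": amp.tagmented_freq * 0.7,
                        "tagmented_case1_tag_only": amp.tagmented_freq * 0.1,
                        "tagmented_case2": amp.tagmented_freq * 0.2,
                        "deletion": amp.indel_freq,
                    }
                    if is_edited
                    else {}
                )
                treated_t, control_t = [], []
                for _ in range(amp.replicates):
                    t_reads, _ = simulate.simulate_amplicon_reads(
                        pegrna, ref_window, win, treated_freqs, amp.n_reads,
                        seed=int(rng_amp.integers(0, 2**31)),
                    )
                    c_reads, _ = simulate.simulate_amplicon_reads(
                        pegrna, ref_window, win, {}, amp.n_reads,
                        seed=int(rng_amp.integers(0, 2**31)),
                    )
                    ref_allele = ref_window
                    edited_allele = simulate.flap_edited_allele(pegrna, ref_window, win)
                    tags = pegrna.tag.all_tags()
                    treated_t.append(
                        editcall.build_outcome_table(
                            site.name, t_reads, ref_allele, edited_allele,
                            tags, pegrna.tag.full_tag,
                        )
                    )
                    control_t.append(
                        editcall.build_outcome_table(
                            site.name, c_reads, ref_allele, edited_allele,
                            tags, pegrna.tag.full_tag,
                        )
                    )
                tables.extend(treated_t)
                rec = editcall.validate_site(treated_t, control_t, site_id=site.name)
                validation_records.append(rec)
                if rec.label == "validated":
                    validated_keys.append(site.key)
            editcall.write_outcome_tables(tables, outdir / "outcome_tables.tsv")
            editcall.write_validation_records(
                validation_records, outdir / "validation.tsv"
            )
            declare("outcome_tables.tsv", "validation.tsv")
        rate = editcall.validation_rate(validation_records)
        summary["stages"]["call"] = {
            "n_validated": sum(r.label == "validated" for r in validation_records),
            "n_false_positive": sum(
                r.label == "false_positive" for r in validation_records
            ),
            "validation_rate": rate,
        }
        log.info("call: %s", summary["stages"]["call"])
    except Exception as exc:  # noqa: BLE001
        _write_manifest(manifest_path, chash, artifacts, failed="call")
        raise StageError("call", exc) from exc

    # ---- stage: analyze ---------------------------------------------------
    try:
        analysis: dict = {}
        tol = config.analysis.match_tolerance
        nominated_keys = [
            (r.site.locus.contig, r.site.nick, r.site.strand) for r in nominated
        ]
        if validated_keys:
            analysis["miss_rate"] = analytics.miss_rate(
                nominated_keys, validated_keys, tol
            )
        if planted is not None:
            planted_keys = [s.key for s in planted]
            analysis["planted_recovery"] = analytics.recall(
                nominated_keys, planted_keys, tol
            )
            # ROC of copy number against the validation labels
            by_label = {r.site_id: r.label for r in validation_records}
            scores, labels = [], []
            for site in planted:
                lab = by_label.get(site.name)
                if lab not in ("validated", "false_positive"):
                    continue
                cn = 0
                for r in reports:
                    s = r.site
                    if (
                        s.locus.contig == site.contig
                        and s.strand == site.strand
                        and s.nick is not None
                        and abs(s.nick - site.nick) <= tol
                    ):
                        cn = max(cn, r.copy_number)
                scores.append(float(cn))
                labels.append(lab)
            if len(set(labels)) == 2:
                roc = analytics.roc(scores, labels, direction="higher")
                analysis["copy_number_auc"] = roc.auc
                with open(outdir / "roc_points.tsv", "w") as fh:
                    fh.write("fpr\ttpr\n")
                    for fpr, tpr in roc.points:
                        fh.write(f"{fpr:.6g}\t{tpr:.6g}\n")
                declare("roc_points.tsv")
            # region mismatch profiles of nominated sites
            with open(outdir / "region_mismatches.tsv", "w") as fh:
                fh.write("site_id\ttarget_mismatch\tpbs_mismatch\trt_mismatch\tpbs_excluded\n")
                for r in nominated:
                    prof = analytics.region_mismatches(r.site, pegrna, genome)
                    fh.write(
                        f"{prof.site_id}\t{prof.target_mismatch}\t"
                        f"{'NA' if prof.pbs_mismatch is None else prof.pbs_mismatch}\t"
                        f"{'NA' if prof.rt_mismatch is None else prof.rt_mismatch}\t"
                        f"{int(prof.pbs_excluded)}\n"
                    )
            declare("region_mismatches.tsv")
            overlap = analytics.overlap_summary(
                {"nominated": set(nominated_keys), "planted": set(planted_keys)}
            )
            analysis["overlap"] = {"&".join(k): v for k, v in overlap.items()}
        summary["stages"]["analyze"] = analysis
        log.info("analyze: %s", analysis)
    except Exception as exc:  # noqa: BLE001
        _write_manifest(manifest_path, chash, artifacts, failed="analyze")
        raise StageError("analyze", exc) from exc

    # ---- stage: report ----------------------------------------------------
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    report_lines = [
        "pipeline report",
        f"seed: {config.seed}",
        f"candidate sites: {summary['stages']['search']['n_candidates']}",
        f"reads in: {summary['stages']['process']['input']}",
        f"mappings kept: {summary['stages']['process']['after_length_filter']}",
        f"nominated sites: {summary['stages']['nominate']['n_nominated']}",
        f"validation: {summary['stages'].get('call', {})}",
        f"analysis: {summary['stages'].get('analyze', {})}",
    ]
    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n")
    declare("summary.json", "report.txt")
    _write_manifest(manifest_path, chash, artifacts)
    return summary


def _write_manifest(
    path: Path, chash: str, artifacts: list[str], failed: Optional[str] = None
) -> None:
    data = {"config_hash": chash, "artifacts": sorted(set(artifacts))}
    if failed:
        data["failed_stage"] = failed
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
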
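"""Config-driven orchestration: simulate -> profile -> metrics -> classify ->
sequence analysis, with per-stage logging and a reproducible run manifest.

Every output table is TSV with a header; the manifest records the resolved
configuration, library totals and normalization weights, per-stage output
files and their checksums. Identical config + seed gives identical output
checksums (the manifest's timestamps aside).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import kinetics, metrics, promoter, simulate, tags
from .config import RunConfig
from .genes import GeneModel, read_bed12, read_gtf, write_bed12, write_gtf

log = logging.getLogger("nascentmetrics")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


class _Data:
    """In-memory handles for the run's genome, annotation and libraries."""

    def __init__(self) -> None:
        self.genes: list[GeneModel] = []
        self.truth: pd.DataFrame | None = None
        self.genome: dict | None = None
        self.genome_length: int | None = None
        self.libraries: dict[str, tags.TagLibrary] = {}
        self.expression: pd.DataFrame | None = None
        self.peaks: pd.DataFrame | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    stages = tuple(stages if stages is not None else cfg.stages)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": cfg.seed,
        "stages": {},
        "libraries": {},
        "files": {},
    }
    manifest["config"] = _config_echo(cfg)
    data = _Data()
    try:
        if "simulate" in stages:
            _stage_simulate(cfg, data, outdir, manifest)
        else:
            _load_data(cfg, data, outdir)
        for lib_name, lib in data.libraries.items():
            manifest["libraries"][lib_name] = {
                "total_mapped": lib.total_mapped,
                "weight": cfg.params.normalization_target / lib.total_mapped,
            }
        if "profile" in stages:
            _stage_profile(cfg, data, outdir, manifest)
        if "metrics" in stages:
            _stage_metrics(cfg, data, outdir, manifest)
        if "classify" in stages:
            _stage_classify(cfg, data, outdir, manifest)
        if "seqanalysis" in stages:
            _stage_seqanalysis(cfg, data, outdir, manifest)
    except PipelineError:
        _finalize(manifest, outdir, failed=True)
        raise
    except Exception as exc:
        _finalize(manifest, outdir, failed=True)
        raise PipelineError("unknown", str(exc)) from exc
    _finalize(manifest, outdir, failed=False)
    log.removeHandler(handler)
    handler.close()
    return manifest


def _finalize(manifest: dict, outdir: Path, failed: bool) -> None:
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["status"] = "failed" if failed else "ok"
    for files in manifest["stages"].values():
        for f in files:
            p = outdir / f
            if p.exists() and f not in manifest["files"]:
                manifest["files"][f] = _sha256(p)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _config_echo(cfg: RunConfig) -> dict:
    echo = {
        "seed": cfg.seed,
        "outdir": str(cfg.outdir),
        "stages": list(cfg.stages),
        "params": dataclasses.asdict(cfg.params),
    }
    if cfg.simulate is not None:
        d = dataclasses.asdict(cfg.simulate)
        d["elongation_efficiency_map"] = {
            f"{k[0]}:{k[1]}": v for k, v in d["elongation_efficiency_map"].items()
        }
        echo["simulate"] = d
    if cfg.inputs is not None:
        echo["inputs"] = {k: str(v) for k, v in cfg.inputs.items()}
    return echo


def _record(manifest: dict, stage: str, outdir: Path, name: str) -> Path:
    manifest["stages"].setdefault(stage, []).append(name)
    return outdir / name


# -- data acquisition ---------------------------------------------------------

def _stage_simulate(cfg: RunConfig, data: _Data, outdir: Path, manifest: dict) -> None:
    sim = cfg.simulate
    if sim is None:
        raise PipelineError("simulate", "no simulate block in the configuration")
    log.info("simulate: %d genes in a %d bp genome (seed %d)",
             sim.n_genes, sim.genome_length, sim.seed)
    data.genes, data.truth = simulate.build_annotation(sim)
    data.genome = simulate.synthesize_genome_sequence(data.genes, data.truth, sim)
    data.genome_length = sim.genome_length
    raw = {
        "chip_histone_basal": simulate.simulate_chip_library(
            data.genes, data.truth, "histone_bimodal", "basal", sim),
        "chip_polii_basal": simulate.simulate_chip_library(
            data.genes, data.truth, "polII_paused", "basal", sim),
        "gro_basal": simulate.simulate_gro_library(data.genes, data.truth, "basal", sim),
        "gro_KLA_1h": simulate.simulate_gro_library(data.genes, data.truth, "KLA_1h", sim),
        "rna_basal": simulate.simulate_rna_library(data.genes, data.truth, "basal", sim),
        "cage": simulate.simulate_cage_library(data.genes, data.truth, sim),
    }
    # ChIP libraries are analyzed after the half-fragment shift; the BED files
    # hold the raw 5' ends, matching what an aligner would produce
    data.libraries = {
        name: tags.shift_tags(lib) if name.startswith("chip") else lib
        for name, lib in raw.items()
    }
    data.expression = simulate.simulate_expression_table(data.truth, sim)

    simulate.write_genome_fasta(data.genome, _record(manifest, "simulate", outdir, "genome.fa"))
    write_bed12(data.genes, _record(manifest, "simulate", outdir, "annotation.bed12"))
    write_gtf(data.genes, _record(manifest, "simulate", outdir, "annotation.gtf"))
    simulate.write_truth_table(data.truth, _record(manifest, "simulate", outdir, "truth.tsv"))
    data.expression.to_csv(_record(manifest, "simulate", outdir, "expression.tsv"),
                           sep="\t", index=False)
    for name, lib in raw.items():
        tags.write_tag_bed(lib, _record(manifest, "simulate", outdir, f"{name}.bed"))
        log.info("simulate: wrote %s (%d tags)", name, lib.total_mapped)


def _load_data(cfg: RunConfig, data: _Data, outdir: Path) -> None:
    """Load inputs from configured paths, or from a previous simulate run."""
    if cfg.inputs is not None:
        inp = cfg.inputs
        ann = Path(inp["annotation"])
        data.genes = read_gtf(ann) if ann.suffix in (".gtf", ".gff") else read_bed12(ann)
        if "genome" in inp:
            from pyfaidx import Fasta
            data.genome = Fasta(str(inp["genome"]))
            data.genome_length = sum(len(r) for r in data.genome.values())
        if "genome_length" in inp:
            data.genome_length = int(inp["genome_length"])
        frag = inp.get("fragment_length", 200)
        for role, stranded, frag_len in (
            ("gro_basal", True, None), ("gro_treated", True, None),
            ("rna_basal", True, None), ("rna_treated", True, None),
            ("cage", True, None),
            ("chip_histone", False, frag), ("chip_polii", False, frag),
        ):
            if role in inp:
                lib = tags.read_tag_bed(inp[role], fragment_length=frag_len,
                                        stranded=stranded)
                if frag_len is not None:
                    lib = tags.shift_tags(lib)
                key = role if role != "gro_treated" else "gro_KLA_1h"
                data.libraries[key] = lib
        if "expression" in inp:
            data.expression = pd.read_csv(inp["expression"], sep="\t")
        if "peaks" in inp:
            data.peaks = kinetics.read_peak_bed(inp["peaks"])
        return
    # synthetic mode without the simulate stage: reload a previous run
    ann = outdir / "annotation.bed12"
    if not ann.exists():
        raise PipelineError(
            "load", f"no inputs configured and {ann} not found; run 'simulate' first")
    data.genes = read_bed12(ann)
    data.genome_length = cfg.simulate.genome_length if cfg.simulate else None
    fasta = outdir / "genome.fa"
    if fasta.exists():
        from pyfaidx import Fasta
        data.genome = Fasta(str(fasta))
    truth_path = outdir / "truth.tsv"
    if truth_path.exists():
        data.truth = simulate.read_truth_table(truth_path)
    expr = outdir / "expression.tsv"
    if expr.exists():
        data.expression = pd.read_csv(expr, sep="\t")
    frag = cfg.simulate.fragment_length if cfg.simulate else 200
    for bed in sorted(outdir.glob("*.bed")):
        name = bed.stem
        is_chip = name.startswith("chip")
        lib = tags.read_tag_bed(bed, fragment_length=frag if is_chip else None,
                                stranded=not is_chip)
        data.libraries[name] = tags.shift_tags(lib) if is_chip else lib


# -- analysis stages ----------------------------------------------------------

def _stage_profile(cfg: RunConfig, data: _Data, outdir: Path, manifest: dict) -> None:
    p = cfg.params
    if not data.libraries:
        raise PipelineError("profile", "no tag libraries available")
    for name, lib in data.libraries.items():
        prof = tags.tss_profile(lib, data.genes, span=p.profile_span,
                                bin_size=p.profile_bin, target=p.normalization_target,
                                sense_only=lib.stranded)
        tags.write_profile_tsv(prof, _record(manifest, "profile", outdir,
                                             f"profile_{name}.tsv"))
        log.info("profile: %s mode at %+.1f bp", name, prof.mode_offset())
    for name in ("chip_polii_basal", "gro_basal"):
        if name in data.libraries:
            tags.write_bedgraph(data.libraries[name], _record(
                manifest, "profile", outdir, f"{name}.bedgraph"),
                target=p.normalization_target)
    # per-gene normalized promoter counts across libraries (heat-map input)
    counts = {"gene_id": [g.gene_id for g in data.genes]}
    for name, lib in data.libraries.items():
        counts[name] = [
            tags.promoter_tag_count(lib, g, window=p.promoter_window,
                                    target=p.normalization_target).normalized_count
            for g in data.genes
        ]
    pd.DataFrame(counts).to_csv(
        _record(manifest, "profile", outdir, "promoter_counts.tsv"),
        sep="\t", index=False)


def _stage_metrics(cfg: RunConfig, data: _Data, outdir: Path, manifest: dict) -> None:
    p = cfg.params
    rows = []
    for cond in ("basal", "KLA_1h"):
        lib = data.libraries.get(f"gro_{cond}")
        if lib is None:
            continue
        for g in data.genes:
            rows.append(dataclasses.asdict(
                metrics.elongation_efficiency(lib, g, condition=cond,
                                              target=p.normalization_target)))
    if rows:
        elong = pd.DataFrame(rows)
        elong.to_csv(
            _record(manifest, "metrics", outdir, "elongation.tsv"), sep="\t", index=False)
        if elong["condition"].nunique() > 1:
            paired = elong.pivot(index="gene_id", columns="condition",
                                 values="efficiency")
            paired.to_csv(_record(manifest, "metrics", outdir,
                                  "elongation_paired.tsv"), sep="\t")
        log.info("metrics: elongation efficiency for %d gene-conditions", len(rows))

    srows = []
    for cond in ("basal", "KLA_1h"):
        rna = data.libraries.get(f"rna_{cond}")
        if rna is None:
            continue
        jrecs, aggregate = metrics.splicing_efficiency_junction(rna, data.genes,
                                                                condition=cond)
        for g, jrec in zip(data.genes, jrecs):
            drec = metrics.splicing_efficiency_density(rna, g, condition=cond,
                                                       target=p.normalization_target)
            merged = dataclasses.asdict(drec)
            for key in ("junction_spanning_density", "junction_exon_density",
                        "efficiency_junction", "evaluable_junction"):
                merged[key] = getattr(jrec, key)
            srows.append(merged)
        log.info("metrics: %s aggregate junction splicing efficiency %.3f",
                 cond, aggregate)
    if srows:
        pd.DataFrame(srows).to_csv(
            _record(manifest, "metrics", outdir, "splicing.tsv"), sep="\t", index=False)

    chip = data.libraries.get("chip_histone_basal")
    if chip is not None and data.genome_length:
        calls = metrics.promoter_enrichment(
            chip, data.genes, data.genome_length, mark="H3K4me3",
            window=p.promoter_window, alpha=p.enrichment_alpha,
            target=p.normalization_target)
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            _record(manifest, "metrics", outdir, "enrichment.tsv"), sep="\t", index=False)
        log.info("metrics: %d/%d promoters enriched over background",
                 sum(c.enriched for c in calls), len(calls))


def _stage_classify(cfg: RunConfig, data: _Data, outdir: Path, manifest: dict) -> None:
    p = cfg.params
    summary: dict = {}
    if data.expression is not None:
        table = kinetics.classify_expression_table(data.expression)
        table.to_csv(_record(manifest, "classify", outdir, "kinetic_classes.tsv"),
                     sep="\t", index=False)
        summary["class_counts"] = table["kinetic_class"].value_counts().to_dict()
        log.info("classify: %s", summary["class_counts"])
    basal, treated = data.libraries.get("gro_basal"), data.libraries.get("gro_KLA_1h")
    if basal is not None and treated is not None:
        calls = kinetics.call_induced_genes(
            basal, treated, data.genes, fold_threshold=p.fold_threshold,
            rpkm_min=p.rpkm_min, q_max=p.fdr_max)
        calls.to_csv(_record(manifest, "classify", outdir, "induced_calls.tsv"),
                     sep="\t", index=False)
        summary["n_induced"] = int(calls["induced"].sum())
        log.info("classify: %d induced genes", summary["n_induced"])
    if data.peaks is not None:
        table, fraction = kinetics.tss_proximal_binding(
            data.peaks, data.genes, radius=p.binding_radius)
        table.to_csv(_record(manifest, "classify", outdir, "tss_proximal.tsv"),
                     sep="\t", index=False)
        summary["tss_proximal_fraction"] = fraction
    with open(_record(manifest, "classify", outdir, "classify_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


def _stage_seqanalysis(cfg: RunConfig, data: _Data, outdir: Path, manifest: dict) -> None:
    p = cfg.params
    if data.genome is None:
        raise PipelineError("seqanalysis", "no genome sequence available")
    classes = None
    if data.truth is not None:
        classes = data.truth.set_index("gene_id")["kinetic_class"]

    gc_rows, tata_rows = [], []
    for g in data.genes:
        rec = promoter.promoter_gc(data.genome, g, window=p.gc_window)
        hit = promoter.scan_tata(data.genome, g, window=p.tata_window)
        cls = str(classes.loc[g.gene_id]) if classes is not None else ""
        gc_rows.append((g.gene_id, cls, rec.gc))
        tata_rows.append((g.gene_id, cls, hit.hit, hit.position, hit.site))
    gc_df = pd.DataFrame(gc_rows, columns=["gene_id", "kinetic_class", "gc"])
    gc_df.to_csv(_record(manifest, "seqanalysis", outdir, "promoter_gc.tsv"),
                 sep="\t", index=False)
    tata_df = pd.DataFrame(tata_rows, columns=["gene_id", "kinetic_class", "tata_hit",
                                               "position", "site"])
    tata_df.to_csv(_record(manifest, "seqanalysis", outdir, "tata_hits.tsv"),
                   sep="\t", index=False)

    summary: dict = {}
    if classes is not None:
        ie = gc_df[gc_df["kinetic_class"] == "IE"]["gc"]
        late = gc_df[gc_df["kinetic_class"] == "late"]["gc"]
        if len(ie) and len(late):
            cutoff, disc = promoter.optimal_gc_cutoff(ie, late)
            summary["gc_cutoff"] = cutoff
            summary["gc_discrimination"] = disc
            summary["fraction_ie_above_cutoff"] = float((ie > cutoff).mean())
            summary["fraction_late_above_cutoff"] = float((late > cutoff).mean())
            log.info("seqanalysis: GC cutoff %.3f (discrimination %.3f)", cutoff, disc)
        for cls in ("IE", "late", "other"):
            sub = tata_df[tata_df["kinetic_class"] == cls]
            if len(sub):
                summary[f"tata_fraction_{cls}"] = float(sub["tata_hit"].mean())

    cage = data.libraries.get("cage")
    if cage is not None:
        refined = [promoter.refine_tss_from_cage(cage, g, flank=p.cage_flank,
                                                 cluster_width=p.cage_cluster_width)
                   for g in data.genes]
        pd.DataFrame([dataclasses.asdict(r) for r in refined]).to_csv(
            _record(manifest, "seqanalysis", outdir, "refined_tss.tsv"),
            sep="\t", index=False)
        log.info("seqanalysis: refined %d/%d TSSs from CAGE",
                 sum(r.refined for r in refined), len(refined))

    if p.motif_file and classes is not None:
        pwms = promoter.read_jaspar(p.motif_file)
        fore = [g for g in data.genes if classes.loc[g.gene_id] == "IE"]
        back = [g for g in data.genes if classes.loc[g.gene_id] == "late"]
        if fore and back:
            reports = [dataclasses.asdict(
                promoter.motif_enrichment(fore, back, pwm, data.genome,
                                          region=p.gc_window)) for pwm in pwms]
            with open(_record(manifest, "seqanalysis", outdir,
                              "motif_enrichment.json"), "w") as fh:
                json.dump(reports, fh, indent=2)
    with open(_record(manifest, "seqanalysis", outdir, "seqanalysis_summary.json"),
              "w") as fh:
        json.dump(summary, fh, indent=2)
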
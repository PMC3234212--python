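"""Parameter-recovery benchmarks run against the synthetic generator.

Each function builds a seeded synthetic dataset with known ground truth, runs
the corresponding estimator, and returns summary recovery statistics. They are
used both by the test suite and by the reproduction script, so the study
conditions (gene counts, read depths, planted parameter grids) live here in
one place.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import kinetics, metrics, promoter, simulate, tags
from .genes import GeneModel
from .simulate import SimConfig


def _seeded(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream])


# -- elongation efficiency -----------------------------------------------------

def elongation_recovery(seed: int = 0, n_genes: int = 200,
                        reads_per_gene: int = 3000,
                        ee_range: tuple[float, float] = (0.05, 2.0)) -> dict:
    """Recover per-gene elongation efficiencies planted uniformly in ``ee_range``."""
    cfg = SimConfig(
        n_genes=n_genes,
        genome_length=2_000_000,
        gene_length_range=(2600, 6000),
        n_exons_range=(1, 1),
        library_sizes={"gro": int(n_genes * reads_per_gene / 0.855)},
        gro_allocation="equal",
        seed=seed,
    )
    genes, truth = simulate.build_annotation(cfg)
    truth = truth.copy()
    truth["ee_basal"] = _seeded(seed, 101).uniform(*ee_range, size=n_genes)
    lib = simulate.simulate_gro_library(genes, truth, "basal", cfg)
    true_map = truth.set_index("gene_id")["ee_basal"]
    rel_errors = []
    for g in genes:
        rec = metrics.elongation_efficiency(lib, g)
        if rec.evaluable:
            t = float(true_map.loc[g.gene_id])
            rel_errors.append(abs(rec.efficiency - t) / t)
    return {
        "median_relative_error": float(np.median(rel_errors)),
        "n_genes": n_genes,
        "n_evaluable": len(rel_errors),
    }


# -- splicing efficiency -------------------------------------------------------

def splicing_recovery(seed: int = 0, n_genes: int = 99,
                      reads_per_gene: int = 10_000,
                      se_values: tuple[float, ...] = (0.5, 0.9, 0.99)) -> dict:
    """Recover splicing efficiencies by both estimators and compare them.

    Genes are compact (13 exons of 80 bp, 12 introns of 100 bp) so that at
    10^4 reads/gene the 19-bp junction windows are densely sampled enough for
    a per-gene comparison of the two estimators.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        genome_length=450_000,
        gene_length_range=(2240, 2240),
        n_exons_range=(13, 13),
        min_exon_length=80,
        min_intron_length=100,
        splicing_efficiency_values=se_values,
        library_sizes={"rna": n_genes * reads_per_gene},
        seed=seed,
    )
    genes, truth = simulate.build_annotation(cfg)
    lib = simulate.simulate_rna_library(genes, truth, "basal", cfg)
    true_map = truth.set_index("gene_id")["true_splicing_efficiency"]
    jrecords, _ = metrics.splicing_efficiency_junction(lib, genes)
    density_err = []
    cross_diff = []
    for g, jrec in zip(genes, jrecords):
        drec = metrics.splicing_efficiency_density(lib, g)
        if drec.evaluable_density:
            density_err.append(abs(drec.efficiency_density - float(true_map.loc[g.gene_id])))
            if jrec.evaluable_junction:
                cross_diff.append(abs(drec.efficiency_density - jrec.efficiency_junction))
    return {
        "density_max_abs_error": float(np.max(density_err)),
        "cross_estimator_max_abs_diff": float(np.max(cross_diff)),
        "n_genes": n_genes,
        "n_evaluable": len(density_err),
    }


# -- CAGE TSS refinement -------------------------------------------------------

def _tss_config(seed: int, n_genes: int, tags_per_gene: int,
                dispersion: float, noise_fraction: float) -> SimConfig:
    return SimConfig(
        n_genes=n_genes,
        genome_length=600_000,
        gene_length_range=(3000, 3000),
        n_exons_range=(1, 1),
        cage_dispersion=dispersion,
        cage_noise_fraction=noise_fraction,
        library_sizes={"cage": n_genes * tags_per_gene},
        seed=seed,
    )


def tss_recovery(seed: int = 0, n_genes: int = 100, tags_per_gene: int = 500) -> dict:
    """TSS refinement: exact recovery noise-free, +/-5 bp recovery under noise."""
    results = {}
    for label, dispersion, noise in (("noisefree", 0.0, 0.0), ("noisy", 5.0, 0.10)):
        cfg = _tss_config(seed, n_genes, tags_per_gene, dispersion, noise)
        genes, truth = simulate.build_annotation(cfg)
        lib = simulate.simulate_cage_library(genes, truth, cfg)
        off_map = truth.set_index("gene_id")["true_tss_offset"]
        errs = []
        for g in genes:
            ref = promoter.refine_tss_from_cage(lib, g)
            true_tss = g.offset_to_genomic(int(off_map.loc[g.gene_id]))
            errs.append(abs(int(ref.refined_tss) - int(true_tss)))
        errs = np.array(errs)
        results[f"exact_fraction_{label}"] = float(np.mean(errs == 0))
        results[f"within_5bp_fraction_{label}"] = float(np.mean(errs <= 5))
    results["n_genes"] = n_genes
    return results


def refine_bruteforce(cage: tags.TagLibrary, gene: GeneModel, flank: int = 1000,
                      cluster_width: int = 100) -> int:
    """Independent all-windows oracle for CAGE TSS refinement (per-tag scan)."""
    t = cage.tags
    sel = t[(t["chrom"] == gene.chrom) & (t["strand"] == gene.strand)]
    offs = [int(o) for o in gene.offset_of(sel["pos"].to_numpy()) if abs(o) <= flank]
    if not offs:
        return gene.tss
    best = None
    for start in range(-flank, flank - cluster_width + 2):
        count = sum(1 for o in offs if start <= o < start + cluster_width)
        if best is None or count > best[0]:
            best = (count, start)
    _, start = best
    best_bp = None
    for bp in range(start, start + cluster_width):
        c = sum(1 for o in offs if o == bp)
        if best_bp is None or c > best_bp[0]:
            best_bp = (c, bp)
    return int(gene.offset_to_genomic(best_bp[1]))


# -- counting oracle and conservation -------------------------------------------

def _random_fixture(seed: int, n_genes: int = 20, n_tags: int = 10_000
                    ) -> tuple[list[GeneModel], tags.TagLibrary]:
    cfg = SimConfig(n_genes=n_genes, genome_length=300_000,
                    gene_length_range=(3000, 6000), n_exons_range=(2, 4), seed=seed)
    genes, _ = simulate.build_annotation(cfg)
    rng = _seeded(seed, 202)
    t = pd.DataFrame({
        "chrom": simulate.CHROM,
        "pos": rng.integers(0, cfg.genome_length, size=n_tags),
        "strand": rng.choice(["+", "-"], size=n_tags),
    })
    return genes, tags.TagLibrary(t, read_length=25, fragment_length=200, stranded=True)


def counting_validation(seed: int = 0) -> dict:
    """Counting operations vs a brute-force per-tag scan; mass conservation;
    strand-mirror invariance of the TSS profile."""
    genes, lib = _random_fixture(seed)
    w = tags.normalize_library(lib)
    rows = list(zip(lib.tags["chrom"], lib.tags["pos"].astype(int), lib.tags["strand"]))

    max_diff = 0.0
    for g in genes:
        # promoter window, inclusive both ends
        bf = sum(1 for c, p, s in rows if c == g.chrom and abs(p - g.tss) <= 1000)
        got = tags.promoter_tag_count(lib, g).normalized_count
        max_diff = max(max_diff, abs(got - bf * w))
        # gene body, sense strand
        bf = sum(1 for c, p, s in rows
                 if c == g.chrom and s == g.strand and g.tx_start <= p < g.tx_end)
        got = tags.gene_body_density(lib, g, sense_only=True)
        max_diff = max(max_diff, abs(got - bf * w / (g.span / 1000.0)))
        got_rpkm = tags.rpkm(lib, g, sense_only=True)
        max_diff = max(max_diff,
                       abs(got_rpkm - bf / (g.span / 1000.0) / (lib.total_mapped / 1e6)))
        # exon / intron split
        d = tags.exon_intron_density(lib, g)
        bf_ex = sum(1 for c, p, s in rows if c == g.chrom and s == g.strand
                    and any(a <= p < b for a, b in g.exons))
        bf_in = sum(1 for c, p, s in rows if c == g.chrom and s == g.strand
                    and any(a <= p < b for a, b in g.introns))
        max_diff = max(max_diff, abs(d.exon_raw - bf_ex), abs(d.intron_raw - bf_in))

    mass = w * lib.total_mapped
    mass_rel_err = abs(mass - tags.NORMALIZATION_TARGET) / tags.NORMALIZATION_TARGET

    # strand-mirror invariance: reverse the coordinate system and all strands
    G = 300_000
    flip = {"+": "-", "-": "+"}
    mt = lib.tags.copy()
    mt["pos"] = G - 1 - mt["pos"]
    mt["strand"] = [flip[s] for s in mt["strand"]]
    mlib = tags.TagLibrary(mt, read_length=25, fragment_length=200, stranded=True)
    mgenes = [
        GeneModel(g.gene_id, g.chrom, flip[g.strand], G - g.tx_end, G - g.tx_start,
                  tuple(sorted((G - e, G - s) for s, e in g.exons)))
        for g in genes
    ]
    prof = tags.tss_profile(lib, genes)
    mprof = tags.tss_profile(mlib, mgenes)
    mirror_diff = float(np.max(np.abs(prof.density - mprof.density)))
    return {
        "mass_relative_error": float(mass_rel_err),
        "counting_oracle_max_diff": float(max_diff),
        "mirror_max_abs_diff": mirror_diff,
        "n_tags": lib.total_mapped,
    }


# -- kinetic classification ------------------------------------------------------

def kinetic_recovery(seed: int = 0, n_genes: int = 300) -> dict:
    """Classification accuracy against planted kinetic classes."""
    out = {"n_genes": n_genes}
    for label, sd in (("noiseless", 0.0), ("noisy", 0.05)):
        cfg = SimConfig(n_genes=n_genes, genome_length=3_000_000,
                        expression_noise_sd=sd, seed=seed)
        genes, truth = simulate.build_annotation(cfg)
        table = simulate.simulate_expression_table(truth, cfg)
        acc = float(np.mean(table["kinetic_class"].to_numpy()
                            == truth["kinetic_class"].to_numpy()))
        out[f"accuracy_{label}"] = acc
    return out


# -- induced-gene calling ---------------------------------------------------------

def induction_benchmark(seed: int = 0, n_genes: int = 500, n_induced: int = 50,
                        fold: float = 5.0, rpkm_induced: float = 2.0,
                        depth: int = 1_000_000) -> dict:
    """Sensitivity and observed FDR on a planted induction experiment."""
    genes, truth, basal, treated = simulate.simulate_induction_pair(
        n_genes=n_genes, n_induced=n_induced, fold=fold,
        rpkm_induced=rpkm_induced, depth=depth, seed=seed)
    calls = kinetics.call_induced_genes(basal, treated, genes)
    merged = calls.merge(truth[["gene_id", "induced"]].rename(
        columns={"induced": "true_induced"}), on="gene_id")
    tp = int((merged["induced"] & merged["true_induced"]).sum())
    fp = int((merged["induced"] & ~merged["true_induced"]).sum())
    n_called = tp + fp
    return {
        "sensitivity": tp / n_induced,
        "observed_fdr": fp / n_called if n_called else 0.0,
        "n_called": n_called,
        "depth": depth,
    }


def induction_null_rate(seed: int = 0, n_seeds: int = 10, n_genes: int = 500,
                        depth: int = 200_000) -> dict:
    """Fraction of q < 0.10 calls under a no-induction null, pooled over seeds."""
    n_calls = 0
    n_total = 0
    for k in range(n_seeds):
        genes, _, basal, treated = simulate.simulate_induction_pair(
            n_genes=n_genes, n_induced=0, depth=depth, gene_length=10_000,
            seed=(seed * 1000 + k) & 0x7FFFFFFF)
        calls = kinetics.call_induced_genes(basal, treated, genes)
        n_calls += int((calls["fdr_q"] < 0.10).sum())
        n_total += len(calls)
    rate = n_calls / n_total
    return {
        "null_q_call_rate": rate,
        "threshold": 0.10 + 3 * np.sqrt(0.10 * 0.90 / n_total),
        "n_tests": n_total,
    }


# -- profile shapes ----------------------------------------------------------------

def profile_shape(seed: int = 0, n_genes: int = 50, library_size: int = 400_000) -> dict:
    """Aggregate shifted-profile mode (Pol II) and nadir (histone marks)."""
    cfg = SimConfig(n_genes=n_genes, genome_length=1_000_000,
                    gene_length_range=(3000, 3000), n_exons_range=(1, 1),
                    library_sizes={"chip": library_size}, seed=seed)
    genes, truth = simulate.build_annotation(cfg)
    pol = tags.shift_tags(simulate.simulate_chip_library(genes, truth,
                                                         "polII_paused", "basal", cfg))
    his = tags.shift_tags(simulate.simulate_chip_library(genes, truth,
                                                         "histone_bimodal", "basal", cfg))
    pol_prof = tags.tss_profile(pol, genes)
    his_prof = tags.tss_profile(his, genes)
    return {
        "polii_mode_bp": pol_prof.mode_offset(),
        "histone_nadir_bp": his_prof.min_offset(lo=-300, hi=200),
        "library_size": library_size,
    }


# -- promoter sequence: GC, TATA, CAGE oracle ----------------------------------------

def sequence_recovery(seed: int = 0, n_genes: int = 100) -> dict:
    """Planted GC / TATA recovery and oracle checks for cutoff and TSS refinement."""
    cfg = SimConfig(
        n_genes=n_genes,
        genome_length=800_000,
        gene_length_range=(2000, 2000),
        n_exons_range=(1, 1),
        class_fractions={"IE": 0.5, "late": 0.5, "other": 0.0},
        gc_level_map={"IE": 0.70, "late": 0.45, "other": 0.50},
        tata_fraction_map={"IE": 0.4, "late": 0.4, "other": 0.4},
        cage_dispersion=5.0,
        cage_noise_fraction=0.10,
        library_sizes={"cage": n_genes * 200},
        seed=seed,
    )
    genes, truth = simulate.build_annotation(cfg)
    genome = simulate.synthesize_genome_sequence(genes, truth, cfg)
    tmap = truth.set_index("gene_id")

    gc_err = []
    tata_hits = []
    gc_by_class = {"IE": [], "late": []}
    for g in genes:
        rec = promoter.promoter_gc(genome, g)
        gc_err.append(abs(rec.gc - float(tmap.at[g.gene_id, "promoter_gc"])))
        gc_by_class[str(tmap.at[g.gene_id, "kinetic_class"])].append(rec.gc)
        tata_hits.append(promoter.scan_tata(genome, g).hit)
    planted_fraction = float(truth["has_tata"].mean())
    recovered_fraction = float(np.mean(tata_hits))

    cutoff, disc = promoter.optimal_gc_cutoff(gc_by_class["IE"], gc_by_class["late"])
    bf_cutoff, bf_disc = _cutoff_bruteforce(gc_by_class["IE"], gc_by_class["late"])

    cage = simulate.simulate_cage_library(genes, truth, cfg)
    mismatches = sum(
        int(promoter.refine_tss_from_cage(cage, g).refined_tss
            != refine_bruteforce(cage, g))
        for g in genes[:25]  # the per-tag oracle is O(windows x tags); 25 genes suffice
    )
    return {
        "gc_max_abs_error": float(np.max(gc_err)),
        "gc_cutoff": cutoff,
        "gc_discrimination": disc,
        "gc_cutoff_oracle_diff": abs(cutoff - bf_cutoff) + abs(disc - bf_disc),
        "tata_fraction_error": abs(recovered_fraction - planted_fraction),
        "refine_oracle_mismatches": mismatches,
        "n_genes": n_genes,
    }


def _cutoff_bruteforce(a, b) -> tuple[float, float]:
    """Independent exhaustive threshold scan (pure-python loops)."""
    candidates = sorted(set(list(a) + list(b)))
    best = None
    for t in candidates:
        fa = sum(1 for x in a if x > t) / len(a)
        fb = sum(1 for x in b if x > t) / len(b)
        d = abs(fa - fb)
        if best is None or d > best[0]:
            best = (d, t)
    return best[1], best[0]
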